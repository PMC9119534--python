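"""End-to-end orchestration: scan → annotate → enrich → meta, plus the
parameter-sensitivity sweep.

Each focal population is scanned through its comparisons (three in the
standard design), the retained windows' peak SNPs are annotated to a
merged gene list, the list is tested for gene-set over-representation,
and the enriched sets' traits are meta-tested against the curated
relevant-trait list.  Every intermediate table is persisted as TSV and
a machine-readable JSON summary records counts at each stage, so the
pipeline's arithmetic is auditable and each stage re-runnable from its
files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, enrich, meta, scan
from .io import load_allele_counts, load_gene_models, load_gmt, load_trait_votes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    gene_models: str
    gmt: str
    trait_votes: str
    comparisons: dict[str, list[scan.ComparisonSpec]]  # focal -> its triples
    out_dir: str = "pbscan_out"
    window_size: int = 20
    step: int = 5
    top_fraction: float = 0.001
    radius: int = 5000
    min_overlap: int = 2
    alpha: float = 0.05
    min_votes: int = 2
    universe_size: int | None = None   # None -> total sets in the GMT source
    estimator: str = "hudson"
    metapopulations: dict[str, list[str]] = field(default_factory=dict)
    pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for focal, specs in self.comparisons.items():
            if not specs:
                raise ValueError(f"focal population {focal!r} has no comparisons")
            for s in specs:
                if s.focal != focal:
                    raise ValueError(
                        f"comparison {s.name!r} listed under focal {focal!r}"
                    )

    def population_labels(self) -> dict[str, list[str]]:
        """Mapping of every label used by comparisons to its map labels."""
        labels: dict[str, list[str]] = {}
        for specs in self.comparisons.values():
            for s in specs:
                for lab in (s.focal, s.close, s.distant):
                    labels[lab] = self.metapopulations.get(lab, [lab])
        return labels

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        comparisons = {
            focal: [scan.ComparisonSpec(**spec) for spec in specs]
            for focal, specs in raw.pop("comparisons").items()
        }
        pairs = [tuple(p) for p in raw.pop("pairs", [])]
        return cls(comparisons=comparisons, pairs=pairs, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["comparisons"] = {
            focal: [dataclasses.asdict(s) for s in specs]
            for focal, specs in self.comparisons.items()
        }
        raw["pairs"] = [list(p) for p in self.pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class FocalResult:
    focal: str
    scans: dict[str, scan.ScanResult]
    gene_list: list[str]
    gene_hits: pd.DataFrame
    enrichment: enrich.EnrichmentResult
    meta_result: meta.MetaResult


@dataclass
class PipelineResult:
    config: PipelineConfig
    focal_results: dict[str, FocalResult]
    pair_results: dict[str, meta.MetaResult]
    summary: dict


def _safe(name: str) -> str:
    return name.replace(" ", "").replace(";", "_").replace("x", "x")


def run_pipeline(config: PipelineConfig, persist: bool = True) -> PipelineResult:
    """Execute the full study design described by ``config``.

    Deterministic given the configuration: identical inputs produce a
    byte-identical summary JSON.  Any stage failure raises with a
    stage-tagged message; tables persisted before the failure remain.
    """
    out = Path(config.out_dir)
    if persist:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        counts = load_allele_counts(config.vcf, config.popmap,
                                    populations=config.population_labels())
        genes = load_gene_models(config.gene_models)
        db = load_gmt(config.gmt)
        votes = load_trait_votes(config.trait_votes)
    except Exception as exc:
        raise RuntimeError(f"[{current}] {exc}") from exc

    relevant = meta.select_relevant_traits(votes, min_votes=config.min_votes)
    universe_size = config.universe_size or db.n_sets

    focal_results: dict[str, FocalResult] = {}
    summary: dict = {
        "n_snps": counts.n_snps,
        "n_snps_skipped_io": counts.n_skipped,
        "n_genes_annotation": len(genes),
        "n_gene_sets": db.n_sets,
        "n_relevant_traits": len(relevant),
        "universe_size": universe_size,
        "focal": {},
    }
    for focal, specs in config.comparisons.items():
        current = stage(f"scan:{focal}")
        try:
            scans = {
                s.name: scan.run_comparison(
                    counts, s, size=config.window_size, step=config.step,
                    fraction=config.top_fraction, estimator=config.estimator,
                )
                for s in specs
            }
        except Exception as exc:
            raise RuntimeError(f"[{current}] {exc}") from exc

        current = stage(f"annotate:{focal}")
        gene_list, hits = annotate.build_gene_list(
            {name: r.retained for name, r in scans.items()},
            genes, radius=config.radius,
        )

        current = stage(f"enrich:{focal}")
        enr = enrich.enrich_gene_list(
            gene_list, db, min_overlap=config.min_overlap, alpha=config.alpha
        )

        current = stage(f"meta:{focal}")
        enriched_traits = list(enr.significant["set"])
        mres = meta.meta_test(enriched_traits, relevant, universe_size)

        focal_results[focal] = FocalResult(
            focal=focal, scans=scans, gene_list=gene_list,
            gene_hits=hits, enrichment=enr, meta_result=mres,
        )
        summary["focal"][focal] = {
            "comparisons": {name: r.log for name, r in scans.items()},
            "n_genes": len(gene_list),
            "n_enriched": len(enriched_traits),
            "n_matches": len(mres.matched_traits),
            "p_value": mres.p_value,
            "odds_ratio": mres.odds_ratio,
            "sample_odds_ratio": mres.sample_odds_ratio,
        }
        if persist:
            _persist_focal(out, focal, focal_results[focal])

    pair_results: dict[str, meta.MetaResult] = {}
    for pop1, pop2 in config.pairs:
        current = stage(f"meta-pair:{pop1}-vs-{pop2}")
        m1 = len(focal_results[pop1].meta_result.matched_traits)
        m2 = len(focal_results[pop2].meta_result.matched_traits)
        table = meta.population_pair_table(m1, m2, len(relevant))
        pr = meta.fisher_one_tailed(table)
        pair_results[f"{pop1} vs {pop2}"] = pr
        summary.setdefault("pairs", {})[f"{pop1} vs {pop2}"] = {
            "matches_1": m1, "matches_2": m2,
            "n_relevant": len(relevant),
            "p_value": pr.p_value, "odds_ratio": pr.odds_ratio,
        }

    if persist:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return PipelineResult(config=config, focal_results=focal_results,
                          pair_results=pair_results, summary=summary)


def _persist_focal(out: Path, focal: str, res: FocalResult) -> None:
    for name, r in res.scans.items():
        tag = f"{focal}_{_safe(name)}"
        r.pbs_table.to_csv(out / f"{tag}_snps.tsv", sep="\t", index=False)
        r.windows.to_csv(out / f"{tag}_windows.tsv", sep="\t", index=False)
    with open(out / f"{focal}_genes.txt", "w") as fh:
        fh.writelines(g + "\n" for g in res.gene_list)
    res.gene_hits.to_csv(out / f"{focal}_gene_hits.tsv", sep="\t", index=False)
    res.enrichment.table.to_csv(out / f"{focal}_enrichment.tsv", sep="\t", index=False)


@dataclass
class SweepGrid:
    """Cartesian sensitivity grid over window geometry, retention and votes."""

    windows: list[tuple[int, int]] = field(default_factory=lambda: [(20, 5), (30, 10)])
    fractions: list[float] = field(default_factory=lambda: [0.001, 0.0005])
    min_votes: list[int] = field(default_factory=lambda: [2, 3])

    def __post_init__(self) -> None:
        if not (self.windows and self.fractions and self.min_votes):
            raise ValueError("every sweep axis must be non-empty")


def sensitivity_sweep(config: PipelineConfig, grid: SweepGrid) -> pd.DataFrame:
    """Repeat the enrichment/meta analysis over every grid combination.

    Returns one row per (window geometry, top fraction, vote threshold,
    focal population) with the meta-test P, OR and stage counts.  The
    combination matching ``config`` reproduces ``run_pipeline`` exactly.
    """
    rows = []
    for (size, step), fraction, mv in product(grid.windows, grid.fractions,
                                              grid.min_votes):
        cfg = dataclasses.replace(
            config, window_size=size, step=step, top_fraction=fraction,
            min_votes=mv,
        )
        res = run_pipeline(cfg, persist=False)
        for focal, fres in res.focal_results.items():
            rows.append({
                "window_size": size,
                "step": step,
                "top_fraction": fraction,
                "min_votes": mv,
                "focal": focal,
                "n_retained": sum(len(r.retained) for r in fres.scans.values()),
                "n_genes": len(fres.gene_list),
                "n_enriched": len(fres.enrichment.significant),
                "n_matches": len(fres.meta_result.matched_traits),
                "p_value": fres.meta_result.p_value,
                "odds_ratio": fres.meta_result.odds_ratio,
            })
    return pd.DataFrame(rows)
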