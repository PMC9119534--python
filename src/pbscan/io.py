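"""Readers for genotypes, population maps, gene models, gene sets and trait votes.

All genomic coordinates are 1-based inclusive internally; conversions
from 0-based half-open conventions (BED) happen only here, at the I/O
boundary.  Only genotyped biallelic SNPs enter the pipeline — indels
and multi-allelic sites are skipped with a logged count, and missing
genotypes reduce the per-SNP allele denominator (no imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PopAlleleCounts:
    """Per-population alternate/total allele counts at each SNP.

    ``snps`` holds chrom, pos (1-based), id; ``alt_counts`` and
    ``total_counts`` are DataFrames with one integer column per
    population, row-aligned with ``snps``.
    """

    snps: pd.DataFrame
    alt_counts: pd.DataFrame
    total_counts: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if list(self.alt_counts.columns) != list(self.total_counts.columns):
            raise ValueError("alt and total population columns differ")
        if (self.alt_counts.to_numpy() > self.total_counts.to_numpy()).any():
            raise ValueError("alternate allele count exceeds total at some site")
        if (self.alt_counts.to_numpy() < 0).any():
            raise ValueError("negative allele count")
        for chrom, grp in self.snps.groupby("chrom", sort=False, observed=True):
            d = np.diff(grp["pos"].to_numpy())
            if (d <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on {chrom}"
                )

    @property
    def populations(self) -> list[str]:
        return list(self.alt_counts.columns)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def alt(self, population: str) -> np.ndarray:
        return self.alt_counts[population].to_numpy()

    def total(self, population: str) -> np.ndarray:
        return self.total_counts[population].to_numpy()


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GeneSetDB:
    """A named collection of gene sets from one source (e.g. a GMT file).

    The background universe defaults to the union of all member genes
    unless given explicitly.
    """

    source: str
    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        union: set[str] = set()
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            union |= set(genes)
        if not self.universe:
            self.universe = frozenset(union)
        elif not union <= set(self.universe):
            raise ValueError("universe does not cover all gene-set members")

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def read_population_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (sample_id, population), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"population map {path}: expected two columns")
    df = df.iloc[:, :2]
    df.columns = ["sample", "population"]
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"population map {path}: duplicate sample {dup!r}")
    return df


def load_allele_counts(
    vcf_path: str | Path,
    popmap_path: str | Path,
    populations: Sequence[str] | Mapping[str, Sequence[str]] | None = None,
) -> PopAlleleCounts:
    """Count alternate/total alleles per population from a VCF.

    ``populations`` selects which map labels to load; a mapping merges
    several map labels into one metapopulation, e.g.
    ``{"WA": ["Wolof", "Yoruba"], "K": ["K"]}``.  ``None`` loads every
    label in the map.  Counts use non-missing genotype calls only;
    non-biallelic or non-SNP records are skipped (logged).  A sample
    listed in the map but absent from the VCF is an error.
    """
    from cyvcf2 import VCF

    popmap = read_population_map(popmap_path)
    if populations is None:
        group_map = {p: [p] for p in popmap["population"].unique()}
    elif isinstance(populations, Mapping):
        group_map = {k: list(v) for k, v in populations.items()}
    else:
        group_map = {p: [p] for p in populations}

    known = set(popmap["population"])
    for out_label, members in group_map.items():
        for m in members:
            if m not in known:
                raise KeyError(f"population {m!r} not present in {popmap_path}")

    vcf = VCF(str(vcf_path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    group_cols: dict[str, np.ndarray] = {}
    for out_label, members in group_map.items():
        samples = popmap.loc[popmap["population"].isin(members), "sample"]
        missing = [s for s in samples if s not in sample_index]
        if missing:
            raise KeyError(
                f"samples in population map but absent from VCF: {missing[:5]}"
            )
        group_cols[out_label] = np.array([sample_index[s] for s in samples])

    chroms: list[str] = []
    positions: list[int] = []
    ids: list[str] = []
    alt_rows: list[list[int]] = []
    tot_rows: list[list[int]] = []
    labels = list(group_cols)
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=missing, 3=hom-alt
        gt = np.asarray(v.gt_types)
        alt_per_sample = np.where(gt == 1, 1, np.where(gt == 3, 2, 0))
        called = gt != 2
        alt_rows.append([int(alt_per_sample[group_cols[p]].sum()) for p in labels])
        tot_rows.append([int(2 * called[group_cols[p]].sum()) for p in labels])
        chroms.append(v.CHROM)
        positions.append(v.POS)
        ids.append(v.ID or f"{v.CHROM}:{v.POS}")
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic/non-SNP records", vcf_path, n_skipped)

    snps = pd.DataFrame({"chrom": chroms, "pos": positions, "id": ids})
    alt_df = pd.DataFrame(alt_rows, columns=labels, dtype=int)
    tot_df = pd.DataFrame(tot_rows, columns=labels, dtype=int)
    return PopAlleleCounts(snps=snps, alt_counts=alt_df, total_counts=tot_df,
                           n_skipped=n_skipped)


def load_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from BED (0-based half-open) or GFF3.

    BED intervals are converted to 1-based inclusive: ``(start+1, end)``.
    GFF3 ``gene`` features use their ID (or Name) attribute and native
    1-based inclusive coordinates.  Duplicate gene ids are rejected.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gff3" if suffix in {".gff", ".gff3"} else "bed"
    if format == "bed":
        genes = _read_bed(path)
    elif format == "gff3":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line has <4 fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            strand = parts[5] if len(parts) >= 6 else "."
            genes.append(
                GeneModel(gene_id=parts[3], chrom=parts[0],
                          start=start0 + 1, end=end0, strand=strand)
            )
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("Name") or [None])[0]
        if gene_id is None:
            raise ValueError(f"{path}: gene feature without ID/Name at {feat.start}")
        genes.append(
            GeneModel(gene_id=gene_id, chrom=feat.seqid,
                      start=feat.start, end=feat.end, strand=feat.strand or ".")
        )
    return genes


def load_gmt(path: str | Path, source: str | None = None) -> GeneSetDB:
    """Read a GMT gene-set database: name TAB description TAB gene..."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT row needs name, description, >=1 gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = frozenset(genes)
    return GeneSetDB(source=source or path.stem, sets=sets)


def write_gmt(db: GeneSetDB, path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    """Write a GeneSetDB to GMT (sorted members for determinism)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in db.sets:
            genes = "\t".join(sorted(db.sets[name]))
            fh.write(f"{name}\t{descriptions.get(name, 'na')}\t{genes}\n")


def load_trait_votes(path: str | Path) -> pd.DataFrame:
    """Read a trait-vote table: trait TAB rater1..rater4 as 0/1 flags.

    Returns a DataFrame with columns ``trait`` and ``votes`` (0–4).
    """
    df = pd.read_csv(path, sep="\t")
    if "trait" not in df.columns:
        raise ValueError(f"{path}: missing 'trait' column")
    rater_cols = [c for c in df.columns if c.lower().startswith("rater")]
    if not rater_cols:
        raise ValueError(f"{path}: no rater columns found")
    flags = df[rater_cols]
    if not flags.isin([0, 1]).all().all():
        raise ValueError(f"{path}: rater flags must be 0/1")
    out = pd.DataFrame({"trait": df["trait"].astype(str).str.strip(),
                        "votes": flags.sum(axis=1).astype(int)})
    return out
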