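"""Synthetic genotype, annotation and gene-set fixtures with planted truth.

The generator emulates the statistical structure a three-population
differentiation scan assumes: several populations drift independently
from a shared ancestral allele frequency under the Balding–Nichols
model (population frequencies Beta-distributed around the ancestral
frequency with drift parameter F), a handful of loci are pushed to
high focal-population differentiation ("planted"), diploid genotypes
are drawn binomially and written to VCF, and gene models / gene-set
databases / rater-vote trait tables are laid out so that every planted
locus has a nearby "linked" gene and some gene sets preferentially
contain planted genes.  A TruthTable records everything needed to
score recovery.

There is no linkage disequilibrium, recombination or admixture: sites
are independent given the ancestral frequency, which is what the
per-SNP scan statistics assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, GeneSetDB, write_gmt

# sub-stream indices for the single user-facing seed
_STAGE_FREQ, _STAGE_GENO, _STAGE_SETS = 0, 1, 2


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


@dataclass(frozen=True)
class Population:
    """One simulated population: label, drift F in [0,1), diploid size."""

    label: str
    drift: float
    n_diploid: int


@dataclass(frozen=True)
class PlantedLocus:
    """A SNP pushed toward high differentiation in one population.

    ``frequency_shift`` is added to the post-drift frequency of
    ``target_population`` and the result clipped to [0, 1];
    ``linked_gene`` names the gene the annotation generator places
    within 5 kb of the SNP.
    """

    chromosome: int
    snp_index: int
    target_population: str
    frequency_shift: float
    linked_gene: str


@dataclass(frozen=True)
class SimulationParams:
    n_chromosomes: int = 3
    snps_per_chromosome: int = 2000
    chromosome_length: int = 2_000_000
    # five roles: focal, close, alternative close, and two distant
    # references (continental African and Eurasian metapopulation
    # analogues).  Sample sizes follow the real study design; drift F
    # values give realistic pairwise FST (~0.02 within-region, ~0.15
    # between continents).
    populations: tuple[Population, ...] = (
        Population("FOC", 0.01, 100),
        Population("CLO", 0.01, 74),
        Population("CL2", 0.02, 42),
        Population("WAF", 0.02, 618),
        Population("EUR", 0.15, 569),
    )
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    planted: tuple[PlantedLocus, ...] = ()
    seed: int = 0
    missing_rate: float = 0.0
    # annotation / gene-set geometry
    genes_per_chromosome: int = 40
    gene_length: int = 2000
    n_sets: int = 60
    n_relevant_sets: int = 8
    set_size_range: tuple[int, int] = (5, 15)
    relevant_planted_fraction: float = 0.6
    distractor_vote_fraction: float = 0.3

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < low < high < 1")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one SNP")
        if self.snps_per_chromosome > self.chromosome_length:
            raise ValueError("more SNPs than base pairs on a chromosome")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        for p in self.populations:
            if not np.isfinite(p.drift) or not (0.0 <= p.drift < 1.0):
                raise ValueError(f"population {p.label}: drift F must be in [0,1)")
            if p.n_diploid < 2:
                raise ValueError(f"population {p.label}: need >= 2 diploids")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        for pl in self.planted:
            if not (0 <= pl.chromosome < self.n_chromosomes):
                raise ValueError(f"planted locus chromosome {pl.chromosome} out of range")
            if not (0 <= pl.snp_index < self.snps_per_chromosome):
                raise ValueError(f"planted locus SNP index {pl.snp_index} out of range")
            if pl.target_population not in {p.label for p in self.populations}:
                raise ValueError(f"unknown target population {pl.target_population!r}")
            if not np.isfinite(pl.frequency_shift) or abs(pl.frequency_shift) > 1:
                raise ValueError("frequency_shift must be finite and in [-1, 1]")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]


@dataclass
class TruthTable:
    """Ground truth for scoring recovery of planted structure."""

    planted: pd.DataFrame          # one row per planted locus, final freqs
    relevant_genes: frozenset[str]
    relevant_sets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        key = self.planted[["chromosome", "snp_index"]]
        if key.duplicated().any():
            raise ValueError("a planted locus appears more than once")


def choose_planted_loci(
    freqs: pd.DataFrame,
    params: SimulationParams,
    n: int = 10,
    shift: float = 0.5,
    target: str = "FOC",
) -> tuple[PlantedLocus, ...]:
    """Pick ``n`` SNPs to plant, spread evenly across chromosomes.

    Planted loci are meant to be *highly differentiated* with exact,
    known effect size, so candidates are restricted to SNPs where the
    shift acts in full — post-drift target frequency at most
    ``1 - shift`` for a positive shift (at least ``-shift`` for a
    negative one) — and to the central 76% of each chromosome so every
    locus is covered by full windows.  Deterministic given ``freqs``.
    """
    per_chrom = [n // params.n_chromosomes] * params.n_chromosomes
    for i in range(n % params.n_chromosomes):
        per_chrom[i] += 1
    loci = []
    g = 0
    L = params.snps_per_chromosome
    lo_idx, hi_idx = int(L * 0.12), int(L * 0.88)
    for c, count in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        block = freqs[freqs["chrom"] == chrom].reset_index(drop=True)
        p = block[target].to_numpy()
        if shift >= 0:
            eligible = np.flatnonzero(p <= 1.0 - shift)
        else:
            eligible = np.flatnonzero(p >= -shift)
        eligible = eligible[(eligible >= lo_idx) & (eligible <= hi_idx)]
        if len(eligible) < count:
            raise ValueError(f"{chrom}: not enough eligible SNPs to plant")
        picks = eligible[np.linspace(0, len(eligible) - 1, count).astype(int)]
        for i in picks:
            g += 1
            loci.append(
                PlantedLocus(
                    chromosome=c,
                    snp_index=int(i),
                    target_population=target,
                    frequency_shift=shift,
                    linked_gene=f"PLANT_G{g:02d}",
                )
            )
    return tuple(loci)


def simulate_three_pop_freqs(params: SimulationParams) -> pd.DataFrame:
    """Draw per-population allele frequencies under Balding–Nichols drift.

    For each SNP an ancestral frequency p is uniform on
    ``ancestral_freq_range``; each population's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) for drift F > 0, and exactly p for
    F = 0.  Deterministic given the seed.

    Returns a DataFrame with chrom, pos, id, anc and one frequency
    column per population label.
    """
    rng = _rng(params.seed, _STAGE_FREQ)
    frames = []
    for c in range(params.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = np.sort(
            rng.choice(params.chromosome_length, size=params.snps_per_chromosome,
                       replace=False)
        ) + 1
        anc = rng.uniform(*params.ancestral_freq_range,
                          size=params.snps_per_chromosome)
        df = pd.DataFrame({
            "chrom": chrom,
            "pos": pos.astype(int),
            "id": [f"{chrom}_snp{i}" for i in range(params.snps_per_chromosome)],
            "anc": anc,
        })
        for p in params.populations:
            if p.drift == 0.0:
                df[p.label] = anc
            else:
                scale = (1.0 - p.drift) / p.drift
                df[p.label] = rng.beta(anc * scale, (1.0 - anc) * scale)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def plant_differentiated_loci(
    freqs: pd.DataFrame,
    planted: Sequence[PlantedLocus],
    params: SimulationParams,
) -> tuple[pd.DataFrame, TruthTable]:
    """Shift target-population frequencies at planted loci (clipped to [0,1]).

    Returns the modified table and a TruthTable recording the final
    frequencies at each planted locus.  All other entries are untouched.
    """
    out = freqs.copy()
    records = []
    labels = params.labels
    for pl in planted:
        if pl.target_population not in labels:
            raise KeyError(f"unknown population {pl.target_population!r}")
        row = pl.chromosome * params.snps_per_chromosome + pl.snp_index
        if not (0 <= row < len(out)):
            raise IndexError("planted locus outside the frequency table")
        before = float(out.at[row, pl.target_population])
        after = float(np.clip(before + pl.frequency_shift, 0.0, 1.0))
        out.at[row, pl.target_population] = after
        rec = {
            "chromosome": pl.chromosome,
            "snp_index": pl.snp_index,
            "chrom": out.at[row, "chrom"],
            "pos": int(out.at[row, "pos"]),
            "id": out.at[row, "id"],
            "target_population": pl.target_population,
            "frequency_shift": pl.frequency_shift,
            "freq_before": before,
            "freq_after": after,
            "linked_gene": pl.linked_gene,
        }
        for lab in labels:
            rec[f"freq_{lab}"] = float(out.at[row, lab])
        records.append(rec)
    truth = TruthTable(
        planted=pd.DataFrame(records),
        relevant_genes=frozenset(pl.linked_gene for pl in planted),
    )
    return out, truth


@dataclass
class GenotypeSim:
    vcf_path: Path
    popmap_path: Path
    genotypes: dict[str, np.ndarray]   # label -> (n_snps, n_diploid), -1 = missing
    samples: dict[str, list[str]]


def simulate_genotypes(
    freqs: pd.DataFrame,
    params: SimulationParams,
    vcf_path: str | Path,
    popmap_path: str | Path,
) -> GenotypeSim:
    """Draw diploid genotypes binomially and write VCF 4.2 + population map.

    Each sample's genotype at a SNP is Binomial(2, p) alternate alleles;
    with ``missing_rate`` > 0 a call is masked to ``./.`` independently.
    The VCF carries contig headers, unique IDs, sorted positions and a
    GT-only FORMAT; the map lists every sample exactly once.
    """
    rng = _rng(params.seed, _STAGE_GENO)
    n_snps = len(freqs)
    genotypes: dict[str, np.ndarray] = {}
    samples: dict[str, list[str]] = {}
    for p in params.populations:
        freq = freqs[p.label].to_numpy()
        if (freq < 0).any() or (freq > 1).any():
            raise ValueError(f"population {p.label}: frequencies outside [0,1]")
        g = rng.binomial(2, freq[:, None], size=(n_snps, p.n_diploid))
        if params.missing_rate > 0:
            mask = rng.random((n_snps, p.n_diploid)) < params.missing_rate
            g = np.where(mask, -1, g)
        genotypes[p.label] = g.astype(np.int8)
        samples[p.label] = [f"{p.label}_{i:04d}" for i in range(p.n_diploid)]

    vcf_path, popmap_path = Path(vcf_path), Path(popmap_path)
    _write_vcf(freqs, params, genotypes, samples, vcf_path)
    with open(popmap_path, "w") as fh:
        for p in params.populations:
            for s in samples[p.label]:
                fh.write(f"{s}\t{p.label}\n")
    return GenotypeSim(vcf_path=vcf_path, popmap_path=popmap_path,
                       genotypes=genotypes, samples=samples)


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(freqs, params, genotypes, samples, path: Path) -> None:
    labels = params.labels
    all_samples = [s for lab in labels for s in samples[lab]]
    cols = np.concatenate([genotypes[lab] for lab in labels], axis=1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pbscan-simulate\n")
        for c in range(params.n_chromosomes):
            fh.write(f"##contig=<ID=chr{c + 1},length={params.chromosome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(all_samples) + "\n")
        chroms = freqs["chrom"].to_numpy()
        poss = freqs["pos"].to_numpy()
        ids = freqs["id"].to_numpy()
        for i in range(len(freqs)):
            gts = "\t".join(_GT_STR[int(g)] for g in cols[i])
            fh.write(f"{chroms[i]}\t{poss[i]}\t{ids[i]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


@dataclass
class AnnotationBundle:
    genes: list[GeneModel]
    gene_sets: GeneSetDB
    votes: pd.DataFrame            # trait, rater1..rater4
    truth: TruthTable


def generate_annotation_and_sets(
    params: SimulationParams,
    freqs: pd.DataFrame,
    truth: TruthTable,
) -> AnnotationBundle:
    """Lay out gene models, a gene-set database and a rater-vote table.

    Planted genes are placed within 5 kb of their locus; background
    genes are tiled non-overlappingly along each chromosome.
    "Relevant" sets draw ``relevant_planted_fraction`` of their members
    from planted genes (at least one each); background sets draw genes
    uniformly.  Relevant sets receive 2–4 rater votes; a
    ``distractor_vote_fraction`` of background sets receive exactly one.
    """
    if params.genes_per_chromosome < 1:
        raise ValueError("need at least one gene per chromosome")
    rng = _rng(params.seed, _STAGE_SETS)
    gene_len = params.gene_length
    genes: list[GeneModel] = []

    # planted genes first: start 200 bp downstream of the planted SNP
    planted_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in truth.planted.itertuples():
        start = min(rec.pos + 200, params.chromosome_length - gene_len)
        end = start + gene_len - 1
        genes.append(GeneModel(rec.linked_gene, rec.chrom, start, end, "+"))
        planted_by_chrom.setdefault(rec.chrom, []).append((start, end))

    spacing = params.chromosome_length // params.genes_per_chromosome
    if spacing <= gene_len:
        raise ValueError("genes cannot fit: gene_length too large for tiling")
    for c in range(params.n_chromosomes):
        chrom = f"chr{c + 1}"
        occupied = planted_by_chrom.get(chrom, [])
        for i in range(params.genes_per_chromosome):
            start = i * spacing + spacing // 4 + 1
            end = start + gene_len - 1
            if any(s <= end and start <= e for s, e in occupied):
                continue  # keep intervals non-overlapping
            genes.append(GeneModel(f"BG_{chrom}_{i:03d}", chrom, start, end, "+"))

    universe = [g.gene_id for g in genes]
    planted_genes = sorted(truth.relevant_genes)
    background_pool = [g for g in universe if g not in truth.relevant_genes]

    sets: dict[str, frozenset[str]] = {}
    lo, hi = params.set_size_range
    relevant_names = []
    for j in range(params.n_relevant_sets):
        size = int(rng.integers(lo, hi + 1))
        n_pl = max(1, round(params.relevant_planted_fraction * size))
        n_pl = min(n_pl, len(planted_genes), size)
        members = list(rng.choice(planted_genes, size=n_pl, replace=False))
        members += list(rng.choice(background_pool, size=size - n_pl, replace=False))
        name = f"SET_R{j + 1:02d}"
        sets[name] = frozenset(members)
        relevant_names.append(name)
    for j in range(params.n_sets - params.n_relevant_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"SET_B{j + 1:02d}"] = frozenset(
            rng.choice(universe, size=size, replace=False)
        )

    vote_rows = []
    for name in sets:
        if name in relevant_names:
            v = int(rng.integers(2, 5))
        elif rng.random() < params.distractor_vote_fraction:
            v = 1
        else:
            v = 0
        flags = np.zeros(4, dtype=int)
        flags[rng.choice(4, size=v, replace=False)] = 1
        vote_rows.append({"trait": name, "rater1": flags[0], "rater2": flags[1],
                          "rater3": flags[2], "rater4": flags[3]})
    votes = pd.DataFrame(vote_rows)

    db = GeneSetDB(source="synthetic", sets=sets,
                   universe=frozenset(universe))
    truth_full = TruthTable(
        planted=truth.planted,
        relevant_genes=truth.relevant_genes,
        relevant_sets=frozenset(relevant_names),
    )
    return AnnotationBundle(genes=genes, gene_sets=db, votes=votes,
                            truth=truth_full)


def write_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (0-based half-open), genome-sorted."""
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start))
    with open(path, "w") as fh:
        for g in ordered:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


@dataclass
class Fixture:
    """All file paths plus in-memory truth for one simulated study."""

    params: SimulationParams
    vcf: Path
    popmap: Path
    bed: Path
    gmt: Path
    votes_tsv: Path
    truth: TruthTable
    freqs: pd.DataFrame
    genotypes: dict[str, np.ndarray]


def simulate_fixture(
    params: SimulationParams,
    out_dir: str | Path,
    _freqs: pd.DataFrame | None = None,
) -> Fixture:
    """Run the full generator and persist every artefact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    freqs = _freqs if _freqs is not None else simulate_three_pop_freqs(params)
    freqs, truth = plant_differentiated_loci(freqs, params.planted, params)
    sim = simulate_genotypes(freqs, params, out / "genotypes.vcf", out / "popmap.tsv")
    bundle = generate_annotation_and_sets(params, freqs, truth)
    write_bed(bundle.genes, out / "genes.bed")
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    bundle.votes.to_csv(out / "trait_votes.tsv", sep="\t", index=False)
    return Fixture(
        params=params,
        vcf=sim.vcf_path,
        popmap=sim.popmap_path,
        bed=out / "genes.bed",
        gmt=out / "gene_sets.gmt",
        votes_tsv=out / "trait_votes.tsv",
        truth=bundle.truth,
        freqs=freqs,
        genotypes=sim.genotypes,
    )


def default_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_planted: int = 10,
    shift: float = 0.5,
    target: str = "FOC",
) -> Fixture:
    """The desk-scale study: 3 chromosomes x 2,000 SNPs, 5 populations,
    ``n_planted`` loci shifted by ``shift`` in the focal population.

    Planted SNPs are chosen after the drift draw (see
    :func:`choose_planted_loci`) so that every planted effect size is
    exactly ``shift``, never truncated by clipping.
    """
    base = SimulationParams(seed=seed)
    freqs = simulate_three_pop_freqs(base)
    planted = choose_planted_loci(freqs, base, n=n_planted, shift=shift,
                                  target=target)
    params = replace(base, planted=planted)
    return simulate_fixture(params, out_dir, _freqs=freqs)
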