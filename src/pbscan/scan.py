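"""Per-SNP population differentiation and windowed PBSn1 scans.

The scan places three populations — a *focal* population and two
references, one closely and one distantly related — on a three-taxon
tree.  Pairwise FST between populations is transformed into additive
branch lengths ``T = -log(1 - FST)``; the Population Branch Statistic
(PBS) of the focal population is the length of its private branch,

    PBS_focal = (T_fc + T_fd - T_cd) / 2,

and its normalised form

    PBSn1 = PBS_focal / (1 + PBS_focal + PBS_close + PBS_distant)

bounds extreme values to [0, 1).  PBSn1 is computed per SNP and then
averaged over sliding windows of a fixed number of SNPs; the windows
with the highest mean PBSn1 are retained as candidate regions of
population-specific differentiation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io import PopAlleleCounts

logger = logging.getLogger(__name__)

# FST is capped just below 1 so that -log(1-FST) stays finite.
_FST_CAP = 1.0 - 1e-8


@dataclass(frozen=True)
class ComparisonSpec:
    """A focal / close / distant population triple.

    ``name`` defaults to the conventional shorthand
    ``"<focal> x <close>; <distant>"``.
    """

    focal: str
    close: str
    distant: str
    name: str = ""

    def __post_init__(self) -> None:
        labels = {self.focal, self.close, self.distant}
        if len(labels) != 3:
            raise ValueError(
                f"comparison requires three distinct populations, got "
                f"({self.focal}, {self.close}, {self.distant})"
            )
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.focal} x {self.close}; {self.distant}"
            )


def hudson_fst(
    alt1: np.ndarray,
    total1: np.ndarray,
    alt2: np.ndarray,
    total2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson's per-SNP FST estimator from allele counts.

    With sample allele frequencies ``p_i = alt_i / total_i`` and allele
    sample sizes ``n_i = total_i``:

        numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        denominator = p1(1-p2) + p2(1-p1)

    Returns ``(fst, defined)`` where ``fst`` is the unclamped estimate
    (may be negative) and ``defined`` marks SNPs where the estimator is
    usable: both totals >= 2 and a non-zero denominator.  Undefined
    entries hold NaN.
    """
    alt1 = np.asarray(alt1, dtype=float)
    alt2 = np.asarray(alt2, dtype=float)
    n1 = np.asarray(total1, dtype=float)
    n2 = np.asarray(total2, dtype=float)

    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(usable, alt1 / np.where(n1 > 0, n1, np.nan), np.nan)
        p2 = np.where(usable, alt2 / np.where(n2 > 0, n2, np.nan), np.nan)
        # corrections subtracted as a single sum so the estimator is
        # bitwise symmetric under exchange of the two populations
        num = (p1 - p2) ** 2 - (
            p1 * (1.0 - p1) / (n1 - 1.0) + p2 * (1.0 - p2) / (n2 - 1.0)
        )
        den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
        fst = num / den
    defined = usable & np.isfinite(fst) & (den != 0)
    return np.where(defined, fst, np.nan), defined


def weir_cockerham_fst(
    alt1: np.ndarray,
    total1: np.ndarray,
    alt2: np.ndarray,
    total2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-population Weir–Cockerham FST from allele counts.

    Allele-frequency formulation (random union of gametes; no observed
    heterozygosity term), suitable when only population allele counts
    are available.  Same return convention as :func:`hudson_fst`.
    """
    a1 = np.asarray(alt1, dtype=float)
    a2 = np.asarray(alt2, dtype=float)
    n1 = np.asarray(total1, dtype=float)
    n2 = np.asarray(total2, dtype=float)
    usable = (n1 >= 2) & (n2 >= 2)

    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = a1 / np.where(n1 > 0, n1, np.nan)
        p2 = a2 / np.where(n2 > 0, n2, np.nan)
        nbar = (n1 + n2) / r
        nc = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        h = pbar * (1.0 - pbar)
        num = s2 - (h - s2 * (r - 1.0) / r) / (nbar - 1.0)
        den = (nc - 1.0) / (nbar - 1.0) * h + (
            1.0 + (r - 1.0) * (nbar - nc) / (nbar - 1.0)
        ) * s2 / r
        fst = num / den
    defined = usable & np.isfinite(fst) & (den != 0)
    return np.where(defined, fst, np.nan), defined


_ESTIMATORS = {"hudson": hudson_fst, "weir-cockerham": weir_cockerham_fst}


def branch_length(fst: np.ndarray | float) -> np.ndarray | float:
    """Branch length ``T = -log(1 - FST)``.

    FST is clamped to [0, 1 - 1e-8] first, so T is always finite and
    non-negative; negative FST estimates map to T = 0.
    """
    clamped = np.clip(fst, 0.0, _FST_CAP)
    out = -np.log1p(-clamped)
    if np.isscalar(fst):
        return float(out)
    return out


def pbs(
    t_fc: np.ndarray | float,
    t_fd: np.ndarray | float,
    t_cd: np.ndarray | float,
    clamp: bool = True,
) -> tuple:
    """Population branch statistics for focal, close and distant.

    PBS_focal  = (T_fc + T_fd - T_cd) / 2
    PBS_close  = (T_fc + T_cd - T_fd) / 2
    PBS_distant= (T_fd + T_cd - T_fc) / 2

    Negative values are clamped to 0 unless ``clamp=False``.
    """
    t_fc = np.asarray(t_fc, dtype=float)
    t_fd = np.asarray(t_fd, dtype=float)
    t_cd = np.asarray(t_cd, dtype=float)
    p_f = (t_fc + t_fd - t_cd) / 2.0
    p_c = (t_fc + t_cd - t_fd) / 2.0
    p_d = (t_fd + t_cd - t_fc) / 2.0
    if clamp:
        p_f = np.maximum(p_f, 0.0)
        p_c = np.maximum(p_c, 0.0)
        p_d = np.maximum(p_d, 0.0)
    return p_f, p_c, p_d


def pbsn1(
    pbs_focal: np.ndarray | float,
    pbs_close: np.ndarray | float,
    pbs_distant: np.ndarray | float,
) -> np.ndarray | float:
    """Normalised PBS of the focal population, in [0, 1).

    PBSn1 = PBS_focal / (1 + PBS_focal + PBS_close + PBS_distant);
    expects clamped (non-negative) PBS values.
    """
    pbs_focal = np.asarray(pbs_focal, dtype=float)
    return pbs_focal / (1.0 + pbs_focal + pbs_close + pbs_distant)


def compute_pbs_table(
    counts: PopAlleleCounts,
    spec: ComparisonSpec,
    estimator: Literal["hudson", "weir-cockerham"] = "hudson",
) -> pd.DataFrame:
    """Per-SNP PBS table for one comparison.

    Columns: chrom, pos, id, fst_fc, fst_fd, fst_cd, pbs_focal,
    pbs_close, pbs_distant, pbsn1, defined.  ``defined`` is False where
    any pairwise FST is undefined (total < 2 or zero denominator);
    such SNPs carry NaN statistics and are excluded downstream.
    """
    for label in (spec.focal, spec.close, spec.distant):
        if label not in counts.populations:
            raise KeyError(f"population {label!r} not present in allele counts")
    est = _ESTIMATORS[estimator]

    alt = {p: counts.alt(p) for p in (spec.focal, spec.close, spec.distant)}
    tot = {p: counts.total(p) for p in (spec.focal, spec.close, spec.distant)}

    fst_fc, ok_fc = est(alt[spec.focal], tot[spec.focal], alt[spec.close], tot[spec.close])
    fst_fd, ok_fd = est(alt[spec.focal], tot[spec.focal], alt[spec.distant], tot[spec.distant])
    fst_cd, ok_cd = est(alt[spec.close], tot[spec.close], alt[spec.distant], tot[spec.distant])
    defined = ok_fc & ok_fd & ok_cd

    t_fc = branch_length(fst_fc)
    t_fd = branch_length(fst_fd)
    t_cd = branch_length(fst_cd)
    p_f, p_c, p_d = pbs(t_fc, t_fd, t_cd)
    norm = pbsn1(p_f, p_c, p_d)

    df = counts.snps[["chrom", "pos", "id"]].copy()
    df["fst_fc"] = fst_fc
    df["fst_fd"] = fst_fd
    df["fst_cd"] = fst_cd
    df["pbs_focal"] = np.where(defined, p_f, np.nan)
    df["pbs_close"] = np.where(defined, p_c, np.nan)
    df["pbs_distant"] = np.where(defined, p_d, np.nan)
    df["pbsn1"] = np.where(defined, norm, np.nan)
    df["defined"] = defined
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.info(
            "%s: %d of %d SNPs excluded (undefined FST)",
            spec.name, n_excluded, len(df),
        )
    return df


def window_scan(
    pbs_table: pd.DataFrame,
    size: int = 20,
    step: int = 5,
) -> pd.DataFrame:
    """Slide fixed-SNP windows over each chromosome and score them.

    ``pbs_table`` must hold chrom, pos, pbsn1 columns, sorted by
    (chromosome, position), with only defined-PBSn1 SNPs.  A chromosome
    with L SNPs yields ``floor((L - size) / step) + 1`` windows when
    L >= size, else none: trailing partial windows are dropped so every
    window covers exactly ``size`` SNPs.  The window score is the
    arithmetic mean of member PBSn1; the peak SNP is the member with the
    highest PBSn1 (ties broken toward the lowest position).
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed window size (windows must tile)")
    if pbs_table["pbsn1"].isna().any():
        raise ValueError("pbs_table contains undefined PBSn1; filter first")

    rows = []
    for chrom, grp in pbs_table.groupby("chrom", sort=False, observed=True):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
        vals = grp["pbsn1"].to_numpy()
        L = len(grp)
        if L < size:
            continue
        n_win = (L - size) // step + 1
        for w in range(n_win):
            i0 = w * step
            i1 = i0 + size  # exclusive
            window = vals[i0:i1]
            # sequential left-to-right sum: reproducible bit-for-bit by any
            # plain accumulation loop (unlike numpy's pairwise summation)
            total = 0.0
            for x in window:
                total += x
            peak = int(np.argmax(window))  # first max -> lowest position
            rows.append(
                {
                    "chrom": chrom,
                    "start_idx": i0,
                    "end_idx": i1 - 1,
                    "start_pos": int(pos[i0]),
                    "end_pos": int(pos[i1 - 1]),
                    "n_snps": size,
                    "mean_pbsn1": float(total / size),
                    "peak_idx": i0 + peak,
                    "peak_pos": int(pos[i0 + peak]),
                    "peak_pbsn1": float(window[peak]),
                }
            )
    columns = [
        "chrom", "start_idx", "end_idx", "start_pos", "end_pos",
        "n_snps", "mean_pbsn1", "peak_idx", "peak_pos", "peak_pbsn1",
    ]
    return pd.DataFrame(rows, columns=columns)


def select_top_windows(windows: pd.DataFrame, fraction: float = 0.001) -> pd.DataFrame:
    """Retain the highest-scoring fraction of windows.

    ``k = ceil(fraction * W)`` windows with the highest mean PBSn1 are
    kept; ties at the cutoff are broken by (chromosome, start position)
    ascending, so the result is deterministic and invariant to input
    permutation.  Output is in genome order.
    """
    if windows.empty:
        raise ValueError("no windows to select from")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    k = math.ceil(fraction * len(windows))
    chrom_codes = pd.Categorical(
        windows["chrom"], categories=sorted(windows["chrom"].astype(str).unique())
    ).codes
    start = windows["start_pos"].to_numpy()
    # lexsort: primary key last -> highest score first, ties in genome order
    order = np.lexsort((start, chrom_codes, -windows["mean_pbsn1"].to_numpy()))
    keep = order[:k]
    keep = keep[np.lexsort((start[keep], chrom_codes[keep]))]
    return windows.iloc[keep].reset_index(drop=True)


@dataclass
class ScanResult:
    """Output of one focal/close/distant comparison."""

    spec: ComparisonSpec
    pbs_table: pd.DataFrame
    windows: pd.DataFrame       # all windows, with 'retained' flag
    retained: pd.DataFrame      # retained subset
    n_snps_input: int = 0
    n_snps_used: int = 0
    log: dict = field(default_factory=dict)


def run_comparison(
    counts: PopAlleleCounts,
    spec: ComparisonSpec,
    size: int = 20,
    step: int = 5,
    fraction: float = 0.001,
    estimator: Literal["hudson", "weir-cockerham"] = "hudson",
) -> ScanResult:
    """Full scan for one comparison: FST → PBSn1 → windows → top windows.

    SNPs with any undefined pairwise FST among the three populations are
    excluded before windowing; exclusion counts are logged and reported
    in the result.
    """
    table = compute_pbs_table(counts, spec, estimator=estimator)
    usable = table[table["defined"]].reset_index(drop=True)
    windows = window_scan(usable, size=size, step=step)
    if windows.empty:
        retained = windows.copy()
        windows = windows.assign(retained=pd.Series(dtype=bool))
    else:
        retained = select_top_windows(windows, fraction=fraction)
        key = set(zip(retained["chrom"], retained["start_pos"]))
        windows = windows.assign(
            retained=[
                (c, s) in key
                for c, s in zip(windows["chrom"], windows["start_pos"])
            ]
        )
    log = {
        "comparison": spec.name,
        "n_snps_input": int(len(table)),
        "n_snps_excluded": int((~table["defined"]).sum()),
        "n_snps_used": int(len(usable)),
        "n_windows": int(len(windows)),
        "n_retained": int(len(retained)),
    }
    logger.info("scan %s: %s", spec.name, log)
    return ScanResult(
        spec=spec,
        pbs_table=table,
        windows=windows,
        retained=retained,
        n_snps_input=log["n_snps_input"],
        n_snps_used=log["n_snps_used"],
        log=log,
    )
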