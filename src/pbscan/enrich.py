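"""Hypergeometric gene-set over-representation with per-source BH FDR.

A gene list of effective size n is tested against each set of a source
database: with K set members in the background universe of size N and
k genes shared between list and set, the enrichment P-value is the
exact hypergeometric upper tail P(X >= k).  Benjamini–Hochberg
adjustment uses the *total* number of sets in the source as the number
of tests m — sets filtered from reporting (overlap below
``min_overlap``) still count toward m, mirroring how per-source FDR is
applied when the database is fixed a priori.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetDB

logger = logging.getLogger(__name__)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with denominator ranks out of m.

    ``m`` defaults to the number of p-values; it may be larger (untested
    hypotheses of the same source counting toward the correction) but
    never smaller.  q_i >= p_i and q is capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    t = len(p)
    if m is None:
        m = t
    if m < t:
        raise ValueError(f"m={m} smaller than number of tested p-values ({t})")
    if t == 0:
        return np.array([])
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, t + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(t)
    q[order] = q_sorted
    return q


@dataclass
class EnrichmentResult:
    """Full per-set table plus the q < alpha significant subset."""

    table: pd.DataFrame
    significant: pd.DataFrame
    n_effective: int      # genes from the list found in the background
    m: int                # BH denominator: total sets in the source


_COLUMNS = ["source", "set", "k", "n", "K", "N", "p", "q", "genes"]


def enrich_gene_list(
    genes: Iterable[str],
    db: GeneSetDB,
    background: Iterable[str] | None = None,
    min_overlap: int = 2,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Over-representation of a gene list in every set of a database.

    n = |genes ∩ background|, K = |set ∩ background|, k = |genes ∩ set|.
    Sets with k < ``min_overlap`` are excluded from the report but still
    count toward the BH denominator m (the source's total set count).
    """
    if not db.sets:
        raise ValueError("empty gene-set database")
    bg = frozenset(background) if background is not None else db.universe
    gene_set = frozenset(genes) & bg
    n = len(gene_set)
    N = len(bg)
    m = db.n_sets
    if n == 0:
        logger.warning("gene list has no members in the background universe")
        empty = pd.DataFrame(columns=_COLUMNS)
        return EnrichmentResult(table=empty, significant=empty.copy(),
                                n_effective=0, m=m)

    rows = []
    for name, members in db.sets.items():
        eff = frozenset(members) & bg
        overlap = gene_set & eff
        k = len(overlap)
        if k < min_overlap:
            continue
        p = hypergeom_test(k, n, len(eff), N)
        rows.append({
            "source": db.source, "set": name, "k": k, "n": n,
            "K": len(eff), "N": N, "p": p,
            "genes": ";".join(sorted(overlap)),
        })
    table = pd.DataFrame(rows, columns=[c for c in _COLUMNS if c != "q"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy(), m=m)
    else:
        table["q"] = pd.Series(dtype=float)
    table = table[_COLUMNS].sort_values(["p", "set"], kind="stable").reset_index(drop=True)
    significant = table[table["q"] < alpha].reset_index(drop=True)
    return EnrichmentResult(table=table, significant=significant,
                            n_effective=n, m=m)
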