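"""Trait-level meta-tests: are endurance-relevant traits over-represented?

Two 2x2 constructions are used.  Population-versus-universe: among all
traits of a source (the universe, e.g. every GWAS-catalog gene-set),
cross-classify by "enriched in this population" and "curated as
relevant".  Population-pair: over the curated relevant-trait universe
alone, cross-classify detection by the two populations.  Both are
tested with a one-tailed Fisher exact test (alternative: greater on
cell a) and the odds ratio is reported as the conditional maximum-
likelihood estimate given the margins — the estimate R's fisher.test
prints — with the sample cross-product ratio ad/bc alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows = (group 1, group 2), columns = (detected/relevant, not)."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("relevant", "not relevant")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class MetaResult:
    """One-tailed Fisher result on a 2x2 table."""

    table: ContingencyTable
    p_value: float
    odds_ratio: float            # conditional MLE given margins
    sample_odds_ratio: float     # cross-product ad/bc (inf if bc == 0)
    matched_traits: tuple[str, ...] = field(default_factory=tuple)
    degenerate: bool = False


def select_relevant_traits(vote_table: pd.DataFrame, min_votes: int = 2) -> set[str]:
    """Traits flagged by at least ``min_votes`` of the four raters.

    ``min_votes=2`` gives the primary curated list, ``3`` the stricter
    alternative used in sensitivity analyses.
    """
    if not vote_table["votes"].between(0, 4).all():
        raise ValueError("votes must lie in 0..4")
    sel = vote_table.loc[vote_table["votes"] >= min_votes, "trait"]
    return set(sel.astype(str).str.strip())


def _norm(names: Iterable[str]) -> set[str]:
    return {" ".join(str(t).split()) for t in names}


def population_vs_universe_table(
    enriched_traits: Iterable[str],
    relevant_traits: Iterable[str],
    universe_size: int,
) -> ContingencyTable:
    """Cross-classify the trait universe by enrichment and curated relevance.

    a = enriched & relevant, b = enriched only, c = relevant only,
    d = the remainder of the universe.  Trait names are matched by
    exact string equality after whitespace normalisation.
    """
    enriched = _norm(enriched_traits)
    relevant = _norm(relevant_traits)
    a = len(enriched & relevant)
    b = len(enriched - relevant)
    c = len(relevant - enriched)
    d = universe_size - a - b - c
    if d < 0:
        raise ValueError("universe smaller than the union of trait lists")
    return ContingencyTable(a, b, c, d,
                            row_labels=("enriched", "not enriched"),
                            col_labels=("relevant", "not relevant"))


def population_pair_table(
    matches_1: int, matches_2: int, n_relevant: int
) -> ContingencyTable:
    """Detection of relevant traits by two populations over the curated list.

    Rows are populations, columns are (detected, not detected) among the
    ``n_relevant`` curated traits.
    """
    if matches_1 > n_relevant or matches_2 > n_relevant:
        raise ValueError("matches exceed the relevant-trait universe")
    if min(matches_1, matches_2) < 0:
        raise ValueError("negative match count")
    return ContingencyTable(matches_1, n_relevant - matches_1,
                            matches_2, n_relevant - matches_2,
                            row_labels=("population 1", "population 2"),
                            col_labels=("detected", "not detected"))


def fisher_one_tailed(
    table: ContingencyTable,
    matched_traits: Iterable[str] = (),
) -> MetaResult:
    """One-tailed Fisher exact test (alternative: greater on cell a).

    The odds ratio is the conditional MLE given all margins (the root of
    the noncentral-hypergeometric mean equation); the sample
    cross-product ratio is reported alongside.  Degenerate margins
    (a + b == 0 or a + c == 0) give P = 1 with the OR flagged NaN.
    """
    arr = table.as_array()
    if table.a + table.b == 0 or table.a + table.c == 0:
        return MetaResult(table=table, p_value=1.0,
                          odds_ratio=float("nan"),
                          sample_odds_ratio=float("nan"),
                          matched_traits=tuple(sorted(matched_traits)),
                          degenerate=True)
    p = float(fisher_exact(arr, alternative="greater")[1])
    or_cmle = float(_odds_ratio(arr, kind="conditional").statistic)
    bc = table.b * table.c
    or_sample = (table.a * table.d / bc) if bc > 0 else float("inf")
    return MetaResult(table=table, p_value=p, odds_ratio=or_cmle,
                      sample_odds_ratio=or_sample,
                      matched_traits=tuple(sorted(matched_traits)))


def meta_test(
    enriched_traits: Iterable[str],
    relevant_traits: Iterable[str],
    universe_size: int,
) -> MetaResult:
    """Population-versus-universe meta-test with matched trait names."""
    enriched = _norm(enriched_traits)
    relevant = _norm(relevant_traits)
    table = population_vs_universe_table(enriched, relevant, universe_size)
    return fisher_one_tailed(table, matched_traits=enriched & relevant)
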