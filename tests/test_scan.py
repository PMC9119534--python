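"""FST, branch lengths, PBS/PBSn1 and the sliding-window scan."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pbscan.io import PopAlleleCounts
from pbscan.scan import (
    ComparisonSpec,
    branch_length,
    compute_pbs_table,
    hudson_fst,
    pbs,
    pbsn1,
    run_comparison,
    select_top_windows,
    weir_cockerham_fst,
    window_scan,
)

nonneg = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


class TestHudsonFst:
    def test_no_differentiation_is_nonpositive(self):
        fst, ok = hudson_fst(np.array([30]), np.array([100]),
                             np.array([30]), np.array([100]))
        assert ok[0]
        p = 0.3
        assert fst[0] == pytest.approx(-2 * p * (1 - p) / 99 / (2 * p * (1 - p)))
        assert fst[0] <= 0

    def test_fixed_difference_is_one(self):
        fst, ok = hudson_fst(np.array([100]), np.array([100]),
                             np.array([0]), np.array([100]))
        assert ok[0] and fst[0] == pytest.approx(1.0)

    def test_direct_formula_evaluation(self):
        """80/100 vs 20/100: (0.36 - 2*0.16/99) / 0.68."""
        fst, _ = hudson_fst(np.array([80]), np.array([100]),
                            np.array([20]), np.array([100]))
        expected = (0.36 - 2 * 0.16 / 99) / 0.68
        assert fst[0] == pytest.approx(expected, rel=1e-12)
        assert fst[0] == pytest.approx(0.5247, abs=5e-5)

    def test_small_sample_flagged_unusable(self):
        fst, ok = hudson_fst(np.array([1, 5]), np.array([1, 10]),
                             np.array([0, 2]), np.array([4, 10]))
        assert not ok[0] and np.isnan(fst[0])
        assert ok[1]

    def test_monomorphic_site_undefined(self):
        fst, ok = hudson_fst(np.array([0]), np.array([10]),
                             np.array([0]), np.array([10]))
        assert not ok[0]


class TestWeirCockerham:
    def test_sanity_against_hudson_regimes(self):
        rng = np.random.default_rng(0)
        n = np.full(200, 200)
        alt1 = rng.integers(1, 199, 200)
        alt2 = rng.integers(1, 199, 200)
        wc, ok = weir_cockerham_fst(alt1, n, alt2, n)
        hu, ok2 = hudson_fst(alt1, n, alt2, n)
        assert ok.all() and ok2.all()
        # both estimators agree closely at equal, large sample sizes
        np.testing.assert_allclose(wc, hu, atol=0.02)

    def test_fixed_difference_near_one(self):
        wc, ok = weir_cockerham_fst(np.array([100]), np.array([100]),
                                    np.array([0]), np.array([100]))
        assert ok[0] and wc[0] == pytest.approx(1.0, abs=0.02)


class TestBranchLength:
    @pytest.mark.parametrize(
        "fst,expected",
        [(0.0, 0.0), (-0.02, 0.0), (0.5, math.log(2))],
    )
    def test_closed_form(self, fst, expected):
        assert branch_length(fst) == pytest.approx(expected, rel=1e-12)

    def test_cap_keeps_t_finite(self):
        assert np.isfinite(branch_length(1.0))
        assert np.isfinite(branch_length(2.0))


class TestPbs:
    def test_symmetric_tree(self):
        f, c, d = pbs(0.4, 0.4, 0.4)
        assert f == c == d == pytest.approx(0.2)

    def test_arithmetic(self):
        f, c, d = pbs(0.2, 0.3, 0.1)
        assert f == pytest.approx(0.2)
        assert c == pytest.approx(0.0)
        assert d == pytest.approx(0.1)

    @given(nonneg, nonneg, nonneg)
    @settings(deadline=None)
    def test_unclamped_sum_identity(self, tfc, tfd, tcd):
        f, c, d = pbs(tfc, tfd, tcd, clamp=False)
        assert float(f + c + d) == pytest.approx((tfc + tfd + tcd) / 2, rel=1e-9, abs=1e-12)

    @given(nonneg, nonneg, nonneg)
    @settings(deadline=None)
    def test_focal_symmetric_in_reference_swap(self, tfc, tfd, tcd):
        f1, _, _ = pbs(tfc, tfd, tcd)
        # swapping close and distant swaps t_fc/t_fd but keeps t_cd
        f2, _, _ = pbs(tfd, tfc, tcd)
        assert float(f1) == pytest.approx(float(f2), rel=1e-12, abs=0.0)


class TestPbsn1:
    @pytest.mark.parametrize(
        "f,c,d,expected",
        [(0.0, 0.0, 0.0, 0.0), (0.2, 0.1, 0.05, 0.2 / 1.35)],
    )
    def test_arithmetic(self, f, c, d, expected):
        assert pbsn1(f, c, d) == pytest.approx(expected, rel=1e-12)

    @given(nonneg, nonneg, nonneg)
    @settings(deadline=None)
    def test_bounded_below_one(self, f, c, d):
        v = float(pbsn1(f, c, d))
        assert 0.0 <= v < 1.0

    @given(nonneg, nonneg, st.floats(min_value=0.0, max_value=10.0))
    @settings(deadline=None)
    def test_monotone_in_focal_pbs(self, c, d, f):
        assert float(pbsn1(f + 0.1, c, d)) > float(pbsn1(f, c, d))


def make_pbsn1_table(values_by_chrom):
    rows = []
    for chrom, values in values_by_chrom.items():
        for i, v in enumerate(values):
            rows.append({"chrom": chrom, "pos": (i + 1) * 10, "pbsn1": v})
    return pd.DataFrame(rows)


class TestWindowScan:
    def test_window_count_formula(self):
        table = make_pbsn1_table({"chr1": np.linspace(0, 0.5, 104)})
        windows = window_scan(table, size=20, step=5)
        assert len(windows) == (104 - 20) // 5 + 1 == 17

    def test_constant_signal_gives_constant_means(self):
        table = make_pbsn1_table({"chr1": np.full(60, 0.25)})
        windows = window_scan(table)
        assert (windows["mean_pbsn1"] == 0.25).all()

    def test_short_chromosome_yields_no_windows(self):
        table = make_pbsn1_table({"chr1": np.full(19, 0.1)})
        assert window_scan(table).empty

    def test_windows_never_span_chromosomes(self):
        table = make_pbsn1_table({"chr1": np.full(25, 0.1), "chr2": np.full(25, 0.2)})
        windows = window_scan(table)
        assert len(windows) == 4
        assert set(windows["mean_pbsn1"].round(6)) == {0.1, 0.2}

    def test_means_match_brute_force_loop(self):
        """Window means equal an independent nested-loop recomputation,
        exact to floating-point equality, on a 10^3-SNP instance."""
        rng = np.random.default_rng(99)
        values = {"chr1": rng.random(600) * 0.3, "chr2": rng.random(400) * 0.3}
        table = make_pbsn1_table(values)
        windows = window_scan(table, size=20, step=5)
        expected = []
        for chrom in ("chr1", "chr2"):  # brute-force oracle
            v = values[chrom]
            start = 0
            while start + 20 <= len(v):
                total = 0.0
                for j in range(start, start + 20):
                    total += v[j]
                expected.append(total / 20)
                start += 5
        assert len(windows) == len(expected)
        assert list(windows["mean_pbsn1"]) == expected

    def test_peak_ties_resolve_to_lowest_position(self):
        v = np.zeros(20)
        v[3] = v[7] = 0.5
        windows = window_scan(make_pbsn1_table({"chr1": v}), size=20, step=5)
        assert windows.at[0, "peak_pos"] == 40  # index 3, positions are (i+1)*10

    @pytest.mark.parametrize("size,step", [(0, 5), (20, 0), (20, 21)])
    def test_invalid_geometry_rejected(self, size, step):
        table = make_pbsn1_table({"chr1": np.full(30, 0.1)})
        with pytest.raises(ValueError):
            window_scan(table, size=size, step=step)


class TestTopWindows:
    def make_windows(self, scores):
        return pd.DataFrame({
            "chrom": "chr1",
            "start_pos": np.arange(len(scores)) * 100 + 1,
            "mean_pbsn1": scores,
        })

    def test_ceil_count(self):
        windows = self.make_windows(np.linspace(0, 1, 2000))
        assert len(select_top_windows(windows, 0.001)) == 2

    def test_all_ties_keep_genome_order(self):
        windows = self.make_windows(np.full(100, 0.3))
        top = select_top_windows(windows, 0.05)
        assert list(top["start_pos"]) == [1, 101, 201, 301, 401]

    def test_permutation_invariant_and_matches_bruteforce_topk(self):
        rng = np.random.default_rng(3)
        scores = rng.choice([0.1, 0.2, 0.3], size=50)
        windows = self.make_windows(scores)
        top = select_top_windows(windows, 0.1)
        shuffled = windows.sample(frac=1, random_state=0).reset_index(drop=True)
        top_shuffled = select_top_windows(shuffled, 0.1)
        pd.testing.assert_frame_equal(top, top_shuffled)
        # brute force: sort by (-score, start) and take k
        k = math.ceil(0.1 * 50)
        expected = windows.sort_values(
            ["mean_pbsn1", "start_pos"], ascending=[False, True], kind="stable"
        ).head(k).sort_values("start_pos")
        assert set(top["start_pos"]) == set(expected["start_pos"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_top_windows(pd.DataFrame(columns=["chrom", "start_pos", "mean_pbsn1"]))


def counts_from_freqs(freq_by_pop, n_alleles=200):
    """Population-level allele counts at a fixed total, for deterministic tests."""
    n_snps = len(next(iter(freq_by_pop.values())))
    snps = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n_snps + 1) * 10,
        "id": [f"s{i}" for i in range(n_snps)],
    })
    alt = pd.DataFrame({p: np.round(np.asarray(f) * n_alleles).astype(int)
                        for p, f in freq_by_pop.items()})
    tot = pd.DataFrame({p: np.full(n_snps, n_alleles) for p in freq_by_pop})
    return PopAlleleCounts(snps=snps, alt_counts=alt, total_counts=tot)


class TestRunComparison:
    def test_planted_locus_window_ranks_first(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(0.3, 0.7, 300)
        jitter = lambda: np.clip(base + rng.normal(0, 0.02, 300), 0.01, 0.99)
        freqs = {"F": jitter(), "C": jitter(), "D": jitter()}
        freqs["F"][150] = np.clip(base[150] + 0.6, 0, 1)  # one strong locus
        counts = counts_from_freqs(freqs)
        res = run_comparison(counts, ComparisonSpec("F", "C", "D"), fraction=0.01)
        best = res.windows.loc[res.windows["mean_pbsn1"].idxmax()]
        assert best["start_idx"] <= 150 <= best["end_idx"]
        assert bool(best["retained"])

    def test_identical_focal_and_close_gives_zero_pbsn1(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0.2, 0.8, 120)
        d = rng.uniform(0.2, 0.8, 120)
        counts = counts_from_freqs({"F": f, "C": f.copy(), "D": d})
        res = run_comparison(counts, ComparisonSpec("F", "C", "D"), fraction=0.05)
        used = res.pbs_table[res.pbs_table["defined"]]
        np.testing.assert_allclose(used["pbsn1"], 0.0, atol=1e-12)
        assert (res.retained["mean_pbsn1"] <= 1e-12).all()

    def test_reference_swap_leaves_focal_pbs_unchanged(self):
        rng = np.random.default_rng(5)
        freqs = {p: rng.uniform(0.1, 0.9, 100) for p in ("F", "C", "D")}
        counts = counts_from_freqs(freqs)
        t1 = compute_pbs_table(counts, ComparisonSpec("F", "C", "D"))
        t2 = compute_pbs_table(counts, ComparisonSpec("F", "D", "C"))
        np.testing.assert_array_equal(
            t1["pbs_focal"].to_numpy(), t2["pbs_focal"].to_numpy()
        )

    def test_missing_population_errors(self):
        counts = counts_from_freqs({"F": np.full(30, 0.5), "C": np.full(30, 0.4),
                                    "D": np.full(30, 0.3)})
        with pytest.raises(KeyError):
            run_comparison(counts, ComparisonSpec("F", "C", "MISSING"))
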