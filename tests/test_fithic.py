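import numpy as np
import pandas as pd
import pytest

from hicsig import synth
from hicsig.core_data import GenomicBin, canonicalize
from hicsig.fithic import (
    DistanceFunction,
    bin_statistics,
    enumerate_possible_pairs,
    equal_occupancy_binning,
    fit_distance_function,
    naive_pvalue,
    refine,
    run_fithic,
    spline_pvalues,
)
from hicsig.multitest import binom_sf
from .conftest import bin_at


def decay_map(n_bins=60, binsize=1000, N=20_000, loops=None, seed=5):
    bins = synth.make_bins({"chr1": n_bins * binsize}, binsize)
    return synth.simulate_decay(
        bins, N, loops=loops, seed=seed, dist_low=2 * binsize
    ), bins


class TestEnumeratePossiblePairs:
    def test_four_bins_hand_enumeration(self):
        s = 1000
        # distances: s (3 pairs), 2s (2 pairs), 3s (1 pair) -> M = 6
        full = canonicalize(
            [
                (GenomicBin("chr1", i * s, (i + 1) * s),
                 GenomicBin("chr1", j * s, (j + 1) * s), 1)
                for i in range(4) for j in range(i + 1, 4)
            ],
            resolution=s,
        )
        universe = enumerate_possible_pairs(full, s, 3 * s)
        assert len(universe) == 6

    def test_m_invariant_to_counts(self):
        cmap1, _ = decay_map(seed=1)
        cmap2, _ = decay_map(seed=2)
        u1 = enumerate_possible_pairs(cmap1, 2000)
        u2 = enumerate_possible_pairs(cmap2, 2000)
        # same bin universe, different counts: same M
        assert len(u1) == len(u2)
        assert not np.array_equal(u1["count"], u2["count"])

    def test_zero_count_pairs_included(self):
        cmap, _ = decay_map(N=50)  # sparse: most pairs unobserved
        universe = enumerate_possible_pairs(cmap, 2000)
        assert (universe["count"] == 0).any()
        assert universe["count"].sum() <= 50

    def test_bad_range(self):
        cmap, _ = decay_map()
        with pytest.raises(ValueError, match="dist_low"):
            enumerate_possible_pairs(cmap, 5000, 1000)


class TestNaivePvalue:
    def test_zero_count(self):
        assert naive_pvalue(0, 100, 4) == 1.0

    def test_closed_form(self):
        assert naive_pvalue(1, 1, 4) == pytest.approx(0.25)

    def test_matches_binom_sf_grid(self):
        for k in range(0, 6):
            for N in (6, 20, 100):
                for M in (2, 10, 500):
                    assert naive_pvalue(k, N, M) == binom_sf(k, N, 1 / M)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            naive_pvalue(1, 10, 0)


def universe_from_counts(counts):
    """One pair per ascending distance with the given counts."""
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start1": 0,
            "end1": 1000,
            "start2": np.arange(len(counts)) * 1000 + 2000,
            "end2": np.arange(len(counts)) * 1000 + 3000,
            "distance": np.arange(len(counts)) * 1000 + 2000,
            "count": counts,
        }
    )


class TestEqualOccupancyBinning:
    def test_greedy_oracle_example(self):
        universe = universe_from_counts([5, 3, 2, 2, 2, 1, 1])
        assignment = equal_occupancy_binning(universe, 2)
        assert list(assignment) == [0, 0, 1, 1, 1, 1, 1]
        totals = universe.groupby(assignment)["count"].sum()
        assert list(totals) == [8, 8]

    def test_single_bin(self):
        universe = universe_from_counts([4, 1, 7])
        assert set(equal_occupancy_binning(universe, 1)) == {0}

    def test_b_reduced_with_warning(self):
        universe = universe_from_counts([2, 3])
        with pytest.warns(UserWarning, match="reduced"):
            assignment = equal_occupancy_binning(universe, 10)
        assert assignment.max() <= 1

    def test_overshoot_bounded_by_largest_group(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 40, 300)
        universe = universe_from_counts(counts)
        b = 12
        assignment = equal_occupancy_binning(universe, b)
        totals = universe.groupby(assignment)["count"].sum()
        target = counts.sum() / b
        largest = universe.groupby("distance")["count"].sum().max()
        # all bins except the last stop as soon as they reach the target
        assert (totals.iloc[:-1] <= target + largest).all()

    def test_ties_indivisible(self):
        universe = universe_from_counts([5, 3, 2, 2])
        universe.loc[1, "distance"] = universe.loc[0, "distance"]
        assignment = equal_occupancy_binning(universe, 2)
        assert assignment[0] == assignment[1]

    def test_pairs_occupancy_mode(self):
        universe = universe_from_counts([100, 1, 1, 1])
        assignment = equal_occupancy_binning(universe, 2, occupancy="pairs")
        totals = universe.groupby(assignment).size()
        assert list(totals) == [2, 2]


class TestBinStatistics:
    def test_zero_count_pairs_lower_the_mean(self):
        universe = universe_from_counts([4, 0])
        stats = bin_statistics(universe, np.zeros(2, dtype=int))
        assert stats["c"].iloc[0] == 2.0

    def test_single_pair_bin(self):
        universe = universe_from_counts([7])
        stats = bin_statistics(universe, np.zeros(1, dtype=int))
        N = universe["count"].sum()
        assert stats.iloc[0]["c"] == 7
        assert stats.iloc[0]["prior"] == 7 / N
        assert stats.iloc[0]["d"] == universe["distance"].iloc[0]

    def test_conservation(self):
        cmap, _ = decay_map(seed=8)
        universe = enumerate_possible_pairs(cmap, 2000)
        assignment = equal_occupancy_binning(universe, 10)
        stats = bin_statistics(universe, assignment)
        # sum over bins of n_pairs * c equals the in-range read total
        assert (stats["n_pairs"] * stats["c"]).sum() == pytest.approx(
            universe["count"].sum()
        )
        assert stats["n_pairs"].sum() == len(universe)


class TestFitDistanceFunction:
    def test_constant_priors_stay_flat(self):
        f = fit_distance_function([1000, 2000, 3000], [0.01, 0.01, 0.01])
        for d in (500, 1500, 9000):
            assert f(d) == pytest.approx(0.01)

    def test_two_points_interpolate(self):
        f = fit_distance_function([1000, 2000], [0.01, 0.001])
        assert f(1000) == pytest.approx(0.01)
        assert f(2000) == pytest.approx(0.001)
        mid = f(1500)
        assert 0.001 < mid < 0.01

    def test_constant_extrapolation(self):
        f = fit_distance_function([1000, 2000], [0.01, 0.001])
        assert f(5000) == pytest.approx(f(2000))
        assert f(10) == pytest.approx(f(1000))

    def test_non_increasing_everywhere(self):
        rng = np.random.default_rng(13)
        d = np.sort(rng.uniform(1000, 100_000, 40))
        priors = 1 / d + rng.normal(0, 1e-5, 40)
        f = fit_distance_function(d, np.clip(priors, 1e-8, 1))
        grid = np.linspace(500, 150_000, 500)
        values = f(grid)
        assert np.all(np.diff(values) <= 1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fit_distance_function([1000, np.nan], [0.1, 0.2])


class TestSplinePvalues:
    def test_zero_count_pair_pvalue_one(self):
        universe = universe_from_counts([0, 3])
        f = DistanceFunction.constant(0.01)
        pvals = spline_pvalues(universe, f, 100)
        assert pvals[0] == 1.0

    def test_flat_f_reproduces_naive(self):
        cmap, _ = decay_map(seed=14)
        universe = enumerate_possible_pairs(cmap, 2000)
        M = len(universe)
        N = int(universe["count"].sum())
        f = DistanceFunction.constant(1.0 / M)
        pvals = spline_pvalues(universe, f, N)
        naive = naive_pvalue(universe["count"].to_numpy().astype(int), N, M)
        assert np.array_equal(pvals, naive)

    def test_smaller_f_gives_smaller_pvalue_at_equal_count(self):
        universe = universe_from_counts([5, 5])
        f = DistanceFunction(np.array([2000.0, 3000.0]), np.array([0.01, 0.001]))
        pvals = spline_pvalues(universe, f, 1000)
        assert pvals[1] <= pvals[0]


class TestRefine:
    def test_nothing_excluded_keeps_f(self):
        cmap, _ = decay_map(seed=15)
        universe = enumerate_possible_pairs(cmap, 2000)
        N = int(universe["count"].sum())
        qvals = np.ones(len(universe))
        from hicsig.fithic import _fit_phase

        _, f1 = _fit_phase(universe, 20, N)
        _, f2, _ = refine(universe, qvals, 20, N)
        assert np.array_equal(f1.grid_d, f2.grid_d)
        assert np.array_equal(f1.grid_p, f2.grid_p)

    def test_all_excluded_errors(self):
        cmap, _ = decay_map(seed=16)
        universe = enumerate_possible_pairs(cmap, 2000)
        with pytest.raises(ValueError, match="excluded"):
            refine(universe, np.zeros(len(universe)), 20,
                   int(universe["count"].sum()))


class TestRunFithic:
    def test_trans_input_rejected(self):
        cmap = canonicalize(
            [(bin_at("chr1", 0), bin_at("chr2", 0), 5)], resolution=1000
        )
        with pytest.raises(ValueError, match="intra"):
            run_fithic(cmap)

    def test_empty_range_rejected(self):
        cmap = canonicalize(
            [(bin_at("chr1", 0), bin_at("chr1", 1000), 5)], resolution=1000
        )
        with pytest.raises(ValueError):
            run_fithic(cmap, dist_low=10_000, dist_high=20_000)

    def test_refinement_q_zero_equals_phase1(self):
        cmap, _ = decay_map(seed=17)
        r1 = run_fithic(cmap, b=20, refinement_q=0.0)
        r2 = run_fithic(cmap, b=20, two_phase=False)
        assert np.array_equal(r1.table["pvalue"], r2.table["pvalue"])
        assert r1.metadata["phase"] == 1

    def test_planted_loop_phase2_not_worse(self):
        binsize = 1000
        loops = [(("chr1", 10_000, "chr1", 20_000), 10.0)]
        cmap, _ = decay_map(n_bins=80, N=40_000, loops=loops, seed=18)
        phase1 = run_fithic(cmap, b=40, two_phase=False)
        phase2 = run_fithic(cmap, b=40)
        def loop_pval(res):
            t = res.table
            row = t[(t["start1"] == 10_000) & (t["start2"] == 20_000)]
            return row["pvalue"].iloc[0]
        assert loop_pval(phase2) <= loop_pval(phase1)
        t2 = phase2.table
        row = t2[(t2["start1"] == 10_000) & (t2["start2"] == 20_000)]
        assert row["significant"].iloc[0]

    def test_record_order_invariance(self):
        cmap, _ = decay_map(seed=19)
        shuffled = canonicalize(
            cmap.table.sample(frac=1, random_state=4), resolution=1000
        )
        r1 = run_fithic(cmap, b=20)
        r2 = run_fithic(shuffled, b=20)
        assert np.allclose(r1.table["pvalue"], r2.table["pvalue"])

    def test_null_calibration_single_seed(self):
        cmap, _ = decay_map(n_bins=100, N=50_000, seed=20)
        result = run_fithic(cmap, b=100)
        frac = result.n_significant / len(result)
        assert frac <= 0.05
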