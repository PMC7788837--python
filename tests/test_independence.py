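import numpy as np
import pytest

from mixindep import (
    GenotypeTable,
    MarkerModel,
    bin_support,
    chisq_statistic,
    critical_value,
    null_chisq_set,
    p_value,
    simulate_null_K,
    simulate_null_X,
    simulate_unlinked,
    test_independence as run_test,
)
from mixindep.distributions import DiscreteDistribution
from mixindep.sharing import ShareProbTable


def kdist(probs):
    return DiscreteDistribution("K", np.asarray(probs, dtype=float))


class TestBinning:
    def test_already_satisfied_support_unchanged(self):
        binning = bin_support(kdist([0.5, 0.5]), 100)
        assert binning.edges.tolist() == [0, 1]

    def test_tails_merged_inward(self):
        binning = bin_support(kdist([0.01, 0.49, 0.49, 0.01]), 100)
        assert binning.edges.tolist() == [0, 2]  # bins {0,1} and {2,3}
        assert binning.probs == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_every_bin_meets_the_minimum(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(rng.integers(3, 40)))
        n = int(rng.integers(30, 2000))
        try:
            binning = bin_support(kdist(p), n)
        except ValueError:
            return  # legitimately impossible for this draw
        assert (n * binning.probs >= 5 - 1e-9).all()
        assert binning.edges[0] == 0
        assert binning.probs.sum() == pytest.approx(1.0)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="no variation"):
            bin_support(kdist([0.0, 1.0, 0.0]), 1000)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bin_support(kdist([0.5, 0.5]), 9)


class TestChisqStatistic:
    def test_perfect_fit_is_zero(self):
        expected = kdist([0.25, 0.5, 0.25])
        binning = bin_support(expected, 400)
        assert chisq_statistic(np.array([100, 200, 100]), expected, binning) == 0.0

    def test_two_bin_example(self):
        expected = kdist([0.5, 0.5])
        binning = bin_support(expected, 100)
        assert chisq_statistic(np.array([60, 40]), expected, binning) == pytest.approx(4.0)

    def test_count_total_must_match_binning(self):
        expected = kdist([0.5, 0.5])
        binning = bin_support(expected, 100)
        with pytest.raises(ValueError, match="binning was built"):
            chisq_statistic(np.array([60, 41]), expected, binning)


class TestNullSimulation:
    def test_simulated_K_shape_and_totals(self):
        h = np.full(100, 0.4)
        sims = simulate_null_K(h, 2504, 500, seed=1)
        assert sims.shape == (500, 101)
        assert (sims.sum(axis=1) == 2504).all()

    def test_all_homozygous_panel_is_point_mass(self):
        sims = simulate_null_K(np.zeros(4), 50, 20, seed=2)
        assert (sims[:, 0] == 50).all() and (sims[:, 1:] == 0).all()

    def test_replicate_K_means_match_poisson_binomial(self):
        h = np.array([0.2, 0.5, 0.7, 0.9])
        sims = simulate_null_K(h, 1000, 400, seed=3)
        means = (sims * np.arange(5)).sum(axis=1) / 1000
        se = np.sqrt((h * (1 - h)).sum() / 1000)
        assert abs(means.mean() - h.sum()) < 3 * se / np.sqrt(400)

    def test_simulated_X_shape_and_certain_sharing(self):
        probs = ShareProbTable(["m1", "m2"], np.array([[0.0, 0.0, 1.0]] * 2), "expected")
        sims = simulate_null_X(probs, 30, 10, seed=4)
        assert sims.shape == (10, 5)
        assert (sims[:, 4] == 30).all()

    def test_replicate_X_means_match_expectation(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet(np.ones(3), size=6)
        probs = ShareProbTable([f"m{i}" for i in range(6)], p, "expected")
        sims = simulate_null_X(probs, 1252, 500, seed=6)
        mean_x = (sims * np.arange(13)).sum(axis=1).mean() / 1252
        expect = (p[:, 1] + 2 * p[:, 2]).sum()
        assert abs(mean_x - expect) < 0.05


class TestNullSet:
    def test_exact_replicates_give_zero_chisq(self):
        expected = kdist([0.25, 0.5, 0.25])
        binning = bin_support(expected, 400)
        sims = np.tile([100, 200, 100], (50, 1))
        null = null_chisq_set(sims, expected, binning)
        assert (null.values == 0).all()
        assert null.ecdf(0.0) == 1.0

    def test_null_mean_tracks_degrees_of_freedom(self):
        h = np.full(30, 0.5)
        from mixindep import expected_K_distribution

        expected = expected_K_distribution(h)
        binning = bin_support(expected, 5000)
        sims = simulate_null_K(h, 5000, 2000, seed=7)
        null = null_chisq_set(sims, expected, binning)
        df = binning.n_bins - 1
        assert abs(null.values.mean() - df) / df < 0.15

    def test_ecdf_monotone_between_zero_and_one(self):
        null = null_chisq_set(
            simulate_null_K(np.full(5, 0.5), 200, 300, seed=8),
            kdist(np.array([1, 5, 10, 10, 5, 1]) / 32),
            bin_support(kdist(np.array([1, 5, 10, 10, 5, 1]) / 32), 200),
        )
        grid = np.linspace(0, null.values.max() + 1, 50)
        vals = null.ecdf(grid)
        assert (np.diff(vals) >= 0).all()
        assert vals[0] >= 0 and vals[-1] == 1.0


class TestCriticalValueAndP:
    def test_order_statistic_example(self):
        values = np.arange(1.0, 101.0)
        assert critical_value(values, alpha=0.05) == 95.0

    def test_alpha_extremes(self):
        values = np.arange(1.0, 101.0)
        assert critical_value(values, alpha=0.999) == 1.0
        assert critical_value(values, alpha=0.001) == 100.0

    def test_p_value_and_decision_never_disagree(self):
        rng = np.random.default_rng(9)
        for B in (100, 250, 500):
            values = rng.chisquare(10, size=B)
            cv = critical_value(values, alpha=0.05)
            for obs in values:  # decisions evaluated on attainable values
                assert (p_value(values, obs) < 0.05) == (obs > cv)

    def test_add_one_p_value_never_zero(self):
        values = np.linspace(0, 1, 100)
        assert p_value(values, 100.0, add_one=True) == pytest.approx(1 / 101)


class TestEndToEnd:
    def test_same_seed_bit_identical(self):
        models = [MarkerModel("SNP", ["A", "T"], np.array([0.6, 0.4]))] * 12
        table = simulate_unlinked(list(models), 300, seed=10)
        r1 = run_test(table, "X", B=150, seed=42)
        r2 = run_test(table, "X", B=150, seed=42)
        assert r1.chisq == r2.chisq and r1.p == r2.p and r1.critical == r2.critical
        assert np.array_equal(r1.null.values, r2.null.values)

    def test_duplicated_markers_detected_as_dependent(self):
        one = [MarkerModel("STR", [str(i) for i in range(6)], np.full(6, 1 / 6))]
        base = simulate_unlinked(one, 500, seed=11)
        alleles = np.repeat(base.alleles, 10, axis=1)
        table = GenotypeTable(
            base.sample_ids,
            [f"m{j}" for j in range(10)],
            alleles,
            np.zeros((500, 10), dtype=bool),
        )
        result = run_test(table, "K", B=300, seed=12)
        assert result.reject and result.p < 0.01

    def test_result_reports_consistent_decision(self):
        models = [
            MarkerModel("STR", [str(i) for i in range(5)], np.full(5, 0.2))
            for _ in range(8)
        ]
        table = simulate_unlinked(models, 400, seed=13)
        for stat in ("K", "X"):
            res = run_test(table, stat, B=200, seed=14)
            assert res.reject == (res.p < res.alpha)
            assert 0 <= res.p <= 1
            assert res.to_dict()["n_bins"] == res.binning.n_bins

    def test_share_mode_observed_also_runs(self):
        models = [
            MarkerModel("SNP", ["C", "G"], np.array([0.5, 0.5])) for _ in range(10)
        ]
        table = simulate_unlinked(models, 400, seed=15)
        res = run_test(table, "X", B=200, share_mode="observed", seed=16)
        assert res.share_mode == "observed"
        assert 0 <= res.p <= 1
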