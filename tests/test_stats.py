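"""Random-phase null, peak tests, condition comparisons, behavioural tables."""

import numpy as np
import pytest
from scipy import stats as sst

from phrasetag import (
    BehavioralTable,
    InvalidInputError,
    NullDistribution,
    compare_conditions,
    fisher_exact_one_sided,
    pairwise_condition_tests,
    peak_significance,
    rayleigh_null_mean,
    round_p,
    simulate_null_itpc,
)


class TestNullDistribution:
    def test_range_and_ci_rank_convention(self, null_24_32):
        vals = null_24_32.values
        assert vals.shape == (5000,)
        assert np.all((vals >= 0) & (vals <= 1))
        lo, hi = null_24_32.confidence_interval(0.95)
        srt = np.sort(vals)
        assert lo == srt[249] and hi == srt[4749]  # 250th / 4750th entries

    def test_chunked_equals_batch(self):
        batch = simulate_null_itpc(K=24, n_electrodes=8, n_rep=500, seed=11)
        chunked = simulate_null_itpc(K=24, n_electrodes=8, n_rep=500, seed=11, chunk_size=77)
        assert np.array_equal(batch.values, chunked.values)
        assert np.array_equal(np.quantile(batch.values, [0.05, 0.5, 0.95]),
                              np.quantile(chunked.values, [0.05, 0.5, 0.95]))

    def test_mean_and_sd_match_independent_brute_force(self, null_24_32):
        # fresh-RNG brute force: 10^6 single-electrode ITPCs at K=24
        rng = np.random.default_rng(987654)
        th = rng.uniform(0, 2 * np.pi, size=(1_000_000, 24))
        single = np.abs(np.exp(1j * th).mean(axis=1))
        mu, sd = single.mean(), single.std()
        # electrode averages: mean unchanged, sd scaled by 1/sqrt(32)
        se_mean = sd / np.sqrt(32) / np.sqrt(null_24_32.n_rep)
        assert abs(null_24_32.mean() - mu) < 3 * se_mean + 3 * sd / np.sqrt(single.size)
        sd_rep = null_24_32.values.std(ddof=1)
        expected_sd = sd / np.sqrt(32)
        # MC standard error of a sample SD ~ sd / sqrt(2 n)
        se_sd = expected_sd / np.sqrt(2 * null_24_32.n_rep)
        assert abs(sd_rep - expected_sd) < 3 * se_sd + 3 * expected_sd / np.sqrt(2 * single.size)

    def test_parameter_validation(self):
        with pytest.raises(InvalidInputError):
            simulate_null_itpc(K=1)
        with pytest.raises(InvalidInputError):
            simulate_null_itpc(n_rep=50)


class TestPeakSignificance:
    def test_observed_far_above_null(self, null_24_32):
        obs = np.full(20, null_24_32.values.max() + 0.1)
        assert peak_significance(obs, null_24_32) < 1e-10

    def test_single_value_at_median(self, null_24_32):
        med = float(np.median(null_24_32.values))
        assert peak_significance([med], null_24_32) == pytest.approx(0.5, abs=0.02)

    def test_calibration_p_uniform_under_null(self, null_24_32):
        # observed groups drawn from the same generative process as the null
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            th = rng.uniform(0, 2 * np.pi, size=(20, 32, 24))
            obs = np.abs(np.exp(1j * th).mean(axis=-1)).mean(axis=-1)
            pvals.append(peak_significance(obs, null_24_32))
        assert sst.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_rejected(self, null_24_32):
        with pytest.raises(InvalidInputError):
            peak_significance([], null_24_32)


class TestCompareConditions:
    def test_hand_ranked_example(self):
        # groups {1,2} and {3,4}: ranks 1..4, H = 12/(4*5) * (2*1 + 2*1) = 2.4
        p = compare_conditions([[1.0, 2.0], [3.0, 4.0]])
        assert p == pytest.approx(float(sst.chi2.sf(2.4, df=1)))

    def test_label_permutation_invariant(self, rng):
        groups = [rng.normal(size=6) for _ in range(4)]
        assert compare_conditions(groups) == pytest.approx(
            compare_conditions(groups[::-1]), rel=1e-12
        )

    def test_calibration_under_exchangeability(self):
        rng = np.random.default_rng(21)
        pvals = [
            compare_conditions([rng.normal(size=10) for _ in range(4)]) for _ in range(200)
        ]
        assert sst.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_conditions([[1.0], [2.0, 3.0]])
        with pytest.raises(InvalidInputError):
            compare_conditions([[1.0, 1.0], [1.0, 1.0]])


class TestPairwiseWilcoxon:
    def test_all_positive_differences_n5(self):
        # exact one-sided p over the 2^5 sign assignments: 1/32
        vals = {"AN": np.array([2.0, 3, 4, 5, 6]), "AV": np.array([1.0, 2, 3, 4, 5])}
        p = pairwise_condition_tests(vals, [("AN", "AV", "greater")])[("AN", "AV")]
        assert p == pytest.approx(1 / 32)

    def test_antisymmetric_two_sided(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        a = pairwise_condition_tests({"x": x, "y": y}, [("x", "y", "two-sided")])[("x", "y")]
        b = pairwise_condition_tests({"x": y, "y": x}, [("x", "y", "two-sided")])[("x", "y")]
        assert a == pytest.approx(b)

    def test_one_sided_not_larger_than_two_sided(self, rng):
        x = rng.normal(size=10) + 0.5
        y = rng.normal(size=10)
        vals = {"x": x, "y": y}
        p1 = pairwise_condition_tests(vals, [("x", "y", "greater")])[("x", "y")]
        p2 = pairwise_condition_tests(vals, [("x", "y", "two-sided")])[("x", "y")]
        assert p1 <= p2 + 1e-12

    def test_all_zero_differences_undefined(self):
        vals = {"a": np.ones(5), "b": np.ones(5)}
        p = pairwise_condition_tests(vals, [("a", "b", "greater")])[("a", "b")]
        assert np.isnan(p)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[32, 1], [22, 6]], 0.031),   # phrase judgments: AN vs RR
            ([[32, 1], [24, 3]], 0.234),   # AN vs MP
            ([[24, 3], [22, 6]], 0.253),   # MP vs RR
        ],
    )
    def test_behavioural_tables_round_to_printed_values(self, table, expected):
        assert round_p(fisher_exact_one_sided(np.array(table))) == expected

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(1, 30, size=(2, 2))
            ours = fisher_exact_one_sided(t)
            ref = sst.fisher_exact(t, alternative="greater")[1]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_hypergeometric_support_sums_to_one(self):
        c = np.array([[32, 1], [22, 6]])
        M, n_success, n_draw = c.sum(), c[:, 0].sum(), c[0].sum()
        lo = max(0, n_draw - (M - n_success))
        hi = min(n_draw, n_success)
        total = sum(sst.hypergeom.pmf(k, M, n_success, n_draw) for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            BehavioralTable(np.array([[1, 2, 3], [4, 5, 6]]))
        with pytest.raises(InvalidInputError):
            fisher_exact_one_sided(np.array([[0, 0], [1, 2]]))
        with pytest.raises(InvalidInputError):
            BehavioralTable(np.array([[1.5, 2.0], [1.0, 2.0]]))


def test_round_p_half_up():
    assert round_p(0.2345) == 0.235
    assert round_p(0.0314) == 0.031
    assert round_p(0.0305) == 0.031


def test_rayleigh_null_mean_value():
    assert rayleigh_null_mean(24) == pytest.approx(0.1809, abs=5e-5)
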