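import math

import numpy as np
import pytest
from scipy import stats

import odorcode as oc
from odorcode.popstats import (
    activity_ratio,
    exact_binomial_test,
    session_significance_count,
    sparseness_index,
    spearman_permutation,
    two_proportion_ztest,
)
from odorcode.session import ODOUR_RESPONSE_WINDOW, RateMatrix


def binom_pmf(k, n, p):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


class TestSparsenessIndex:
    def test_worked_example(self):
        # A = (mean x)^2 / mean(x^2) = 1 / 2 ; SI = (1 - 1/2) / (1 - 1/4) = 2/3
        x = np.array([2.0, 2.0, 0.0, 0.0])
        assert activity_ratio(x) == pytest.approx(0.5)
        assert sparseness_index(x) == pytest.approx(2 / 3)

    def test_uniform_gives_zero(self):
        assert sparseness_index(np.full(10, 3.7)) == pytest.approx(0.0)

    def test_one_hot_gives_one(self):
        x = np.zeros(8)
        x[3] = 5.0
        assert sparseness_index(x) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.gamma(1.0, 2.0, size=int(rng.integers(2, 30)))
            c = float(rng.uniform(0.1, 50))
            assert sparseness_index(c * x) == pytest.approx(sparseness_index(x))

    def test_bounds_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.gamma(0.5, 1.0, size=int(rng.integers(2, 40)))
            if np.all(x == 0):
                continue
            si = sparseness_index(x)
            assert 0.0 <= si <= 1.0 + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            activity_ratio(np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            activity_ratio(np.zeros(4))
        with pytest.raises(ValueError):
            sparseness_index(np.array([1.0]))


def _rate_matrix(values, normalization="raw"):
    values = np.asarray(values, dtype=float)
    return RateMatrix(
        values=values,
        window=ODOUR_RESPONSE_WINDOW,
        normalization=normalization,
        neuron_ids=[f"n{i}" for i in range(values.shape[0])],
        trial_idxs=list(range(values.shape[1])),
    )


class TestPopulationSparseness:
    def test_per_stimulus_values(self):
        # two stimuli, two trials each; trial-averaged x per stimulus
        values = np.array(
            [[2.0, 2.0, 0.0, 0.0], [2.0, 2.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0], [0.0, 0.0, 1.0, 1.0]]
        )
        labels = np.array([1, 1, 2, 2])
        res = oc.population_sparseness(_rate_matrix(values), labels)
        # stimulus 1: x = (2,2,0,0) -> SI = 2/3 ; stimulus 2: x = (0,0,1,1) -> 2/3
        assert res.stimulus_ids == [1, 2]
        assert np.allclose(res.sparseness_indices, [2 / 3, 2 / 3])

    def test_control_excluded_by_default(self):
        values = np.ones((3, 4))
        labels = np.array([0, 0, 1, 1])
        res = oc.population_sparseness(_rate_matrix(values), labels)
        assert res.stimulus_ids == [1]

    def test_rejects_zscored_input(self):
        with pytest.raises(ValueError):
            oc.population_sparseness(
                _rate_matrix(np.ones((2, 2)), "zscored"), np.array([1, 1])
            )

    def test_pooled_single_session_equals_population(self, session1):
        session, _ = session1
        trials = session.odour_trials()
        rm = oc.compute_rate_matrix(
            session, trials, ODOUR_RESPONSE_WINDOW, "raw",
            neurons=session.neurons_in_region("AMY"),
        )
        labels = np.array([t.stimulus_id for t in trials])
        single = oc.population_sparseness(rm, labels, region="AMY")
        pooled = oc.pooled_sparseness([(rm, labels)], region="AMY")
        assert np.allclose(single.sparseness_indices, pooled.sparseness_indices)

    def test_compare_across_regions_smoke(self):
        rng = np.random.default_rng(0)
        results = []
        for region, lo in (("PC", 0.2), ("AMY", 0.5)):
            si = np.clip(rng.normal(lo, 0.05, 15), 0, 1)
            results.append(
                oc.SparsenessResult(
                    region=region,
                    stimulus_ids=list(range(1, 16)),
                    activity_ratios=1 - si,
                    sparseness_indices=si,
                    n_neurons=50,
                )
            )
        cmp = oc.compare_sparseness_across_regions(results)
        assert cmp.p < 0.01
        assert "PC" in cmp.tukey_summary and "AMY" in cmp.tukey_summary


class TestRepetitionSuppression:
    def test_exact_linear_profile_recovers_slope(self):
        # 2 neurons x 16 trials: z = a + b * cycle, two trials per cycle
        cycles = np.repeat(np.arange(1, 9), 2)
        b = np.array([-0.35, 0.6])
        values = 1.0 + b[:, None] * cycles[None, :]
        res = oc.repetition_suppression(_rate_matrix(values, "zscored"), cycles)
        assert np.allclose(res.slopes, b, atol=1e-12)

    def test_control_trials_excluded(self):
        cycles = np.concatenate([np.arange(1, 9), np.arange(1, 9)])
        labels = np.concatenate([np.full(8, 3), np.zeros(8, dtype=int)])
        values = np.vstack(
            [np.concatenate([-0.5 * np.arange(1, 9), 99.0 * np.ones(8)])] * 2
        )
        res = oc.repetition_suppression(_rate_matrix(values, "zscored"), cycles, labels)
        assert np.allclose(res.slopes, [-0.5, -0.5])

    def test_requires_all_cycles(self):
        cycles = np.repeat(np.arange(1, 8), 2)  # cycle 8 missing
        values = np.ones((2, cycles.size))
        with pytest.raises(ValueError):
            oc.repetition_suppression(_rate_matrix(values, "zscored"), cycles)


class TestValence:
    def test_contrast_and_reference_correlation(self):
        rng = np.random.default_rng(0)
        n_odours = 15
        labels = np.repeat(np.arange(1, n_odours + 1), 4)
        valence = np.linspace(-1, 1, n_odours)
        ratings = np.where(valence[labels - 1] > 0, "liked", "disliked")
        base = valence[labels - 1][None, :] * np.ones((6, 1))
        values = base + 0.05 * rng.normal(size=base.shape)
        res = oc.valence_analysis(
            _rate_matrix(values, "zscored"), labels, ratings,
            reference_valence=valence, n_perm=500, seed=1,
        )
        assert np.all(res.contrasts > 0)
        assert res.p < 0.05
        assert res.spearman_r > 0.9
        assert res.spearman_p < 0.05

    def test_reference_length_checked(self):
        labels = np.repeat([1, 2, 3], 2)
        ratings = np.array(["liked", "disliked"] * 3)
        with pytest.raises(ValueError):
            oc.valence_analysis(
                _rate_matrix(np.ones((2, 6)), "zscored"), labels, ratings,
                reference_valence=np.zeros(15),
            )


class TestSpearmanPermutation:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        r, p = spearman_permutation(x, x**3, n_perm=500, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 2 / 501 + 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_permutation(np.ones(5), np.arange(5.0))

    def test_matches_scipy_r(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 20))
        r, _ = spearman_permutation(x, y, n_perm=10, seed=0)
        assert r == pytest.approx(stats.spearmanr(x, y).statistic)


class TestExactBinomial:
    def test_right_tail_matches_pmf_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(1, 51))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.01, 0.99))
            want = sum(binom_pmf(j, n, p0) for j in range(k, n + 1))
            assert exact_binomial_test(k, n, p0, "right") == pytest.approx(want)

    def test_left_tail_matches_pmf_summation(self):
        for k, n, p0 in [(2, 20, 0.3), (0, 10, 0.5), (7, 7, 0.9)]:
            want = sum(binom_pmf(j, n, p0) for j in range(0, k + 1))
            assert exact_binomial_test(k, n, p0, "left") == pytest.approx(want)

    def test_two_sided_small_p_convention(self):
        # sum of P(X = j) over all j with P(X = j) <= P(X = k)
        for k, n, p0 in [(9, 12, 0.5), (1, 15, 0.2), (10, 30, 0.1)]:
            pk = binom_pmf(k, n, p0)
            want = sum(
                binom_pmf(j, n, p0)
                for j in range(n + 1)
                if binom_pmf(j, n, p0) <= pk * (1 + 1e-12)
            )
            assert exact_binomial_test(k, n, p0, "two") == pytest.approx(want)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exact_binomial_test(5, 4, 0.5)
        with pytest.raises(ValueError):
            exact_binomial_test(1, 4, 1.5)
        with pytest.raises(ValueError):
            exact_binomial_test(1, 4, 0.5, "sideways")


class TestTwoProportionZ:
    def test_antisymmetric_under_swap(self):
        a = two_proportion_ztest(30, 100, 10, 80)
        b = two_proportion_ztest(10, 80, 30, 100)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_equal_proportions_give_zero(self):
        res = two_proportion_ztest(10, 50, 20, 100)
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_degenerate_pooled_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(0, 10, 0, 10)


class TestSessionSignificanceCount:
    def test_count_and_binomial(self):
        pvals = np.array([0.01, 0.2, 0.04, 0.5, 0.049])
        k, p = session_significance_count(pvals, alpha=0.05, p_chance=0.05)
        assert k == 3
        assert p == pytest.approx(exact_binomial_test(3, 5, 0.05, "right"))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            session_significance_count(np.array([]))
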