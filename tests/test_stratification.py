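import numpy as np
import pytest

from survscreen import (
    PermutationConfig,
    SimulationSpec,
    SurvivalDataset,
    concordance_index,
    fit_cox,
    km_estimate,
    logrank_permutation_test,
    logrank_statistic,
    risk_score,
    simulate_dataset,
    step1_select,
    step2_select,
    stratify,
)
from survscreen.errors import (
    DegenerateStratificationError,
    UndefinedStatisticError,
)

from conftest import random_survival_dataset


class TestRiskScore:
    def test_linear_predictor_cases(self, rng):
        ds = random_survival_dataset(rng, n=10, p=2)
        assert np.all(risk_score(ds, (0, 1), [0.0, 0.0]) == 0)
        np.testing.assert_allclose(risk_score(ds, (1,), [1.0]),
                                   ds.expression[:, 1])
        np.testing.assert_allclose(
            risk_score(ds, (0, 1), [0.5, -1.0]),
            0.5 * ds.expression[:, 0] - ds.expression[:, 1],
        )

    def test_length_mismatch(self, rng):
        ds = random_survival_dataset(rng, n=5, p=2)
        with pytest.raises(ValueError):
            risk_score(ds, (0, 1), [1.0])


class TestStratify:
    def test_median_even_split(self):
        group, cutoff = stratify(np.array([1.0, 2.0, 3.0, 4.0]))
        assert cutoff == pytest.approx(2.5)
        np.testing.assert_array_equal(group, [0, 0, 1, 1])

    def test_constant_scores_degenerate(self):
        with pytest.raises(DegenerateStratificationError):
            stratify(np.ones(6))

    def test_median_split_is_balanced(self, rng):
        scores = rng.normal(size=50)  # distinct almost surely
        group, _ = stratify(scores)
        assert group.sum() == 25

    def test_quantile_and_fixed_rules(self, rng):
        scores = rng.normal(size=40)
        g, c = stratify(scores, "quantile:0.25")
        assert c == pytest.approx(np.quantile(scores, 0.25))
        g2, c2 = stratify(scores, ("value", 0.0))
        np.testing.assert_array_equal(g2, scores > 0.0)

    def test_ties_go_low(self):
        group, cutoff = stratify(np.array([1.0, 1.0, 2.0]), ("value", 1.0))
        np.testing.assert_array_equal(group, [0, 0, 1])


def hand_logrank(time, event, group):
    """Independent expansion of the observed-minus-expected table."""
    U = V = 0.0
    for ti in np.unique(time[event == 1]):
        at = time >= ti
        n, n1 = at.sum(), (at & (group == 1)).sum()
        d = ((time == ti) & (event == 1)).sum()
        d1 = ((time == ti) & (event == 1) & (group == 1)).sum()
        U += d1 - n1 * d / n
        if n > 1:
            V += n1 * (n - n1) * d * (n - d) / (n**2 * (n - 1))
    return U**2 / V


class TestLogRank:
    def test_group_swap_symmetry(self, rng):
        ds = random_survival_dataset(rng, n=30, p=1)
        g = (rng.uniform(size=30) > 0.5).astype(int)
        _, q1 = logrank_statistic(ds.time, ds.event, g)
        _, q2 = logrank_statistic(ds.time, ds.event, 1 - g)
        assert q1 == pytest.approx(q2)

    def test_hand_expanded_four_samples(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, int)
        group = np.array([1, 0, 1, 0])  # {1,3} vs {2,4}
        table, q = logrank_statistic(time, event, group)
        np.testing.assert_allclose(table.e1, [2 / 4, 1 / 3, 1 / 2, 0.0])
        assert q == pytest.approx(hand_logrank(time, event, group))

    def test_matches_hand_expansion_random(self, rng):
        for _ in range(10):
            ds = random_survival_dataset(rng, n=25, p=1)
            g = (rng.uniform(size=25) > 0.4).astype(int)
            if g.min() == g.max():
                continue
            _, q = logrank_statistic(ds.time, ds.event, g)
            assert q == pytest.approx(hand_logrank(ds.time, ds.event, g),
                                      abs=1e-10)

    def test_single_group_rejected(self, rng):
        ds = random_survival_dataset(rng, n=10, p=1)
        with pytest.raises(DegenerateStratificationError):
            logrank_statistic(ds.time, ds.event, np.ones(10, int))


class TestLogRankPermutation:
    def test_strong_separation_hits_floor(self):
        ds = simulate_dataset(SimulationSpec(n=200, seed=6))
        fit = fit_cox(ds, (0,))
        group, _ = stratify(risk_score(ds, (0,), fit.coefficients))
        p = logrank_permutation_test(ds.time, ds.event, group,
                                     PermutationConfig(99, seed=1))
        assert p == pytest.approx(1 / 100)

    def test_p_in_unit_interval_and_deterministic(self, rng):
        ds = random_survival_dataset(rng, n=40, p=1)
        g = (np.arange(40) % 2).astype(int)
        cfg = PermutationConfig(49, seed=5)
        p1 = logrank_permutation_test(ds.time, ds.event, g, cfg)
        p2 = logrank_permutation_test(ds.time, ds.event, g, cfg)
        assert 0 < p1 <= 1 and p1 == p2


class TestKaplanMeier:
    def test_all_censored_flat_one(self):
        km = km_estimate(np.array([1.0, 2.0]), np.array([0, 0]))
        assert km.times.size == 0
        assert km.survival_at(5.0) == 1.0

    def test_single_event_step_to_zero(self):
        km = km_estimate(np.array([5.0]), np.array([1]))
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(5.0) == 0.0

    def test_hand_product_limit_with_censoring(self):
        km = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.survival_at(2.5) == pytest.approx(2 / 3)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.uniform(0.1, 5, 30)
        km = km_estimate(t, np.ones(30, int))
        for q in (0.5, 1.0, 3.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())
        assert (np.diff(km.survival) <= 1e-12).all()


class TestConcordance:
    def test_perfect_and_tied(self, rng):
        t = np.sort(rng.uniform(1, 10, 12))
        e = np.ones(12, int)
        assert concordance_index(t, e, -t) == pytest.approx(1.0)
        assert concordance_index(t, e, np.zeros(12)) == pytest.approx(0.5)

    def test_brute_force_enumeration(self, rng):
        t = rng.uniform(0.5, 8, 8)
        e = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        s = rng.normal(size=8)
        num = den = 0.0
        for i in range(8):
            for j in range(8):
                if t[i] < t[j] and e[i] == 1:
                    den += 1
                    num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
        assert concordance_index(t, e, s) == pytest.approx(num / den)

    def test_antisymmetry(self, rng):
        ds = random_survival_dataset(rng, n=20, p=1)
        s = rng.normal(size=20)
        c = concordance_index(ds.time, ds.event, s)
        assert concordance_index(ds.time, ds.event, -s) == pytest.approx(1 - c)

    def test_no_permissible_pairs(self):
        with pytest.raises(UndefinedStatisticError):
            concordance_index(np.array([1.0, 1.0]), np.array([0, 0]),
                              np.array([0.1, 0.2]))


class TestStep2Select:
    def test_empty_step1_gives_empty_result(self, sim50):
        assert step2_select(sim50, [], alpha2=0.05) == []

    def test_zero_threshold_selects_nothing(self):
        ds = simulate_dataset(SimulationSpec(n=80, seed=9))
        s1 = step1_select(ds, 1, 0.05, PermutationConfig(49, seed=2))
        s2 = step2_select(ds, s1, alpha2=0.0,
                          config=PermutationConfig(49, seed=3))
        assert len(s2) == sum(r.selected for r in s1)
        assert not any(r.selected for r in s2)

    def test_strong_singleton_passes_both_steps(self):
        """The strongly prognostic feature survives the full pipeline with a
        balanced split, a large log-rank Q and a concordant risk score."""
        ds = simulate_dataset(SimulationSpec(n=150, seed=10))
        s1 = step1_select(ds, 1, 0.02, PermutationConfig(199, seed=2))
        s2 = step2_select(ds, s1, alpha2=0.02,
                          config=PermutationConfig(199, seed=3))
        by_idx = {r.tuple_indices: r for r in s2}
        strong = by_idx[(0,)]
        assert strong.selected and strong.perm_p == pytest.approx(1 / 200)
        assert strong.logrank_Q > 10
        assert strong.c_index > 0.6
        assert abs((strong.group == 1).sum() - 75) <= 1
        assert strong.km_high.survival_at(np.median(ds.time)) < \
            strong.km_low.survival_at(np.median(ds.time))
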