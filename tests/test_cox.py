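import numpy as np
import pytest

from survscreen import (
    SurvivalDataset,
    build_risk_sets,
    fit_cox,
    partial_log_likelihood,
    wald_statistics,
)
from survscreen.cox import SurvivalOrder, batch_newton
from survscreen._kernels import newton_many
from survscreen.errors import (
    DegenerateDataError,
    NonIdentifiableError,
    UnusableFitError,
)

from conftest import random_survival_dataset


def naive_breslow_loglik(ds, idx, beta):
    """Direct risk-set expansion of the Breslow partial likelihood."""
    beta = np.atleast_1d(beta)
    eta = ds.expression[:, list(idx)] @ beta
    ll = 0.0
    for ti in np.unique(ds.time[ds.event == 1]):
        deaths = (ds.time == ti) & (ds.event == 1)
        risk = ds.time >= ti
        ll += eta[deaths].sum() - deaths.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


class TestPartialLogLikelihood:
    def test_zero_beta_closed_form(self, tiny_dataset):
        rs = build_risk_sets(tiny_dataset)
        expected = -(rs.d * np.log(rs.sizes)).sum()
        assert partial_log_likelihood(tiny_dataset, (0,), [0.0]) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize("beta", [-2.0, 0.0, 3.5])
    def test_single_sample_is_zero(self, beta):
        ds = SurvivalDataset(np.array([[1.3]]), np.array([5.0]), np.array([1]))
        assert partial_log_likelihood(ds, (0,), [beta]) == pytest.approx(0.0)

    def test_hand_expanded_sum(self, tiny_dataset):
        got = partial_log_likelihood(tiny_dataset, (0,), [0.8])
        assert got == pytest.approx(
            naive_breslow_loglik(tiny_dataset, (0,), 0.8), abs=1e-12
        )

    def test_breslow_with_ties_matches_naive(self, rng):
        ds = SurvivalDataset(
            rng.normal(size=(12, 2)),
            rng.integers(1, 5, 12).astype(float),
            rng.integers(0, 2, 12) | np.r_[1, np.zeros(11, int)],
        )
        beta = np.array([0.4, -0.9])
        assert partial_log_likelihood(ds, (0, 1), beta) == pytest.approx(
            naive_breslow_loglik(ds, (0, 1), beta), abs=1e-10
        )

    def test_location_invariance(self, rng):
        ds = random_survival_dataset(rng, n=25, p=1)
        shifted = SurvivalDataset(ds.expression + 7.3, ds.time, ds.event)
        for b in (-1.0, 0.3):
            assert partial_log_likelihood(ds, (0,), [b]) == pytest.approx(
                partial_log_likelihood(shifted, (0,), [b]), abs=1e-8
            )


class TestFitCox:
    def test_constant_covariate_not_identifiable(self):
        ds = SurvivalDataset(np.ones((5, 1)), np.arange(1.0, 6.0), np.ones(5, int))
        with pytest.raises(NonIdentifiableError):
            fit_cox(ds, (0,))

    def test_zero_events_degenerate(self):
        ds = SurvivalDataset(np.random.default_rng(0).normal(size=(5, 1)),
                             np.arange(1.0, 6.0), np.zeros(5, int))
        with pytest.raises(DegenerateDataError):
            fit_cox(ds, (0,))

    def test_monotone_likelihood_flagged(self):
        ds = SurvivalDataset(np.array([[1.0], [0.0]]), np.array([1.0, 2.0]),
                             np.ones(2, int))
        fit = fit_cox(ds, (0,))
        assert fit.divergence_flag and not fit.converged

    def test_scale_equivariance(self, rng):
        ds = random_survival_dataset(rng, n=40, p=1)
        scaled = SurvivalDataset(ds.expression * 4.0, ds.time, ds.event)
        f1, f2 = fit_cox(ds, (0,)), fit_cox(scaled, (0,))
        assert f2.coefficients[0] == pytest.approx(f1.coefficients[0] / 4.0,
                                                   rel=1e-6)
        assert f2.wald_z[0] == pytest.approx(f1.wald_z[0], rel=1e-6)

    def test_score_vanishes_at_optimum(self, rng):
        ds = random_survival_dataset(rng, n=35, p=2)
        fit = fit_cox(ds, (0, 1))
        assert fit.converged
        h = 1e-6
        for j in range(2):
            up, dn = fit.coefficients.copy(), fit.coefficients.copy()
            up[j] += h
            dn[j] -= h
            deriv = (
                partial_log_likelihood(ds, (0, 1), up)
                - partial_log_likelihood(ds, (0, 1), dn)
            ) / (2 * h)
            assert abs(deriv) < 1e-4

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        for _ in range(5):
            ds = random_survival_dataset(rng, n=30, p=2)
            fit = fit_cox(ds, (0, 1))
            df = pd.DataFrame(ds.expression, columns=["a", "b"])
            df["t"], df["e"] = ds.time, ds.event
            ref = lifelines.CoxPHFitter().fit(
                df, "t", "e", fit_options={"precision": 1e-11}
            )
            np.testing.assert_allclose(fit.coefficients, ref.params_.to_numpy(),
                                       atol=1e-4)
            np.testing.assert_allclose(
                fit.wald_z,
                (ref.params_ / ref.standard_errors_).to_numpy(),
                atol=1e-3,
            )


class TestWaldStatistics:
    def test_definition(self, rng):
        ds = random_survival_dataset(rng, n=30, p=1)
        fit = fit_cox(ds, (0,))
        np.testing.assert_allclose(
            wald_statistics(fit), fit.coefficients / fit.std_errors
        )

    def test_nonconverged_fit_unusable(self):
        ds = SurvivalDataset(np.array([[1.0], [0.0]]), np.array([1.0, 2.0]),
                             np.ones(2, int))
        with pytest.raises(UnusableFitError):
            wald_statistics(fit_cox(ds, (0,)))


class TestBatchEngines:
    def test_batch_and_kernel_match_single_fits(self, rng):
        """The vectorised and compiled engines agree with fit_cox on
        explicitly permuted datasets."""
        ds = random_survival_dataset(rng, n=40, p=2)
        so = SurvivalOrder.from_dataset(ds)
        perms = np.stack([rng.permutation(40) for _ in range(12)])
        inv = np.empty_like(perms)
        inv[np.arange(12)[:, None], perms] = np.arange(40)
        Xs = ds.expression[:, [0, 1]][inv[:, so.order]]
        b_np, z_np, ok_np = batch_newton(Xs, so)
        b_nb, z_nb, ok_nb = newton_many(Xs, so)
        np.testing.assert_array_equal(ok_np, ok_nb)
        np.testing.assert_allclose(b_np[ok_np], b_nb[ok_nb], atol=1e-6)
        np.testing.assert_allclose(z_np[ok_np], z_nb[ok_nb], atol=1e-5)
        for b in range(12):
            single = fit_cox(
                SurvivalDataset(ds.expression, ds.time[perms[b]],
                                ds.event[perms[b]]),
                (0, 1),
            )
            if single.converged:
                assert ok_np[b]
                np.testing.assert_allclose(single.coefficients, b_np[b],
                                           atol=1e-5)
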