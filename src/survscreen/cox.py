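"""Cox proportional-hazards partial likelihood for covariate tuples.

Maximum partial-likelihood estimation is done by Newton-Raphson with
step-halving; tied event times use the Breslow convention, i.e. a single
risk-set denominator per distinct event time raised to the death count.
A vectorised Newton engine (`batch_newton`) refits the same tuple against
many permuted outcome assignments at once, which is what makes permutation
calibration affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SurvivalDataset
from .errors import DegenerateDataError, NonIdentifiableError, UnusableFitError

#: coefficients beyond this magnitude are treated as monotone-likelihood blowup
DIVERGENCE_BOUND = 20.0


class SurvivalOrder:
    """Sorted-time bookkeeping shared by every partial-likelihood evaluation.

    Sorting the samples once by observed time turns every Breslow risk-set
    sum into a reverse cumulative sum; the attributes below index that
    sorted order:

    - ``order``: sample indices sorted by ascending time (stable),
    - ``group_starts``: first sorted row of each distinct time that has >= 1
      death (the risk set at that time is ``sorted_rows[start:]``),
    - ``d``: deaths per such group,
    - ``death_rows``: sorted-row indices of all deaths,
    - ``death_starts``: offsets into ``death_rows`` delimiting groups.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(bool)
        if not event.any():
            raise DegenerateDataError("no observed events")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        ts = time[self.order]
        es = event[self.order]
        _, starts = np.unique(ts, return_index=True)
        d_all = np.add.reduceat(es.astype(np.int64), starts)
        keep = d_all > 0
        self.group_starts = starts[keep]
        self.d = d_all[keep]
        self.death_rows = np.flatnonzero(es)
        grp_of_death = (
            np.searchsorted(self.group_starts, self.death_rows, side="right") - 1
        )
        self.death_starts = np.flatnonzero(
            np.r_[True, np.diff(grp_of_death) > 0]
        )
        self.n_events = int(self.d.sum())

    @classmethod
    def from_dataset(cls, dataset: SurvivalDataset) -> "SurvivalOrder":
        return cls(dataset.time, dataset.event)


def _rcum(a: np.ndarray, axis: int) -> np.ndarray:
    """Reverse cumulative sum along `axis`."""
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


def _pll_terms(Xs: np.ndarray, beta: np.ndarray, so: SurvivalOrder,
               want_derivs: bool = True):
    """Breslow log partial likelihood (and optionally gradient/information).

    Xs has shape (R, n, k): R covariate layouts, each aligned to the sorted
    time order of `so`. Returns (loglik (R,), grad (R,k), info (R,k,k)).
    """
    eta = np.einsum("rnk,rk->rn", Xs, beta)
    shift = eta.max(axis=1, keepdims=True)
    w = np.exp(eta - shift)
    s0 = _rcum(w, axis=1)[:, so.group_starts]  # (R, G)
    loglik = (
        eta[:, so.death_rows].sum(axis=1)
        - (so.d * (np.log(s0) + shift)).sum(axis=1)
    )
    if not want_derivs:
        return loglik, None, None
    wX = w[..., None] * Xs
    s1 = _rcum(wX, axis=1)[:, so.group_starts]  # (R, G, k)
    wXX = wX[..., :, None] * Xs[..., None, :]
    s2 = _rcum(wXX, axis=1)[:, so.group_starts]  # (R, G, k, k)
    mbar = s1 / s0[..., None]
    grad = Xs[:, so.death_rows].sum(axis=1) - (so.d[:, None] * mbar).sum(axis=1)
    info = (
        so.d[:, None, None]
        * (s2 / s0[..., None, None] - mbar[..., :, None] * mbar[..., None, :])
    ).sum(axis=1)
    return loglik, grad, info


def _sorted_covariates(dataset: SurvivalDataset, tuple_indices,
                       so: SurvivalOrder) -> np.ndarray:
    idx = np.asarray(tuple_indices, dtype=int)
    if idx.ndim != 1 or idx.size < 1:
        raise ValueError("tuple_indices must be a non-empty 1-D index sequence")
    if idx.min() < 0 or idx.max() >= dataset.n_features:
        raise ValueError("tuple_indices out of range")
    return dataset.expression[so.order][:, idx]


def partial_log_likelihood(dataset: SurvivalDataset, tuple_indices,
                           beta) -> float:
    """Breslow log partial likelihood of `beta` for one covariate tuple."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    so = SurvivalOrder.from_dataset(dataset)
    Xs = _sorted_covariates(dataset, tuple_indices, so)[None]
    if beta.size != Xs.shape[2]:
        raise ValueError("beta length must match the tuple size")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    ll, _, _ = _pll_terms(Xs, beta[None], so, want_derivs=False)
    return float(ll[0])


@dataclass(frozen=True)
class CoxFit:
    """Result of maximising the partial likelihood for one tuple."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    wald_z: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_iterations: int
    divergence_flag: bool = False

    @property
    def k(self) -> int:
        return self.coefficients.size


def fit_cox(
    dataset: SurvivalDataset,
    tuple_indices,
    max_iter: int = 50,
    tol: float = 1e-8,
    bound: float = DIVERGENCE_BOUND,
) -> CoxFit:
    """Newton-Raphson maximisation of the Breslow partial likelihood.

    Standard errors come from the inverse observed information diagonal.
    `converged` is set when the largest coefficient change drops below
    `tol`; if any coefficient magnitude exceeds `bound` the likelihood is
    taken to be monotone (separated data) and `divergence_flag` is raised
    instead of an exception so permutation replicates can record the event.
    """
    so = SurvivalOrder.from_dataset(dataset)
    Xs = _sorted_covariates(dataset, tuple_indices, so)
    k = Xs.shape[1]
    if np.any(np.ptp(Xs, axis=0) == 0):
        raise NonIdentifiableError(
            "a covariate in the tuple is constant across samples"
        )
    Xs = Xs[None]
    beta = np.zeros(k)
    ll, grad, info = _pll_terms(Xs, beta[None], so)
    converged = diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info[0], grad[0])
        except np.linalg.LinAlgError as exc:
            raise NonIdentifiableError(
                "observed information is singular for this tuple"
            ) from exc
        # step-halving: insist on a non-decreasing partial likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _pll_terms(Xs, cand[None], so)
            if ll_new[0] >= ll[0] - 1e-12 and np.isfinite(ll_new[0]):
                break
            scale /= 2.0
        delta = cand - beta
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.abs(beta).max() > bound:
            diverged = True
            break
        if np.abs(delta).max() < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info[0])
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    return CoxFit(
        coefficients=beta,
        std_errors=se,
        wald_z=z,
        log_partial_likelihood=float(ll[0]),
        converged=converged and not diverged,
        n_iterations=it,
        divergence_flag=diverged,
    )


def wald_statistics(fit: CoxFit) -> np.ndarray:
    """Per-component Wald z = beta_hat / se from a converged fit."""
    if not fit.converged:
        raise UnusableFitError("Wald statistics require a converged fit")
    return fit.wald_z


def _fused_grad_info(Xs, beta, death_x, iu, so):
    """Gradient and observed information for R layouts in one packed pass.

    All Breslow risk-set sums (S0, S1, and the upper triangle of S2) ride a
    single reverse cumulative sum over a channel-packed array, which keeps
    the per-Newton-iteration memory traffic low.
    """
    R, n, k = Xs.shape
    nu = iu[0].size
    eta = np.einsum("rnk,rk->rn", Xs, beta)
    np.subtract(eta, eta.max(axis=1, keepdims=True), out=eta)
    w = np.exp(eta)
    C = np.empty((R, n, 1 + k + nu), dtype=Xs.dtype)
    C[..., 0] = w
    C[..., 1 : 1 + k] = w[..., None] * Xs
    C[..., 1 + k :] = C[..., 1 + iu[0]] * Xs[..., iu[1]]
    S = np.flip(np.cumsum(np.flip(C, axis=1), axis=1), axis=1)[:, so.group_starts]
    s0 = S[..., 0]
    mbar = S[..., 1 : 1 + k] / s0[..., None]
    grad = death_x - np.einsum("g,rgk->rk", so.d, mbar)
    m2 = S[..., 1 + k :] / s0[..., None] - mbar[..., iu[0]] * mbar[..., iu[1]]
    tri = np.einsum("g,rgu->ru", so.d, m2)
    info = np.empty((R, k, k), dtype=Xs.dtype)
    info[:, iu[0], iu[1]] = tri
    info[:, iu[1], iu[0]] = tri
    return grad, info


def _solve_newton(info, grad):
    """Batched Newton step with a per-item fallback; flags singular systems."""
    bad = ~(
        np.isfinite(grad).all(axis=1) & np.isfinite(info).all(axis=(1, 2))
    )
    step = np.zeros_like(grad)
    good = ~bad
    if good.any():
        try:
            step[good] = np.linalg.solve(info[good], grad[good][..., None])[..., 0]
        except np.linalg.LinAlgError:
            for j in np.flatnonzero(good):
                try:
                    step[j] = np.linalg.solve(info[j], grad[j])
                except np.linalg.LinAlgError:
                    bad[j] = True
    return step, bad


def batch_newton(
    Xs: np.ndarray,
    so: SurvivalOrder,
    max_iter: int = 50,
    tol: float = 1e-8,
    bound: float = DIVERGENCE_BOUND,
):
    """Fit the same Cox tuple against R outcome layouts simultaneously.

    Xs has shape (R, n, k) with rows aligned to `so`'s sorted order. Plain
    Newton updates (no step-halving) with a divergence safeguard; layouts
    whose update fails, diverges or does not converge are flagged.

    Returns (beta (R,k), z (R,k), ok (R,) bool). Components of failed
    layouts have z = NaN; callers doing permutation tests should treat
    them as infinitely extreme (conservative).
    """
    R, _, k = Xs.shape
    iu = np.triu_indices(k)
    death_x_all = Xs[:, so.death_rows, :].sum(axis=1)
    beta = np.zeros((R, k), dtype=Xs.dtype)
    z = np.full((R, k), np.nan)
    converged = np.zeros(R, dtype=bool)
    failed = np.zeros(R, dtype=bool)
    active = np.ones(R, dtype=bool)
    for _ in range(max_iter):
        ai = np.flatnonzero(active)
        if ai.size == 0:
            break
        grad, info = _fused_grad_info(Xs[ai], beta[ai], death_x_all[ai], iu, so)
        step, bad = _solve_newton(info, grad)
        beta[ai] += step
        div = np.abs(beta[ai]).max(axis=1) > bound
        conv = (np.abs(step).max(axis=1) < tol) & ~bad & ~div
        ci = ai[conv]
        if ci.size:
            # the information at the pre-update beta is within O(tol) of the
            # converged one; reuse it for the standard errors
            sel = np.flatnonzero(conv)
            try:
                cov = np.linalg.inv(info[sel])
                se = np.sqrt(
                    np.clip(np.diagonal(cov, axis1=1, axis2=2), 0.0, np.inf)
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    z[ci] = np.where(se > 0, beta[ci] / se, np.nan)
                converged[ci] = True
            except np.linalg.LinAlgError:
                failed[ci] = True
        failed[ai[bad | div]] = True
        active[ai] = ~(conv | bad | div)
    failed |= active  # ran out of iterations
    ok = converged & ~failed & np.isfinite(z).all(axis=1)
    return beta, z, ok
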