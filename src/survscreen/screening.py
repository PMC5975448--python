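"""Step 1 — screen covariate k-tuples by permutation-calibrated Wald tests.

Every k-tuple of features is fitted jointly in a Cox model; each
component's Wald statistic is then referred to a null distribution built
by randomly re-pairing the (time, event) outcomes with the fixed
expression rows and refitting. A tuple is selected when every component's
permutation p-value is at or below the threshold, so selection demands
joint — not merely marginal — significance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from ._kernels import HAVE_NUMBA, newton_many
from .cox import CoxFit, SurvivalOrder, batch_newton, fit_cox
from .datasets import PermutationConfig, SurvivalDataset
from .errors import (
    DegenerateDataError,
    InvalidConfigError,
    NonIdentifiableError,
    UnusableFitError,
)

#: permutation chunk schedule: small first chunks let early stopping bail out
#: cheaply on clearly-null tuples, large later chunks amortise overhead
_FIRST_CHUNK = 64
_CHUNK = 256
#: coefficient tolerance for permutation refits; |z| is only compared against
#: the observed statistic, so 1e-5 on beta is far below the decision scale
_PERM_TOL = 1e-5


def enumerate_tuples(p: int, k: int) -> list:
    """All C(p, k) ascending k-index combinations in lexicographic order."""
    if k < 1 or k > p:
        raise InvalidConfigError(f"tuple size k={k} must satisfy 1 <= k <= p={p}")
    return list(itertools.combinations(range(p), k))


def make_outcome_permutations(
    dataset: SurvivalDataset, config: PermutationConfig
) -> np.ndarray:
    """Draw B random re-pairings of (time, event) against the sample rows.

    Returns an integer array of shape (B, n): under permutation ``b``,
    sample ``i`` receives the outcome pair of original sample ``perm[b, i]``
    while its expression row stays fixed. The same B permutations are shared
    by every tuple in a run, which makes results independent of the order in
    which tuples are processed.
    """
    rng = np.random.default_rng(config.seed)
    n = dataset.n_samples
    base = np.broadcast_to(np.arange(n), (config.n_permutations, n))
    return rng.permuted(base, axis=1)


def _permutation_row_gather(permutations: np.ndarray, so: SurvivalOrder) -> np.ndarray:
    """Row-index matrix G with G[b, j] = expression row occupying sorted slot j
    of permutation b's outcome order."""
    B, n = permutations.shape
    inv = np.empty_like(permutations)
    inv[np.arange(B)[:, None], permutations] = np.arange(n)
    return inv[:, so.order]


def _null_abs_z(X_tuple: np.ndarray, rows: np.ndarray, so: SurvivalOrder) -> np.ndarray:
    """|Wald z| for each permuted layout; failed fits become +inf (conservative)."""
    Xs = X_tuple[rows]
    if HAVE_NUMBA:
        _, z, ok = newton_many(Xs, so, tol=_PERM_TOL)
    else:  # pragma: no cover - numpy fallback, cross-checked in tests
        _, z, ok = batch_newton(Xs, so, tol=_PERM_TOL)
    az = np.abs(z)
    az[~ok] = np.inf
    az[~np.isfinite(az)] = np.inf
    return az


def _perm_p_components(
    X_tuple: np.ndarray,
    z_obs_abs: np.ndarray,
    rows: np.ndarray,
    so: SurvivalOrder,
    early_stop_hits: int | None,
) -> np.ndarray:
    counts = np.zeros(X_tuple.shape[1], dtype=np.int64)
    B = rows.shape[0]
    used = 0
    while used < B:
        size = _FIRST_CHUNK if used < 2 * _FIRST_CHUNK else _CHUNK
        az = _null_abs_z(X_tuple, rows[used : used + size], so)
        counts += (az >= z_obs_abs[None, :]).sum(axis=0)
        used += az.shape[0]
        if early_stop_hits is not None and counts.min() >= early_stop_hits:
            break
    return (1.0 + counts) / (used + 1.0)


def wald_permutation_test(
    dataset: SurvivalDataset,
    tuple_indices,
    observed_fit: CoxFit,
    permutations: np.ndarray,
    early_stop_hits: int | None = None,
) -> np.ndarray:
    """Two-sided permutation p-value for each Wald component of one tuple.

    p_j = (1 + #{r : |z0_{j,r}| >= |z_j|}) / (B_used + 1). With
    ``early_stop_hits`` set, permutation chunks stop once that many
    exceedances have accumulated on every component and the p-value uses
    the permutations actually evaluated.
    """
    if permutations.ndim != 2 or permutations.shape[0] < 1:
        raise InvalidConfigError("need at least one permutation")
    if not observed_fit.converged:
        raise UnusableFitError("observed fit did not converge")
    so = SurvivalOrder.from_dataset(dataset)
    rows = _permutation_row_gather(permutations, so)
    idx = np.asarray(tuple_indices, dtype=int)
    return _perm_p_components(
        dataset.expression[:, idx],
        np.abs(observed_fit.wald_z),
        rows,
        so,
        early_stop_hits,
    )


@dataclass(frozen=True)
class TupleResult:
    """Step-1 verdict for one k-tuple."""

    tuple_indices: tuple
    feature_ids: tuple
    fit: CoxFit | None
    perm_p: np.ndarray | None
    selected: bool
    failure: str | None = None


def _screen_one(dataset, idx, alpha1, rows, so, early_stop_hits):
    fids = tuple(dataset.feature_ids[j] for j in idx)
    try:
        fit = fit_cox(dataset, idx)
    except (NonIdentifiableError, DegenerateDataError) as exc:
        return TupleResult(tuple(idx), fids, None, None, False, failure=str(exc))
    if not fit.converged:
        reason = "diverged (monotone likelihood)" if fit.divergence_flag \
            else "did not converge"
        return TupleResult(tuple(idx), fids, fit, None, False, failure=reason)
    perm_p = _perm_p_components(
        dataset.expression[:, np.asarray(idx, dtype=int)],
        np.abs(fit.wald_z),
        rows,
        so,
        early_stop_hits,
    )
    return TupleResult(
        tuple(idx), fids, fit, perm_p, selected=bool(perm_p.max() <= alpha1)
    )


def step1_select(
    dataset: SurvivalDataset,
    k: int,
    alpha1: float,
    config: PermutationConfig,
    workers: int = 1,
    tuples=None,
) -> list:
    """Screen every k-tuple; select those with all components significant.

    Tuples whose observed fit is non-identifiable or diverges are reported
    with a failure reason and excluded from selection, never dropped
    silently. ``tuples`` restricts the screen to an explicit subset of
    index tuples (the full enumeration is the default).
    """
    if tuples is None:
        tuples = enumerate_tuples(dataset.n_features, k)
    else:
        tuples = [tuple(sorted(t)) for t in tuples]
    so = SurvivalOrder.from_dataset(dataset)
    perms = make_outcome_permutations(dataset, config)
    rows = _permutation_row_gather(perms, so)
    esh = config.early_stop_hits
    if workers and workers > 1:
        chunks = np.array_split(np.arange(len(tuples)), workers * 4)
        parts = Parallel(n_jobs=workers)(
            delayed(_screen_chunk)(dataset, [tuples[i] for i in c], alpha1, rows, so, esh)
            for c in chunks if len(c)
        )
        return [r for part in parts for r in part]
    return _screen_chunk(dataset, tuples, alpha1, rows, so, esh)


def _screen_chunk(dataset, tuples, alpha1, rows, so, early_stop_hits):
    return [
        _screen_one(dataset, idx, alpha1, rows, so, early_stop_hits)
        for idx in tuples
    ]
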