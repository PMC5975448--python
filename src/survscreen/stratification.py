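"""Step 2 — risk-group stratification with a permutation-calibrated log-rank test.

Each tuple that survived step 1 is turned into a scalar risk score (the
linear predictor of its Cox fit). A cutoff on the score splits samples
into high- and low-risk groups; the two-group log-rank statistic, built
from observed-minus-expected deaths with hypergeometric variances at each
distinct event time, is then calibrated by permuting the (time, event)
pairs against the fixed group labels. Kaplan-Meier curves and Harrell's
concordance index are reported as descriptive diagnostics; selection uses
only the log-rank permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cox import SurvivalOrder
from .datasets import PermutationConfig, SurvivalDataset
from .errors import (
    DegenerateDataError,
    DegenerateStratificationError,
    InvalidConfigError,
    UndefinedStatisticError,
)
from .screening import _permutation_row_gather, make_outcome_permutations


def risk_score(dataset: SurvivalDataset, tuple_indices, coefficients) -> np.ndarray:
    """Linear predictor x'beta_hat per sample, using the step-1 coefficients."""
    idx = np.asarray(tuple_indices, dtype=int)
    beta = np.asarray(coefficients, dtype=float)
    if beta.ndim != 1 or beta.size != idx.size:
        raise ValueError("coefficients must be 1-D and match the tuple size")
    return dataset.expression[:, idx] @ beta


def _resolve_cutoff(scores: np.ndarray, cutoff_rule) -> float:
    if isinstance(cutoff_rule, str):
        rule = cutoff_rule.strip().lower()
        if rule == "median":
            return float(np.median(scores))
        if rule.startswith("quantile:"):
            return float(np.quantile(scores, float(rule.split(":", 1)[1])))
        if rule.startswith("value:"):
            return float(rule.split(":", 1)[1])
        raise InvalidConfigError(f"unknown cutoff rule {cutoff_rule!r}")
    if isinstance(cutoff_rule, tuple) and len(cutoff_rule) == 2:
        kind, val = cutoff_rule
        if kind == "quantile":
            return float(np.quantile(scores, val))
        if kind == "value":
            return float(val)
        raise InvalidConfigError(f"unknown cutoff rule {cutoff_rule!r}")
    return float(cutoff_rule)  # bare number = fixed cutoff value


def stratify(scores, cutoff_rule="median"):
    """Split samples into high (score > cutoff) and low risk groups.

    Ties at the cutoff go to the low-risk group. Returns
    ``(group_labels, cutoff)`` with group 1 = high risk; raises if either
    group would be empty (e.g. all scores identical).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise DegenerateStratificationError("need at least two samples to stratify")
    cutoff = _resolve_cutoff(scores, cutoff_rule)
    group = (scores > cutoff).astype(np.int8)
    if group.all() or not group.any():
        raise DegenerateStratificationError(
            "stratification produced an empty risk group "
            f"(cutoff={cutoff:g}; scores may be constant)"
        )
    return group, cutoff


@dataclass(frozen=True)
class LogRankTable:
    """Per-event-time bookkeeping of the two-group log-rank statistic."""

    times: np.ndarray      # distinct event times
    n: np.ndarray          # total at risk
    n1: np.ndarray         # at risk, high-risk group
    n0: np.ndarray         # at risk, low-risk group
    d: np.ndarray          # total deaths
    d1: np.ndarray         # deaths in high-risk group
    e1: np.ndarray         # expected deaths in high-risk group, n1*d/n
    v1: np.ndarray         # hypergeometric variance of d1


def _logrank_terms(g_sorted: np.ndarray, so: SurvivalOrder):
    """(sum(d1-e1), sum(v1)) for group layouts aligned to sorted order.

    g_sorted: (R, n) 0/1 high-risk indicators in sorted-time order.
    """
    n_tot = so.n - so.group_starts          # at risk per event group
    d = so.d.astype(float)
    n1 = np.flip(
        np.cumsum(np.flip(g_sorted.astype(float), axis=1), axis=1), axis=1
    )[:, so.group_starts]
    d1 = np.add.reduceat(
        g_sorted[:, so.death_rows].astype(float), so.death_starts, axis=1
    )
    e1 = n1 * d / n_tot
    n0 = n_tot - n1
    denom = n_tot.astype(float) ** 2 * np.maximum(n_tot - 1, 1)
    v1 = n1 * n0 * d * (n_tot - d) / denom
    return (d1 - e1).sum(axis=1), v1.sum(axis=1), (n_tot, n1, n0, d, d1, e1, v1)


def logrank_statistic(time, event, group):
    """Two-group log-rank chi-square Q with its per-time table.

    Q = (sum_i (d1i - e1i))^2 / sum_i v1i over distinct event times; times
    with zero hypergeometric variance contribute nothing to the denominator
    but keep their observed-minus-expected term in the numerator.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    if group.min() == group.max():
        raise DegenerateStratificationError("both risk groups must be non-empty")
    if not (event == 1).any():
        raise DegenerateDataError("log-rank test needs at least one event")
    so = SurvivalOrder(time, event)
    g_sorted = (group[so.order] == 1)[None].astype(np.int8)
    U, V, (n_tot, n1, n0, d, d1, e1, v1) = _logrank_terms(g_sorted, so)
    if V[0] <= 0:
        raise UndefinedStatisticError("log-rank variance is zero on these data")
    # event times carried by the sorted layout
    times = np.asarray(time)[so.order][so.group_starts]
    table = LogRankTable(
        times=times, n=n_tot, n1=n1[0], n0=n0[0],
        d=d, d1=d1[0], e1=e1[0], v1=v1[0],
    )
    return table, float(U[0] ** 2 / V[0])


def logrank_permutation_test(time, event, group, config: PermutationConfig) -> float:
    """One-sided permutation p for the log-rank Q of a fixed stratification.

    The (time, event) pairs are permuted against the fixed group labels
    (the labels derive from expression through beta_hat, which outcome
    rearrangement does not alter); p = (1 + #{r: Q0_r >= Q}) / (B + 1).
    Permutations with zero log-rank variance count as exceedances
    (conservative).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    _, Q = logrank_statistic(time, event, group)
    so = SurvivalOrder(time, event)
    n = time.size
    rng = np.random.default_rng(config.seed)
    base = np.broadcast_to(np.arange(n), (config.n_permutations, n))
    perms = rng.permuted(base, axis=1)
    rows = _permutation_row_gather(perms, so)
    g01 = (group == 1).astype(np.int8)
    g_sorted = g01[rows]
    U, V, _ = _logrank_terms(g_sorted, so)
    with np.errstate(divide="ignore", invalid="ignore"):
        Q0 = np.where(V > 0, U * U / np.where(V > 0, V, 1.0), np.inf)
    return float((1.0 + (Q0 >= Q).sum()) / (config.n_permutations + 1.0))


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate of a survival function."""

    times: np.ndarray          # distinct event times (steps)
    survival: np.ndarray       # S(t) just after each step
    at_risk: np.ndarray        # n at risk entering each step
    n_events: np.ndarray       # deaths at each step
    censor_times: np.ndarray   # observed times of censored samples

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(time, event) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i/n_i)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise DegenerateDataError("empty sample")
    censor_times = np.sort(time[event == 0])
    if not (event == 1).any():
        return KMCurve(
            times=np.empty(0), survival=np.empty(0), at_risk=np.empty(0, int),
            n_events=np.empty(0, int), censor_times=censor_times,
        )
    so = SurvivalOrder(time, event)
    n_at_risk = so.n - so.group_starts
    surv = np.cumprod(1.0 - so.d / n_at_risk)
    times = time[so.order][so.group_starts]
    return KMCurve(
        times=times, survival=surv, at_risk=n_at_risk,
        n_events=so.d.copy(), censor_times=censor_times,
    )


def concordance_index(time, event, scores) -> float:
    """Harrell's C over permissible pairs.

    A pair is permissible when the two observed times differ and the
    earlier one is a death. A pair is concordant when the shorter survivor
    carries the higher risk score; score ties count 1/2. C in [0, 1].
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    scores = np.asarray(scores, dtype=float)
    # earlier sample i (row) vs later sample j (col)
    permissible = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_pairs = int(permissible.sum())
    if n_pairs == 0:
        raise UndefinedStatisticError("no permissible pairs for the C-index")
    higher = scores[:, None] > scores[None, :]
    tied = scores[:, None] == scores[None, :]
    concordant = (higher & permissible).sum() + 0.5 * (tied & permissible).sum()
    return float(concordant / n_pairs)


@dataclass(frozen=True)
class StratificationResult:
    """Step-2 verdict for one step-1-selected tuple."""

    tuple_indices: tuple
    feature_ids: tuple
    risk_scores: np.ndarray | None = None
    cutoff: float | None = None
    group: np.ndarray | None = None
    logrank_Q: float | None = None
    perm_p: float | None = None
    km_high: KMCurve | None = None
    km_low: KMCurve | None = None
    c_index: float | None = None
    selected: bool = False
    failure: str | None = None


def step2_select(
    dataset: SurvivalDataset,
    step1_results,
    alpha2: float,
    cutoff_rule="median",
    config: PermutationConfig | None = None,
) -> list:
    """Stratify every step-1-selected tuple and keep the significant ones.

    Degenerate stratifications (empty group, zero variance) are reported
    with a reason rather than dropped. An empty step-1 selection yields an
    empty list.
    """
    config = config or PermutationConfig()
    out = []
    for res in step1_results:
        if not getattr(res, "selected", False):
            continue
        idx = tuple(res.tuple_indices)
        fids = tuple(res.feature_ids)
        scores = risk_score(dataset, idx, res.fit.coefficients)
        try:
            group, cutoff = stratify(scores, cutoff_rule)
            _, Q = logrank_statistic(dataset.time, dataset.event, group)
            p = logrank_permutation_test(dataset.time, dataset.event, group, config)
        except (DegenerateStratificationError, UndefinedStatisticError,
                DegenerateDataError) as exc:
            out.append(StratificationResult(idx, fids, risk_scores=scores,
                                            failure=str(exc)))
            continue
        hi, lo = group == 1, group == 0
        out.append(
            StratificationResult(
                tuple_indices=idx,
                feature_ids=fids,
                risk_scores=scores,
                cutoff=cutoff,
                group=group,
                logrank_Q=Q,
                perm_p=p,
                km_high=km_estimate(dataset.time[hi], dataset.event[hi]),
                km_low=km_estimate(dataset.time[lo], dataset.event[lo]),
                c_index=concordance_index(dataset.time, dataset.event, scores),
                selected=bool(p <= alpha2),
            )
        )
    return out
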