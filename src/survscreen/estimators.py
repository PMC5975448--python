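"""Scikit-learn style front end for two-step joint covariate detection."""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .datasets import PermutationConfig, SurvivalDataset, standardize
from .screening import step1_select
from .stratification import step2_select


def _as_time_event(y, n: int):
    """Accept (time, event) in the common survival encodings.

    Supported: a structured array with event/time fields (scikit-survival
    convention, event first), a DataFrame with 'time' and 'event' columns,
    a 2-column array ordered (time, event), or a (time, event) pair of
    sequences.
    """
    if isinstance(y, pd.DataFrame):
        if not {"time", "event"} <= set(y.columns):
            raise ValueError("y DataFrame must have 'time' and 'event' columns")
        return y["time"].to_numpy(float), y["event"].to_numpy()
    arr = np.asarray(y)
    if arr.dtype.names:
        names = list(arr.dtype.names)
        ev = arr[names[0]].astype(int) if arr[names[0]].dtype == bool \
            else np.asarray(arr[names[0]])
        return np.asarray(arr[names[1]], dtype=float), np.asarray(ev)
    if isinstance(y, (tuple, list)) and len(y) == 2 and not isinstance(
        y[0], numbers.Number
    ):
        return np.asarray(y[0], dtype=float), np.asarray(y[1])
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1]
    raise ValueError(
        "y must encode (time, event): structured array, DataFrame, "
        "2-column array, or a pair of sequences"
    )


class JointCovariateDetector(SelectorMixin, BaseEstimator):
    """Select feature tuples that are jointly prognostic for survival.

    Step 1 fits a Cox proportional-hazards model to every k-tuple of
    features and keeps tuples whose Wald statistics are all significant
    under a permutation null built by re-pairing outcomes with samples.
    Step 2 turns each surviving tuple into a risk score (the Cox linear
    predictor), splits samples at a score cutoff, and keeps tuples whose
    high/low-risk split passes a permutation-calibrated log-rank test.

    Parameters
    ----------
    k : tuple size (1 = individual screening, 2 = pair screening).
    alpha1 : step-1 per-component permutation p-value threshold.
    alpha2 : step-2 log-rank permutation p-value threshold.
    n_permutations : outcome permutations B for both steps.
    early_stop_hits : stop a tuple's step-1 permutations once this many
        null exceedances have accumulated on every component (None = never).
    cutoff : "median", "quantile:q", "value:v" or a number — risk-score
        cutoff rule for stratification.
    zscore : standardize each feature before fitting.
    random_state : seed for the permutation draws.

    Attributes
    ----------
    step1_results_ : list of TupleResult for every enumerated tuple.
    step2_results_ : list of StratificationResult for step-1 survivors.
    selected_tuples_ : index tuples in the final (step-2) selection.
    support_ : boolean mask, union of features in selected tuples.
    """

    def __init__(
        self,
        k: int = 2,
        alpha1: float = 0.001,
        alpha2: float = 0.001,
        n_permutations: int = 1000,
        early_stop_hits: int | None = 20,
        cutoff="median",
        zscore: bool = False,
        random_state: int | None = None,
    ):
        self.k = k
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.n_permutations = n_permutations
        self.early_stop_hits = early_stop_hits
        self.cutoff = cutoff
        self.zscore = zscore
        self.random_state = random_state

    def _seed(self) -> int:
        if self.random_state is None:
            return int(np.random.default_rng().integers(2**31 - 1))
        if isinstance(self.random_state, numbers.Integral):
            return int(self.random_state)
        return int(np.asarray(self.random_state).ravel()[0])

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, dtype=float)
        time, event = _as_time_event(y, X.shape[0])
        fids = (
            tuple(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else tuple(f"x{j}" for j in range(X.shape[1]))
        )
        ds = SurvivalDataset(
            expression=X, time=time, event=event, feature_ids=fids
        )
        if self.zscore:
            ds = standardize(ds)
        seed = self._seed()
        esh = self.early_stop_hits
        if esh is not None:
            esh = min(esh, self.n_permutations)
        cfg1 = PermutationConfig(
            n_permutations=self.n_permutations, seed=seed,
            early_stop_hits=esh,
        )
        cfg2 = PermutationConfig(n_permutations=self.n_permutations, seed=seed + 1)
        self.step1_results_ = step1_select(ds, self.k, self.alpha1, cfg1)
        self.step2_results_ = step2_select(
            ds, self.step1_results_, self.alpha2, self.cutoff, cfg2
        )
        self.selected_tuples_ = [
            r.tuple_indices for r in self.step2_results_ if r.selected
        ]
        mask = np.zeros(X.shape[1], dtype=bool)
        for idx in self.selected_tuples_:
            mask[list(idx)] = True
        self.support_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def results_frame(self) -> pd.DataFrame:
        """Tidy per-tuple summary of both steps (one row per step-2 tuple)."""
        check_is_fitted(self, "step2_results_")
        rows = []
        for r in self.step2_results_:
            rows.append(
                {
                    "features": "+".join(r.feature_ids),
                    "cutoff": r.cutoff,
                    "logrank_Q": r.logrank_Q,
                    "perm_p": r.perm_p,
                    "c_index": r.c_index,
                    "selected": r.selected,
                    "failure": r.failure or "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["features", "cutoff", "logrank_Q", "perm_p", "c_index",
                     "selected", "failure"],
        )
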