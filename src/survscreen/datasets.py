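"""Survival expression data: container, validation, risk sets and tidy I/O.

The on-disk dialect is a tab- or comma-separated UTF-8 table with a header
row, one row per sample, columns ``[sample_id, time, event, feature...]``.
Time is the observed follow-up time (strictly positive), event is 1 when
death was observed and 0 when the sample is right-censored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidConfigError, ValidationError

ID_COL = "sample_id"
TIME_COL = "time"
EVENT_COL = "event"


@dataclass(frozen=True)
class SurvivalDataset:
    """An expression matrix with right-censored survival outcomes.

    Parameters
    ----------
    expression : (n_samples, n_features) float array
        Expression levels, one row per sample.
    time : (n_samples,) float array
        Observed survival/follow-up times, strictly positive.
    event : (n_samples,) int array
        1 = death observed, 0 = right-censored.
    feature_ids, sample_ids : sequences of unique strings.
    """

    expression: np.ndarray
    time: np.ndarray
    event: np.ndarray
    feature_ids: tuple = ()
    sample_ids: tuple = ()

    def __post_init__(self):
        X = np.asarray(self.expression, dtype=float)
        if X.ndim != 2:
            raise ValidationError("expression must be a 2-D samples x features matrix")
        t = np.asarray(self.time, dtype=float).ravel()
        e = np.asarray(self.event).ravel()
        n, p = X.shape
        fids = tuple(self.feature_ids) or tuple(f"feature-{j + 1}" for j in range(p))
        sids = tuple(str(s) for s in self.sample_ids) or tuple(
            f"sample-{i + 1}" for i in range(n)
        )
        if len(t) != n or len(e) != n or len(sids) != n:
            raise ValidationError(
                "time, event and sample_ids must match the expression row count"
            )
        if len(fids) != p:
            raise ValidationError("feature_ids must match the expression column count")
        if len(set(fids)) != p:
            raise ValidationError("feature_ids must be unique")
        if len(set(sids)) != n:
            raise ValidationError("sample_ids must be unique")
        if not np.all(np.isfinite(X)):
            raise ValidationError("expression contains missing or non-finite values")
        if not np.all(np.isfinite(t)):
            raise ValidationError("time contains missing or non-finite values")
        bad = np.flatnonzero(t <= 0)
        if bad.size:
            raise ValidationError(
                f"non-positive survival time for sample(s): "
                f"{', '.join(sids[i] for i in bad[:5])}"
            )
        if not np.isin(e, (0, 1)).all():
            raise ValidationError("event indicator must be 0 (censored) or 1 (death)")
        object.__setattr__(self, "expression", X)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e.astype(np.int8))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in fids))
        object.__setattr__(self, "sample_ids", sids)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_features(self) -> int:
        return self.expression.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.expression, columns=list(self.feature_ids))
        df.insert(0, EVENT_COL, self.event.astype(int))
        df.insert(0, TIME_COL, self.time)
        df.insert(0, ID_COL, list(self.sample_ids))
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        time_col: str = TIME_COL,
        event_col: str = EVENT_COL,
        id_col: str = ID_COL,
    ) -> "SurvivalDataset":
        for col in (time_col, event_col):
            if col not in df.columns:
                raise ValidationError(f"required column {col!r} not found in table")
        df = df.copy()
        if id_col in df.columns:
            sids = df.pop(id_col).astype(str).tolist()
        else:
            sids = [f"sample-{i + 1}" for i in range(len(df))]
        missing = df[time_col].isna() | df[event_col].isna()
        if missing.any():
            dropped = [sids[i] for i in np.flatnonzero(missing.to_numpy())]
            warnings.warn(
                f"dropping {len(dropped)} sample(s) with missing time/event: "
                f"{', '.join(dropped[:10])}",
                stacklevel=2,
            )
            keep = ~missing.to_numpy()
            df = df.loc[keep]
            sids = [s for s, k in zip(sids, keep) if k]
        t = df.pop(time_col).to_numpy(dtype=float)
        e = df.pop(event_col).to_numpy()
        feature_cols = list(df.columns)
        if not feature_cols:
            raise ValidationError("table has no feature columns")
        return cls(
            expression=df.to_numpy(dtype=float),
            time=t,
            event=e,
            feature_ids=tuple(feature_cols),
            sample_ids=tuple(sids),
        )


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_dataset(
    path,
    time_col: str = TIME_COL,
    event_col: str = EVENT_COL,
    id_col: str = ID_COL,
) -> SurvivalDataset:
    """Read a tidy survival expression table (TSV by default, CSV by suffix)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # malformed file
        raise ValidationError(f"could not parse {path}: {exc}") from exc
    return SurvivalDataset.from_frame(
        df, time_col=time_col, event_col=event_col, id_col=id_col
    )


def write_dataset(dataset: SurvivalDataset, path) -> None:
    """Write a dataset in the tidy dialect read back by :func:`read_dataset`."""
    dataset.to_frame().to_csv(path, sep=_sep_for(path), index=False)


def standardize(dataset: SurvivalDataset) -> SurvivalDataset:
    """Z-score each feature column (population sd); constant columns become 0."""
    X = dataset.expression
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return SurvivalDataset(
        expression=(X - mu) / sd,
        time=dataset.time,
        event=dataset.event,
        feature_ids=dataset.feature_ids,
        sample_ids=dataset.sample_ids,
    )


@dataclass(frozen=True)
class RiskSetIndex:
    """Distinct event times with their risk sets and death counts.

    ``at_risk[i]`` holds the sample indices with observed time >= ``times[i]``;
    ``d[i]`` counts deaths exactly at ``times[i]``.
    """

    times: np.ndarray
    at_risk: tuple
    d: np.ndarray

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(r) for r in self.at_risk])


def build_risk_sets(dataset: SurvivalDataset) -> RiskSetIndex:
    """Index the risk set and death count at every distinct event time."""
    t, e = dataset.time, dataset.event
    if dataset.n_events == 0:
        raise DegenerateDataError("dataset has zero observed events")
    event_times = np.unique(t[e == 1])
    at_risk = tuple(np.flatnonzero(t >= ti) for ti in event_times)
    d = np.array([int(((t == ti) & (e == 1)).sum()) for ti in event_times])
    return RiskSetIndex(times=event_times, at_risk=at_risk, d=d)


@dataclass(frozen=True)
class PermutationConfig:
    """How many outcome permutations to draw, and how.

    ``n_permutations`` is the number B of random re-pairings of (time, event)
    against the fixed expression rows; ``early_stop_hits`` optionally stops a
    tuple's evaluation once that many null exceedances have accumulated on
    every component (the p-value is then computed from the permutations
    actually used).
    """

    n_permutations: int = 10000
    seed: int = 0
    two_sided: bool = True
    early_stop_hits: int | None = None

    def __post_init__(self):
        if self.n_permutations < 1:
            raise InvalidConfigError("n_permutations must be >= 1")
        if self.early_stop_hits is not None and not (
            1 <= self.early_stop_hits <= self.n_permutations
        ):
            raise InvalidConfigError(
                "early_stop_hits must lie in [1, n_permutations]"
            )
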