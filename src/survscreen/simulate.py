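"""Synthetic censored survival data and the repeated-simulation study harness.

The generator draws an n x p matrix of independent standard-normal
"expression" values X and a latent survival time

    S = exp(-X beta + eps),        eps ~ N(0, noise_var),

so larger linear predictors X beta mean stochastically shorter survival
(on the hazard scale a Cox fit therefore recovers a coefficient of
roughly +beta). By default two of the p = 40 features carry signal,
beta = [0.9, 0.1, 0.001, ..., 0.001]: one strong, one weak, the rest
effectively null. A fixed fraction of samples (10% by default, exact
count) is censored uniformly at random; a censored sample reports a
uniform back-dated fraction of its latent time.

The study harness repeats the full two-step selection on fresh draws and
counts false-positive and false-negative selections of the planted
(alternative-1, alternative-2) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datasets import PermutationConfig, SurvivalDataset
from .errors import InvalidConfigError
from .screening import step1_select
from .stratification import step2_select


def default_beta(p: int = 40) -> np.ndarray:
    """Planted coefficients: one strong (0.9), one weak (0.1), rest 0.001."""
    beta = np.full(p, 0.001)
    beta[0], beta[1] = 0.9, 0.1
    return beta


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic cohort draw."""

    n: int = 50
    p: int = 40
    beta: np.ndarray | None = None
    noise_var: float = 2.0
    censor_frac: float = 0.10
    seed: int = 0
    noise_is_sd: bool = False  # reinterpret noise_var as a standard deviation

    def __post_init__(self):
        if self.n < 2 or self.p < 2:
            raise InvalidConfigError("need n >= 2 samples and p >= 2 features")
        beta = default_beta(self.p) if self.beta is None else np.asarray(
            self.beta, dtype=float
        )
        if beta.size != self.p:
            raise InvalidConfigError("beta length must equal p")
        if not (0 <= self.censor_frac < 1):
            raise InvalidConfigError("censor_frac must lie in [0, 1)")
        if self.noise_var <= 0:
            raise InvalidConfigError("noise_var must be positive")
        object.__setattr__(self, "beta", beta)

    @property
    def noise_sd(self) -> float:
        return self.noise_var if self.noise_is_sd else float(np.sqrt(self.noise_var))


def feature_names(p: int) -> tuple:
    """alternative-1, alternative-2, null-3 ... null-p."""
    return tuple(
        f"alternative-{j + 1}" if j < 2 else f"null-{j + 1}" for j in range(p)
    )


def simulate_dataset(spec: SimulationSpec, return_latent: bool = False):
    """Draw one synthetic cohort; reproducible from ``spec.seed``.

    Exactly ``round(censor_frac * n)`` samples, chosen uniformly, are
    censored: their event indicator is 0 and the observed time is U * S
    with U ~ Uniform(0, 1) applied to the latent time S.
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n, spec.p))
    eps = rng.normal(0.0, spec.noise_sd, size=spec.n)
    latent = np.exp(-X @ spec.beta + eps)
    n_censor = int(round(spec.censor_frac * spec.n))
    event = np.ones(spec.n, dtype=np.int8)
    time = latent.copy()
    if n_censor:
        censored = rng.choice(spec.n, size=n_censor, replace=False)
        event[censored] = 0
        time[censored] = rng.uniform(size=n_censor) * latent[censored]
    ds = SurvivalDataset(
        expression=X,
        time=time,
        event=event,
        feature_ids=feature_names(spec.p),
        sample_ids=tuple(f"sim-{i + 1}" for i in range(spec.n)),
    )
    return (ds, latent) if return_latent else ds


@dataclass(frozen=True)
class ReplicateRecord:
    """Selections and error counts from one simulated cohort."""

    replicate: int
    seed: int
    selected_pairs: tuple          # feature-id pairs in the final selection
    selected_singletons: tuple     # feature ids selected at k=1, step 1
    fp_pairs: int
    fp_singletons: int
    false_negative: bool           # planted pair absent from final selection
    pair_p: float                  # step-2 permutation p of the planted pair
    alt2_single_p: float           # k=1 step-1 p of the weak planted feature
    error: str | None = None


@dataclass(frozen=True)
class StudyReport:
    """Aggregate of the repeated-simulation study."""

    records: tuple
    p: int

    @property
    def n_replicates(self) -> int:
        return len(self.records)

    @property
    def max_fp_pairs(self) -> int:
        return max((r.fp_pairs for r in self.records), default=0)

    @property
    def max_fp_singletons(self) -> int:
        return max((r.fp_singletons for r in self.records), default=0)

    @property
    def fn_count(self) -> int:
        return sum(r.false_negative for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": [r.replicate for r in self.records],
                "seed": [r.seed for r in self.records],
                "n_selected_pairs": [len(r.selected_pairs) for r in self.records],
                "fp_pairs": [r.fp_pairs for r in self.records],
                "fp_singletons": [r.fp_singletons for r in self.records],
                "false_negative": [r.false_negative for r in self.records],
                "pair_p": [r.pair_p for r in self.records],
                "alt2_single_p": [r.alt2_single_p for r in self.records],
                "selected_pairs": [
                    ";".join("+".join(p) for p in r.selected_pairs)
                    for r in self.records
                ],
                "selected_singletons": [
                    ";".join(r.selected_singletons) for r in self.records
                ],
                "error": [r.error or "" for r in self.records],
            }
        )


def _run_replicate(
    i, seed, spec, alpha_single, alpha_pair, alpha2, config, cutoff_rule
):
    rep_spec = SimulationSpec(
        n=spec.n, p=spec.p, beta=spec.beta, noise_var=spec.noise_var,
        censor_frac=spec.censor_frac, seed=seed, noise_is_sd=spec.noise_is_sd,
    )
    ds = simulate_dataset(rep_spec)
    planted = (ds.feature_ids[0], ds.feature_ids[1])
    try:
        cfg1 = PermutationConfig(
            n_permutations=config.n_permutations, seed=seed + 1,
            early_stop_hits=config.early_stop_hits,
        )
        singles = step1_select(ds, k=1, alpha1=alpha_single, config=cfg1)
        alt2_p = next(
            (float(r.perm_p[0]) for r in singles
             if r.tuple_indices == (1,) and r.perm_p is not None),
            float("nan"),
        )
        sel_singles = tuple(
            r.feature_ids[0] for r in singles if r.selected
        )
        pairs1 = step1_select(ds, k=2, alpha1=alpha_pair, config=cfg1)
        cfg2 = PermutationConfig(
            n_permutations=config.n_permutations, seed=seed + 2,
        )
        pairs2 = step2_select(ds, pairs1, alpha2=alpha2,
                              cutoff_rule=cutoff_rule, config=cfg2)
        sel_pairs = tuple(r.feature_ids for r in pairs2 if r.selected)
        pair_p = next(
            (float(r.perm_p) for r in pairs2
             if r.feature_ids == planted and r.perm_p is not None),
            float("nan"),
        )
    except Exception as exc:  # record, don't abort the study
        return ReplicateRecord(i, seed, (), (), 0, 0, True,
                               float("nan"), float("nan"), error=repr(exc))
    fp_pairs = sum(p != planted for p in sel_pairs)
    fp_singles = sum(s != planted[0] for s in sel_singles)
    return ReplicateRecord(
        replicate=i, seed=seed,
        selected_pairs=sel_pairs, selected_singletons=sel_singles,
        fp_pairs=fp_pairs, fp_singletons=fp_singles,
        false_negative=planted not in sel_pairs,
        pair_p=pair_p, alt2_single_p=alt2_p,
    )


def run_simulation_study(
    spec: SimulationSpec,
    replicates: int,
    alpha_single: float = 0.05,
    alpha_pair: float = 0.001,
    alpha2: float = 0.001,
    config: PermutationConfig | None = None,
    cutoff_rule="median",
    workers: int = 1,
) -> StudyReport:
    """Repeat simulate -> step 1 (k=1 and k=2) -> step 2 and count errors.

    A false-positive pair is any finally selected pair other than the
    planted (alternative-1, alternative-2); a false-positive singleton is
    any k=1 selection other than alternative-1; a false negative means the
    planted pair is absent from the final selection.
    """
    if replicates < 1:
        raise InvalidConfigError("replicates must be >= 1")
    config = config or PermutationConfig(n_permutations=1000, early_stop_hits=20)
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 10))
        for s in np.random.SeedSequence(spec.seed).spawn(replicates)
    ]
    if workers and workers > 1:
        records = Parallel(n_jobs=workers)(
            delayed(_run_replicate)(
                i, child_seeds[i], spec, alpha_single, alpha_pair, alpha2,
                config, cutoff_rule,
            )
            for i in range(replicates)
        )
    else:
        records = [
            _run_replicate(i, child_seeds[i], spec, alpha_single, alpha_pair,
                           alpha2, config, cutoff_rule)
            for i in range(replicates)
        ]
    return StudyReport(records=tuple(records), p=spec.p)


def summarize_fp_rates(report: StudyReport, p: int | None = None):
    """Worst-case false-positive probabilities over the study.

    Returns ``(max FP pairs / C(p,2), max FP singletons / p)``.
    """
    p = report.p if p is None else p
    n_pairs = p * (p - 1) // 2
    return (report.max_fp_pairs / n_pairs, report.max_fp_singletons / p)
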