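"""Kaplan-Meier plotting for stratified risk groups."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stratification import KMCurve, StratificationResult  # noqa: E402


def _step_xy(curve: KMCurve, t_max: float):
    xs, ys = [0.0], [1.0]
    for t, s in zip(curve.times, curve.survival):
        xs += [t, t]
        ys += [ys[-1], s]
    xs.append(t_max)
    ys.append(ys[-1])
    return np.asarray(xs), np.asarray(ys)


def km_plot(result: StratificationResult, ax=None, title: str | None = None):
    """Plot the high/low-risk Kaplan-Meier curves of one stratified tuple."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    t_max = max(
        [result.km_high.times.max(initial=0.0),
         result.km_low.times.max(initial=0.0)] +
        [c.max(initial=0.0) for c in
         (result.km_high.censor_times, result.km_low.censor_times)]
    )
    for curve, label, color in (
        (result.km_high, "high risk", "#c0392b"),
        (result.km_low, "low risk", "#2471a3"),
    ):
        xs, ys = _step_xy(curve, t_max)
        ax.plot(xs, ys, label=f"{label} (n={int(curve.at_risk.max(initial=0))})",
                color=color, lw=1.8)
        if curve.censor_times.size:
            cs = np.array([
                1.0 if curve.times.size == 0 else curve.survival_at(t)
                for t in curve.censor_times
            ])
            ax.plot(curve.censor_times, cs, "|", color=color, ms=9, mew=1.4)
    annot = (
        f"Q = {result.logrank_Q:.2f}\n"
        f"perm p = {result.perm_p:.4g}\n"
        f"C-index = {result.c_index:.3f}"
    )
    ax.text(0.02, 0.06, annot, transform=ax.transAxes, fontsize=9,
            va="bottom", bbox=dict(fc="white", ec="0.7", alpha=0.8))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="upper right", fontsize=9)
    ax.set_title(title or " + ".join(result.feature_ids))
    return ax


def save_km_plot(result: StratificationResult, path, title: str | None = None):
    ax = km_plot(result, title=title)
    fig = ax.figure
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
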