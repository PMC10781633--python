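"""Step-curve plotting: per-arm PBR curves and between-arm difference bands."""

from __future__ import annotations

import numpy as np

from .pbr import CurveBand, PbrResult
from .survival import StepCurve

__all__ = ["plot_pbr", "plot_difference"]


def _step_xy(curve: StepCurve, t_max: float | None = None):
    x = np.concatenate(([0.0], curve.times))
    y = np.concatenate(([curve.baseline], curve.estimate))
    if t_max is not None and (x.size == 0 or x[-1] < t_max):
        x = np.concatenate((x, [t_max]))
        y = np.concatenate((y, [y[-1]]))
    return x, y


def plot_pbr(
    results: dict[str, PbrResult],
    cumulative: dict[str, StepCurve] | None = None,
    ax=None,
):
    """Solid PBR curves per arm, optional dashed cumulative-responder curves."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t_max = max(
        (float(r.pbr.times[-1]) for r in results.values() if r.pbr.times.size), default=None
    )
    for arm, result in results.items():
        x, y = _step_xy(result.pbr, t_max)
        (line,) = ax.step(x, y, where="post", label=f"{arm} (PBR)")
        if cumulative and arm in cumulative:
            xc, yc = _step_xy(cumulative[arm], t_max)
            ax.step(
                xc, yc, where="post", linestyle="--", color=line.get_color(),
                label=f"{arm} (cumulative responders)",
            )
    ax.set_xlabel("Days since randomization")
    ax.set_ylabel("Probability of being in response")
    ax.set_ylim(-0.02, 1.0)
    ax.legend(loc="best", fontsize="small")
    return ax


def plot_difference(band: CurveBand, ax=None, label: str = "difference"):
    """Difference curve with its pointwise confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    x, y = _step_xy(band.curve)
    ax.step(x, y, where="post", color="black", label=label)
    xl = np.concatenate(([0.0], band.curve.times))
    lo = np.concatenate(([0.0], band.lower))
    hi = np.concatenate(([0.0], band.upper))
    ax.step(xl, lo, where="post", color="tab:blue", linewidth=0.9,
            label=f"{100 * (1 - band.alpha):.0f}% pointwise CI")
    ax.step(xl, hi, where="post", color="tab:blue", linewidth=0.9)
    ax.axhline(0.0, color="grey", linewidth=0.7)
    ax.set_xlabel("Days since randomization")
    ax.set_ylabel("Difference in probability of being in response")
    ax.legend(loc="best", fontsize="small")
    return ax
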