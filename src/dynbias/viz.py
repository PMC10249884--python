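"""Simple diagnostic figures (bias curves, psychometric functions)."""

from __future__ import annotations

import numpy as np

from .bias import BiasCurve


def plot_bias_curve(curve: BiasCurve, ax=None, label: str | None = None, **kw):
    """Aligned bias vs trials since switch with its error band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = np.isfinite(curve.bias)
    (line,) = ax.plot(curve.s_values[ok], curve.bias[ok], marker="o", label=label, **kw)
    band = np.isfinite(curve.ci_lo) & np.isfinite(curve.ci_hi)
    ax.fill_between(
        curve.s_values[band],
        curve.ci_lo[band],
        curve.ci_hi[band],
        alpha=0.2,
        color=line.get_color(),
    )
    ax.set_xlabel("trials since context switch")
    ax.set_ylabel("aligned bias (deg)")
    return ax


def plot_psychometric(summary, ax=None):
    """Fraction clockwise vs orientation per context from a
    psychometric_summary frame (diagnostic scatter of the fitted PSEs)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for _, row in summary.iterrows():
        if np.isfinite(row.get("pse_deg", np.nan)):
            ax.axvline(row["pse_deg"], ls="--", alpha=0.5)
    ax.axhline(0.5, color="k", lw=0.5)
    ax.set_xlabel("orientation (deg)")
    ax.set_ylabel("P(clockwise)")
    return ax
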