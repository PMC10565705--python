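"""Plotting: smoothed bias curves with the fitted model overlaid."""

from __future__ import annotations

import numpy as np

from .dogmodel import FitResult, smooth_curve

__all__ = ["plot_bias_curve"]


def plot_bias_curve(delta, error, fit: FitResult | None = None, window: float = 21.0,
                    ax=None, path=None):
    """Moving-average error curve (±1 SD band) with an optional model fit.

    The smoothed curve is for display only; any ``fit`` overlaid was
    estimated on the unsmoothed single-trial data.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.0, 3.2))
    curve = smooth_curve(delta, error, window=window)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(curve["delta"], curve["mean"], color="C0", lw=1.5, label="moving average")
    ax.fill_between(curve["delta"], curve["mean"] - curve["sd"],
                    curve["mean"] + curve["sd"], color="C0", alpha=0.15)
    if fit is not None:
        grid = np.linspace(-90.0, 90.0, 361)
        ax.plot(grid, fit.predict(grid), color="C3", lw=1.8,
                label=f"{fit.spec.display_name} fit")
    ax.set_xlabel("Δ (prior − current orientation, °)")
    ax.set_ylabel("adjustment error (°)")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
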