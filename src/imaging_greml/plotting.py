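"""Minimal plotting helpers for results objects (scatter + trend overlays)."""

from __future__ import annotations

import numpy as np

from .inference import TrendFit


def plot_trend(x, y, fit: TrendFit, ax=None, xlabel="", ylabel=""):
    """Scatter of per-ROI points with the fitted trend curve overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ax.scatter(x, y, s=18, color="tab:blue")
    grid = np.linspace(x.min(), x.max(), 200)
    powers = np.arange(len(fit.coefficients))
    curve = sum(c * grid**p for c, p in zip(fit.coefficients, powers))
    ax.plot(grid, curve, color="tab:red", lw=1.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"$R^2$ = {fit.r_squared:.2f}, p = {fit.p_value:.3g}")
    return ax


def plot_count_null(dist, ax=None):
    """Histogram of the Monte-Carlo count null with the observed count marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    counts = np.arange(dist.histogram.size)
    ax.bar(counts, dist.histogram / dist.n_realizations, color="tab:gray")
    ax.axvline(dist.observed_count, color="tab:red", lw=1.5)
    ax.set_xlabel("significant tests")
    ax.set_ylabel("null probability")
    ax.set_title(f"MC p = {dist.p_value:.3g}")
    return ax
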