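"""Optional matplotlib renderings of the standard figures.

Plots are a convenience layer; no data product depends on them.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .tetragram import ALL_TETRAGRAMS, BinnedStrategy, CHANCE_PCT, TetragramTable
from .timeseries import ACFResult

__all__ = ["tetragram_bar", "binned_heatmap", "acf_plot", "lag_plot"]


def tetragram_bar(table: TetragramTable, ax=None, title: str | None = None):
    """Tetragram frequency bars with the 6.25% chance line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    pcts = [table.pct(t) for t in ALL_TETRAGRAMS]
    ax.bar(range(16), pcts, color="steelblue")
    ax.axhline(CHANCE_PCT, ls="--", color="k", lw=1, label=f"chance {CHANCE_PCT:g}%")
    ax.set_xticks(range(16), ALL_TETRAGRAMS, rotation=90, fontsize=7)
    ax.set_ylabel("% of tetragrams")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def binned_heatmap(strategy: BinnedStrategy, ax=None):
    """Tetragram % per time bin as a heat map (bins × 16 tetragrams)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    mat = np.array([[tab.pct(t) for t in ALL_TETRAGRAMS] for tab in strategy.bins])
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(16), ALL_TETRAGRAMS, rotation=90, fontsize=7)
    ax.set_yticks(range(strategy.n_bins), [f"bin {b + 1}" for b in range(strategy.n_bins)])
    ax.figure.colorbar(im, ax=ax, label="% of tetragrams")
    return ax


def acf_plot(result: ACFResult, ax=None, title: str | None = None):
    """Stem plot of r(1..K) with the 95% band cone."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    lags = np.arange(1, result.max_lag + 1)
    ax.stem(lags, result.r)
    if result.lower is not None:
        ax.fill_between(lags, result.lower, result.upper, alpha=0.25, color="tab:blue")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("lag")
    ax.set_ylabel("ACF")
    if title:
        ax.set_title(title)
    return ax


def lag_plot(series: np.ndarray, lag: int = 1, ax=None):
    """Scatter of x(k) vs x(k + lag)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3.5))
    x = np.asarray(series, float)
    ax.scatter(x[:-lag], x[lag:], s=8, alpha=0.6)
    ax.set_xlabel("ω(k)")
    ax.set_ylabel(f"ω(k+{lag})")
    return ax
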