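"""Simple trend and loading figures for fitted DFA models."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_trends(trends: np.ndarray, years, path=None, labels=None):
    """Line plot of the (rotated) common trends over time."""
    trends = np.atleast_2d(trends)
    m = trends.shape[0]
    fig, axes = plt.subplots(m, 1, figsize=(7, 2.2 * m), sharex=True, squeeze=False)
    for j, ax in enumerate(axes[:, 0]):
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.plot(years, trends[j], lw=1.5)
        ax.set_ylabel(labels[j] if labels else f"trend {j + 1}")
    axes[-1, 0].set_xlabel("year")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_loadings(Z: np.ndarray, series_labels, path=None, threshold: float = 0.2):
    """Bar chart of loadings per trend; series in panel (geographic) order.

    Loadings inside +/- threshold are drawn faded — they are conventionally
    not interpreted.
    """
    Z = np.atleast_2d(Z)
    n, m = Z.shape
    fig, axes = plt.subplots(1, m, figsize=(3.2 * m, 0.25 * n + 1.5),
                             sharey=True, squeeze=False)
    ypos = np.arange(n)[::-1]
    for j, ax in enumerate(axes[0]):
        strong = np.abs(Z[:, j]) > threshold
        colors = np.where(strong, "C0", "0.8")
        ax.barh(ypos, Z[:, j], color=colors)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.axvline(threshold, color="0.6", lw=0.6, ls="--")
        ax.axvline(-threshold, color="0.6", lw=0.6, ls="--")
        ax.set_title(f"trend {j + 1}")
    axes[0, 0].set_yticks(ypos)
    axes[0, 0].set_yticklabels(series_labels, fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
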