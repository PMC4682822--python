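"""Plots for layout comparisons: scatter, three-bar summary, displacement histogram."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_layout_comparison", "plot_three_bar", "plot_displacement_hist"]


def plot_layout_comparison(real, opt, fixed_mask, ax=None, title=None):
    """Anchors as red dots, real free positions as black crosses, optima as
    blue circles (anterior left, posterior right; ventral bottom)."""
    real = np.asarray(real, float)
    opt = np.asarray(opt, float)
    fixed = np.asarray(fixed_mask, bool)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    ax.plot(real[fixed, 0], real[fixed, 1], "r.", ms=4, label="anchors (real)")
    ax.plot(real[~fixed, 0], real[~fixed, 1], "kx", ms=5, label="free (real)")
    ax.plot(opt[~fixed, 0], opt[~fixed, 1], "bo", mfc="none", ms=5,
            label="free (optimal)")
    ax.set_xlabel("anterior-posterior (mm)")
    ax.set_ylabel("ventral-dorsal (mm)")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper center", ncol=3, fontsize=8)
    return ax


def plot_three_bar(reports, ax=None):
    """Optimal / real / random-mean TWL bars per cost function."""
    if ax is None:
        _, ax = plt.subplots()
    labels = [r.norm for r in reports]
    x = np.arange(len(reports))
    ax.bar(x - 0.25, [r.twl_opt for r in reports], 0.25, label="optimal",
           color="tab:blue")
    ax.bar(x, [r.twl_real for r in reports], 0.25, label="real",
           color="tab:green")
    rand = [r.twl_random_mean or 0.0 for r in reports]
    ax.bar(x + 0.25, rand, 0.25, label="random mean", color="tab:red")
    ax.set_xticks(x, labels)
    ax.set_ylabel("total wiring length")
    ax.legend()
    return ax


def plot_displacement_hist(summary, ax=None):
    """Histogram of real-vs-optimal displacements (mm) at the summary's bins."""
    if ax is None:
        _, ax = plt.subplots()
    edges = np.asarray(summary.bin_edges)
    ax.bar(edges[:-1], summary.counts, width=summary.bin_width, align="edge",
           color="tab:blue", edgecolor="k")
    ax.set_xlabel("real-to-optimal displacement (mm)")
    ax.set_ylabel("number of neurons")
    return ax
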