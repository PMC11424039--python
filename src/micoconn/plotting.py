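"""Diagnostic plots for deconvolution results and connectomes."""

from __future__ import annotations

import numpy as np

from .connectome import Connectome
from .deconvolution import DeconvolutionResults

__all__ = ["plot_recovered_weights", "plot_connectome_matrix", "plot_age_relationship"]


def plot_recovered_weights(results: DeconvolutionResults, x_true=None, ax=None):
    """Histogram of recovered IASF weights, optionally against ground truth."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if x_true is not None:
        ax.scatter(np.asarray(x_true), results.x, s=12, alpha=0.7)
        lim = max(float(np.max(x_true)), float(results.x.max()), 1e-6)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("true IASF")
        ax.set_ylabel("recovered IASF")
    else:
        ax.hist(results.x[results.kept_mask], bins=30)
        ax.set_xlabel("recovered IASF")
        ax.set_ylabel("streamlines")
    ax.set_title("streamline deconvolution")
    return ax


def plot_connectome_matrix(conn: Connectome, ax=None, cmap="viridis"):
    """Heatmap of the weighted adjacency matrix, nodes grouped by network."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(conn.matrix, cmap=cmap)
    ax.figure.colorbar(im, ax=ax, label=f"{conn.weighting} edge weight")
    if conn.groups:
        bounds = []
        groups = [conn.groups.get(int(r), "") for r in conn.labels]
        for i in range(1, len(groups)):
            if groups[i] != groups[i - 1]:
                bounds.append(i - 0.5)
        for b in bounds:
            ax.axhline(b, color="w", lw=0.5)
            ax.axvline(b, color="w", lw=0.5)
    ax.set_xlabel("ROI")
    ax.set_ylabel("ROI")
    return ax


def plot_age_relationship(metric_table, metric: str, group: str, ax=None):
    """Scatter of one network measure against age with an OLS line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = metric_table[metric_table["group"] == group].dropna(subset=[metric])
    ax.scatter(df["age"], df[metric], s=14, alpha=0.7)
    if len(df) >= 2:
        slope, intercept = np.polyfit(df["age"], df[metric], 1)
        xs = np.linspace(df["age"].min(), df["age"].max(), 20)
        ax.plot(xs, slope * xs + intercept, "r-", lw=1)
    ax.set_xlabel("age (years)")
    ax.set_ylabel(metric)
    ax.set_title(group)
    return ax
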