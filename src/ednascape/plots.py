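"""Publication-style figures for validation results.

Each function returns a matplotlib Figure; callers save it themselves
(``fig.savefig(path)``).  The three figures mirror how whole-network
eDNA assessments are usually presented: per-taxon confusion stacks,
measured-vs-predicted index regression with its 1:1 reference, and the
index-vs-habitat-class association with the fitted mean-response band.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .validate import HabitatAssociation, RegressionSummary  # noqa: E402

__all__ = ["plot_confusion", "plot_regression", "plot_habitat"]

_CONF_COLORS = {"TP": "#2066a8", "TN": "#8ec1da", "FN": "#d47264",
                "FP": "#ae282c"}


def plot_confusion(confusion: pd.DataFrame) -> plt.Figure:
    """Stacked per-taxon confusion fractions, ordered by accuracy."""
    df = confusion.sort_values("accuracy", ascending=False).reset_index(drop=True)
    totals = df[["TP", "TN", "FN", "FP"]].sum(axis=1).to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(df)), 4))
    bottom = np.zeros(len(df))
    for part in ("TP", "TN", "FN", "FP"):
        frac = df[part].to_numpy() / totals
        ax.bar(df["taxon"], frac, bottom=bottom, label=part,
               color=_CONF_COLORS[part], width=0.8)
        bottom += frac
    ax.set_ylabel("fraction of matched sites")
    ax.set_ylim(0, 1)
    ax.legend(ncols=4, loc="lower left", fontsize="small")
    ax.tick_params(axis="x", rotation=90, labelsize="x-small")
    fig.tight_layout()
    return fig


def plot_regression(predicted: np.ndarray, measured: np.ndarray,
                    summary: RegressionSummary) -> plt.Figure:
    """Measured index vs predicted index with OLS fit and 1:1 line."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=25, color="#2066a8", zorder=3)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, summary.intercept + summary.slope * grid, color="#ae282c",
            label=(f"fit: slope {summary.slope:.2f} ± {summary.slope_ci95:.2f}"
                   f", R² = {summary.r2:.2f}"))
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    ax.plot([lo, hi], [lo, hi], ls="--", color="grey", label="1:1")
    ax.set_xlabel("predicted IBCH")
    ax.set_ylabel("measured IBCH")
    ax.legend(fontsize="small")
    fig.tight_layout()
    return fig


def plot_habitat(assoc: HabitatAssociation) -> plt.Figure:
    """Column-normalised index histogram per habitat class with the 95%
    mean-response band of the fitted trend."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    hist = assoc.histogram
    classes = hist.columns.to_numpy(dtype=float)
    half = (classes[1] - classes[0]) / 2 if len(classes) > 1 else 0.5
    mesh = ax.pcolormesh(
        np.append(classes - half, classes[-1] + half),
        np.arange(len(hist.index) + 1) - 0.5,
        hist.to_numpy(), cmap="Blues", shading="flat")
    fig.colorbar(mesh, ax=ax, label="fraction within habitat class")
    ax.plot(assoc.band["habitat"], assoc.band["mean"], color="#ae282c",
            label=f"trend (R² = {assoc.r2:.2f})")
    ax.fill_between(assoc.band["habitat"], assoc.band["lower"],
                    assoc.band["upper"], color="#ae282c", alpha=0.25,
                    label="95% mean band")
    ax.set_xlabel("habitat-status class (worst → best)")
    ax.set_ylabel("predicted IBCH")
    ax.legend(fontsize="small", loc="upper left")
    fig.tight_layout()
    return fig
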