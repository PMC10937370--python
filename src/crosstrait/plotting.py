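"""Scatter of bivariate effects with class probability ellipses."""

from __future__ import annotations

import numpy as np

from .linemodels import LineModel, classify, prior_covariance
from .pairs import PairsLike, as_pairs_frame

__all__ = ["plot_classification"]

_CLASS_COLORS = ("#d62728", "#1f77b4", "#2ca02c", "#9467bd")


def _ellipse_path(cov: np.ndarray, prob: float = 0.95, n: int = 200):
    from scipy.stats import chi2

    radius = np.sqrt(chi2.ppf(prob, df=2))
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    theta = np.linspace(0.0, 2.0 * np.pi, n)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    return radius * circle * np.sqrt(vals) @ vecs.T


def plot_classification(pairs: PairsLike, models: list[LineModel],
                        threshold: float = 0.95, ax=None,
                        xlabel: str = "effect in trait X (log OR)",
                        ylabel: str = "effect in trait Y (log OR)"):
    """Scatter effect pairs colored by assigned class with 95% ellipses.

    Each class's dotted ellipse is the 95% probability region of its
    fitted bivariate effect-size prior; unassigned variants are gray.
    Returns the matplotlib Axes.
    """
    import matplotlib
    if ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    df = as_pairs_frame(pairs)
    assigned = classify(df, models, threshold=threshold)["assigned_label"]
    colors = {m.label: _CLASS_COLORS[i % len(_CLASS_COLORS)]
              for i, m in enumerate(models)}
    colors["unassigned"] = "0.6"
    for label in list(colors):
        sel = assigned == label
        if sel.any():
            ax.errorbar(df.loc[sel, "beta_x"], df.loc[sel, "beta_y"],
                        xerr=df.loc[sel, "se_x"], yerr=df.loc[sel, "se_y"],
                        fmt="o", ms=4, color=colors[label], label=label,
                        elinewidth=0.8, capsize=0)
    for m in models:
        path = _ellipse_path(prior_covariance(m), prob=0.95)
        ax.plot(path[:, 0], path[:, 1], linestyle=":", color=colors[m.label],
                lw=1.2)
    ax.axhline(0, color="0.8", lw=0.6)
    ax.axvline(0, color="0.8", lw=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    return ax
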