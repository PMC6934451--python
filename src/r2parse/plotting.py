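"""Diagnostic figures: the R²-R² fit plot and the R²-Δ² family plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .association import AssociationProfile
from .families import scale_plot_lines
from .model_search import ISNPModel

#: per-family color cycle (first three match the conventional red/green/black
#: family palette of the method's figures)
FAMILY_COLORS = ["red", "green", "black", "orange"]

SIGNIFICANT_COLOR = "#2060c0"
NONSIG_COLOR = "#b0b0b0"
PREDICTED_COLOR = "#103070"


def _order_and_bars(profile: AssociationProfile, p_threshold: float):
    order = np.argsort(
        profile.snps["pos"].to_numpy(), kind="stable"
    )  # genomic order on the x axis
    colors = [
        SIGNIFICANT_COLOR if profile.p_val[i] < p_threshold else NONSIG_COLOR
        for i in order
    ]
    return order, colors


def plot_r2_r2(
    profile: AssociationProfile,
    model: ISNPModel,
    path: str | None = None,
    *,
    p_threshold: float = 0.05,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Estimated R² bars (colored by nominal significance) + predicted line."""
    if not model.valid or model.predicted_r2 is None:
        raise ValueError("model has no predicted values")
    if len(model.predicted_r2) != profile.n_snps:
        raise ValueError("model predictions do not match the profile SNP set")
    order, colors = _order_and_bars(profile, p_threshold)
    x = np.arange(profile.n_snps)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, profile.n_snps / 8), 3.2))
    ax.bar(x, profile.r2_est[order], color=colors, width=0.8, label="estimated R²")
    ax.plot(
        x,
        model.predicted_r2[order],
        color=PREDICTED_COLOR,
        lw=1.2,
        label="predicted R²",
    )
    ax.set_xlabel("ROI SNPs (genomic order)")
    ax.set_ylabel("R²")
    ax.set_title("R²-R² plot")
    ax.annotate(
        f"adj R²(model) = {model.adj_r2_model:.3f}\n"
        f"iSNPs: {', '.join(model.isnp_ids)}",
        xy=(0.02, 0.95),
        xycoords="axes fraction",
        va="top",
        fontsize=8,
    )
    ax.legend(loc="upper right", fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_r2_delta2(
    profile: AssociationProfile,
    model: ISNPModel,
    families: pd.DataFrame,
    path: str | None = None,
    *,
    p_threshold: float = 0.05,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Estimated R² bars + one scaled r² LD line per iSNP family."""
    if len(model.isnp_ids) > 4:
        raise ValueError("at most 4 iSNP families can be drawn")
    order, colors = _order_and_bars(profile, p_threshold)
    heights = scale_plot_lines(profile, model)
    x = np.arange(profile.n_snps)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, profile.n_snps / 8), 3.2))
    ax.bar(x, profile.r2_est[order], color=colors, width=0.8)
    for k, isnp in enumerate(model.isnp_ids):
        ax.plot(
            x,
            heights[order, k],
            color=FAMILY_COLORS[k],
            lw=1.0,
            label=f"family {isnp}",
        )
    ax.set_xlabel("ROI SNPs (genomic order)")
    ax.set_ylabel("R² / scaled Δ²")
    ax.set_title("R²-Δ² plot")
    ax.legend(loc="upper right", fontsize=8)
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
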