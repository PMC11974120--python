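"""Notched box-plot figures of the contact-level biomarker comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .features import FEATURE_NAMES
from .signal import BAND_ORDER

__all__ = ["plot_group_comparisons"]

_FEATURE_LABEL = {"ll": "Line length (z)", "apen": "ApEn (z)"}


def plot_group_comparisons(
    contact_means: pd.DataFrame,
    contacts: pd.DataFrame,
    outcomes: pd.Series,
    comparisons: pd.DataFrame | None = None,
    path=None,
):
    """One panel per (feature, group): notched boxes of TC / non-TC-pre /
    non-TC-post contact means per band, with significance stars from the
    comparison table when provided."""
    cm = contact_means.merge(
        contacts[["patient_id", "channel_name", "is_tc"]],
        on=["patient_id", "channel_name"], how="left")
    cm["outcome"] = cm.patient_id.map(outcomes)
    groups = [g for g in ("responder", "non_responder")
              if (cm.outcome == g).any()]
    fig, axes = plt.subplots(
        len(FEATURE_NAMES), len(groups),
        figsize=(5.5 * len(groups), 3.2 * len(FEATURE_NAMES)),
        squeeze=False)
    for fi, feat in enumerate(FEATURE_NAMES):
        for gi, group in enumerate(groups):
            ax = axes[fi][gi]
            gdf = cm[cm.outcome == group]
            data, positions, labels = [], [], []
            for bi, band in enumerate(BAND_ORDER):
                sub = gdf[gdf.band == band]
                arms = [
                    sub[(sub.period == "pre") & sub.is_tc][feat],
                    sub[(sub.period == "pre") & ~sub.is_tc][feat],
                    sub[(sub.period == "post") & ~sub.is_tc][feat],
                ]
                for ai, arm in enumerate(arms):
                    if len(arm):
                        data.append(arm.to_numpy())
                        positions.append(bi * 4 + ai)
                labels.append(band)
            if not data:
                continue
            bp = ax.boxplot(data, positions=positions, notch=True,
                            widths=0.7, patch_artist=True,
                            flierprops=dict(markersize=2))
            palette = ["#c44e52", "#4c72b0", "#55a868"]
            for patch, pos in zip(bp["boxes"], positions):
                patch.set_facecolor(palette[pos % 4 % 3])
                patch.set_alpha(0.7)
            ax.set_xticks([bi * 4 + 1 for bi in range(len(BAND_ORDER))])
            ax.set_xticklabels(labels, fontsize=8)
            ax.set_title(f"{_FEATURE_LABEL[feat]} - {group}", fontsize=9)
            if comparisons is not None and not comparisons.empty:
                sig = comparisons[
                    (comparisons.group == group + "s") &
                    (comparisons.feature == feat) &
                    comparisons.significant]
                for _, row in sig.iterrows():
                    bi = BAND_ORDER.index(row.band)
                    y = max(d.max() for d in data) * 1.05
                    x = bi * 4 + (0.5 if row.design == "tc_vs_ntc_pre"
                                  else 1.5)
                    ax.text(x, y, "*", ha="center", fontsize=11)
    handles = [plt.Rectangle((0, 0), 1, 1, fc=c, alpha=0.7)
               for c in ["#c44e52", "#4c72b0", "#55a868"]]
    fig.legend(handles, ["TC (pre)", "non-TC pre", "non-TC post"],
               loc="lower center", ncol=3, fontsize=8)
    fig.tight_layout(rect=(0, 0.05, 1, 1))
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
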