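"""Directional nonparametric group comparisons of the contact-level
biomarkers.

Two designs, run separately for responders and non-responders:

* ``tc_vs_ntc_pre`` - pre-operative contact means of thermocoagulated vs
  non-thermocoagulated contacts, Mann-Whitney U, one-tailed for TC > non-TC
  (the direction in which elevated interictal activity marks the ablated
  tissue);
* ``pre_vs_post_ntc`` - paired pre/post contact means of non-TC contacts,
  Wilcoxon signed-rank; both one-tailed directions are evaluated and the
  smaller is reported with its direction label.

Bonferroni correction is applied within each group x design family of
2 features x 4 bands = 8 tests; significance is p_adjusted < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .features import FEATURE_NAMES
from .signal import BAND_ORDER

__all__ = [
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "bonferroni",
    "run_comparisons",
    "ComparisonResult",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
EXACT_MWU_MAX_N = 8
EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class ComparisonResult:
    group: str  # responders | non_responders
    design: str  # tc_vs_ntc_pre | pre_vs_post_ntc
    band: str
    feature: str
    statistic: float
    p_raw: float
    p_adjusted: float
    tail: str  # right | left
    significant: bool
    n_x: int
    n_y: int


def _has_ties(*arrays: np.ndarray) -> bool:
    pooled = np.concatenate(arrays)
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, tail: str = "right"
) -> tuple[float, float]:
    """One-tailed Mann-Whitney U test of x against y.

    ``tail="right"`` tests the alternative x stochastically greater than y;
    ``tail="left"`` the reverse. Exact enumeration for tie-free samples with
    at most 8 per arm, tie-corrected normal approximation otherwise.
    Returns (U of x, one-tailed p).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both arms must be non-empty")
    if tail not in ("right", "left"):
        raise ValueError("tail must be 'right' or 'left'")
    alternative = "greater" if tail == "right" else "less"
    small = max(x.size, y.size) <= EXACT_MWU_MAX_N
    method = "exact" if small and not _has_ties(x, y) else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(
    pre: np.ndarray, post: np.ndarray, tail: str = "right"
) -> tuple[float, float]:
    """One-tailed Wilcoxon signed-rank test on paired values.

    ``tail="right"`` tests pre > post. Zero differences are discarded;
    fewer than 5 informative pairs (or all-zero differences) is an error.
    Exact enumeration for tie-free samples of at most 20 informative pairs,
    normal approximation with tie correction otherwise.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    if tail not in ("right", "left"):
        raise ValueError("tail must be 'right' or 'left'")
    d = pre - post
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: no information")
    if d.size < 5:
        raise ValueError(
            f"need >= 5 non-zero paired differences (got {d.size})")
    alternative = "greater" if tail == "right" else "less"
    tie_free = len(np.unique(np.abs(d))) == d.size
    method = "exact" if (d.size <= EXACT_WILCOXON_MAX_N and tie_free) else "approx"
    res = sstats.wilcoxon(d, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_raw, m_corr: int):
    """Bonferroni adjustment: min(1, m_corr * p)."""
    if m_corr < 1:
        raise ValueError("m_corr must be >= 1")
    p = np.asarray(p_raw, dtype=np.float64)
    out = np.minimum(1.0, m_corr * p)
    return float(out) if np.isscalar(p_raw) else out


def run_comparisons(
    contact_means: pd.DataFrame,
    contacts: pd.DataFrame,
    outcomes: pd.Series,
    bands: tuple[str, ...] = BAND_ORDER,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run both comparison designs per outcome group on normalized contact
    means; returns a tidy frame of :class:`ComparisonResult` rows.

    The Bonferroni family is the 2 x len(bands) tests within each
    group x design. Patients are pooled within a group (contact-level
    analysis). A group with no contacts is skipped with a warning.
    """
    cm = contact_means.merge(
        contacts[["patient_id", "channel_name", "is_tc"]],
        on=["patient_id", "channel_name"], how="left",
    )
    cm["outcome"] = cm.patient_id.map(outcomes)
    results: list[ComparisonResult] = []
    m_corr = len(FEATURE_NAMES) * len(bands)
    for group_label, group_name in (
        ("responder", "responders"),
        ("non_responder", "non_responders"),
    ):
        gdf = cm[cm.outcome == group_label]
        if gdf.empty:
            logger.warning("group %s has no contacts; skipped", group_name)
            continue
        fam: list[tuple] = []
        # design 1: pre-op TC vs non-TC, one-tailed TC > non-TC
        pre = gdf[gdf.period == "pre"]
        for feat in FEATURE_NAMES:
            for band in bands:
                sub = pre[pre.band == band]
                tc = sub.loc[sub.is_tc, feat].to_numpy()
                ntc = sub.loc[~sub.is_tc, feat].to_numpy()
                if tc.size == 0 or ntc.size == 0:
                    logger.warning(
                        "design tc_vs_ntc_pre: empty arm for %s/%s/%s",
                        group_name, band, feat)
                    continue
                stat, p = mann_whitney_u(tc, ntc, tail="right")
                fam.append((group_name, "tc_vs_ntc_pre", band, feat, stat, p,
                            "right", tc.size, ntc.size))
        _append_family(results, fam, m_corr, alpha)
        fam = []
        # design 2: paired pre/post on non-TC contacts, both tails evaluated
        ntc_df = gdf[~gdf.is_tc.astype(bool)]
        wide = ntc_df.pivot_table(
            index=["patient_id", "channel_name", "band"], columns="period",
            values=list(FEATURE_NAMES))
        for feat in FEATURE_NAMES:
            for band in bands:
                try:
                    sub = wide.xs(band, level="band")[feat][["pre", "post"]]
                except KeyError:
                    logger.warning(
                        "design pre_vs_post_ntc: missing period data for "
                        "%s/%s/%s; skipped", group_name, band, feat)
                    continue
                sub = sub.dropna()
                if sub.empty:
                    continue
                pre_v = sub["pre"].to_numpy()
                post_v = sub["post"].to_numpy()
                try:
                    stat_r, p_r = wilcoxon_signed_rank(pre_v, post_v,
                                                       tail="right")
                    stat_l, p_l = wilcoxon_signed_rank(pre_v, post_v,
                                                       tail="left")
                except ValueError as exc:
                    logger.warning(
                        "design pre_vs_post_ntc %s/%s/%s skipped: %s",
                        group_name, band, feat, exc)
                    continue
                if p_r <= p_l:
                    stat, p, tail = stat_r, p_r, "right"
                else:
                    stat, p, tail = stat_l, p_l, "left"
                fam.append((group_name, "pre_vs_post_ntc", band, feat, stat,
                            p, tail, len(sub), len(sub)))
        _append_family(results, fam, m_corr, alpha)
    return pd.DataFrame([r.__dict__ for r in results])


def _append_family(
    results: list[ComparisonResult],
    fam: list[tuple],
    m_corr: int,
    alpha: float,
) -> None:
    for (group, design, band, feat, stat, p, tail, n_x, n_y) in fam:
        p_adj = bonferroni(p, m_corr)
        results.append(
            ComparisonResult(
                group=group, design=design, band=band, feature=feat,
                statistic=stat, p_raw=p, p_adjusted=p_adj, tail=tail,
                significant=bool(p_adj < alpha), n_x=n_x, n_y=n_y,
            )
        )
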