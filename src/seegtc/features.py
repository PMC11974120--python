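"""Window-level electrophysiological biomarkers and their normalization.

Two features per 10 s window and band:

* **Line length (LL)** - the summed absolute first difference
  ``sum_i |x_i - x_{i-1}|`` (microvolts); tracks signal amplitude and
  frequency content. Reported as the raw sum: within-subject z-scoring
  makes the 1/(N-1) convention irrelevant and all windows share one N.
* **Approximate entropy (ApEn)** - Pincus regularity statistic
  ``Phi^m(r) - Phi^{m+1}(r)`` with Chebyshev-distance template matching and
  self-matches included; higher = more irregular. Parameters default to the
  field-standard m = 2, r = 0.2 x window SD; the SD-proportional tolerance
  makes ApEn invariant to affine amplitude changes.

Features live in a long-form table keyed by (patient, channel, period, band,
window) and are normalized by within-subject z-scoring: per (patient, band,
feature), the pooled mean/SD over *all* of that patient's rows - both
periods, all contacts, all windows - so pre/post contrasts survive
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._apen import apen_counts
from .signal import BAND_ORDER, WindowedSignal

__all__ = [
    "ApEnParams",
    "line_length",
    "approximate_entropy",
    "compute_features",
    "zscore_within_subject",
    "contact_average",
    "FEATURE_NAMES",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("ll", "apen")

KEY_COLS = ["patient_id", "channel_name", "period", "band", "window"]


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy parameters: embedding dimension m and tolerance
    r = r_factor x window sample SD."""

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("r_factor must be positive")


def line_length(x: np.ndarray) -> float:
    """Summed absolute first difference of a window (microvolts)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("line_length needs a 1-D vector of >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def approximate_entropy(x: np.ndarray, params: ApEnParams = ApEnParams()) -> float:
    """Classic approximate entropy (nats) of one window.

    A flat window (zero SD) has no new patterns; its ApEn is defined as 0
    (with a logged warning) rather than an error.
    """
    x = np.asarray(x, dtype=np.float64)
    m = params.m
    if x.ndim != 1 or x.size <= m + 1:
        raise ValueError(f"approximate_entropy needs > m+1 = {m + 1} samples")
    sd = float(x.std())
    if sd == 0.0:
        logger.warning("flat window: ApEn defined as 0")
        return 0.0
    r = params.r_factor * sd
    cm, cm1 = apen_counts(x, m, r)
    n = x.size
    phi_m = float(np.mean(np.log(cm / (n - m + 1))))
    phi_m1 = float(np.mean(np.log(cm1 / (n - m))))
    return phi_m - phi_m1


def compute_features(
    windowed: dict[str, WindowedSignal],
    contacts: pd.DataFrame,
    patient_id: str,
    period: str,
    params: ApEnParams = ApEnParams(),
) -> pd.DataFrame:
    """One row of (LL, ApEn) per (channel, band, window) for one
    patient-period.

    ``windowed`` maps band name -> :class:`WindowedSignal` (all four bands
    required, identical channel sets)."""
    missing_bands = [b for b in BAND_ORDER if b not in windowed]
    if missing_bands:
        raise ValueError(f"missing bands: {missing_bands}")
    ref_channels = set(windowed[BAND_ORDER[0]].windows)
    for b in BAND_ORDER[1:]:
        if set(windowed[b].windows) != ref_channels:
            diff = set(windowed[b].windows) ^ ref_channels
            raise ValueError(
                f"band {b!r} channel set differs (e.g. {sorted(diff)[:3]})")
    rows = []
    for band in BAND_ORDER:
        ws = windowed[band]
        for ch, arr in ws.windows.items():
            idx = ws.window_indices[ch]
            for w_pos, w_index in enumerate(idx):
                x = arr[w_pos]
                rows.append(
                    (patient_id, ch, period, band, int(w_index),
                     line_length(x), approximate_entropy(x, params))
                )
    df = pd.DataFrame(rows, columns=KEY_COLS + ["ll", "apen"])
    df.attrs["normalized"] = False
    return df


def zscore_within_subject(features: pd.DataFrame) -> pd.DataFrame:
    """Within-subject z-scoring: per (patient, band, feature), subtract the
    pooled mean and divide by the pooled SD over all of that patient's rows
    (both periods, all contacts, all windows). Idempotent up to numerical
    tolerance; errors on a zero-SD group."""
    df = features.copy()
    for feat in FEATURE_NAMES:
        grouped = df.groupby(["patient_id", "band"])[feat]
        mean = grouped.transform("mean")
        sd = grouped.transform("std")
        bad = sd == 0
        if bad.any():
            key = df.loc[bad, ["patient_id", "band"]].iloc[0]
            raise ValueError(
                f"zero pooled SD for feature {feat!r} in group "
                f"({key.patient_id}, {key.band})"
            )
        df[feat] = (df[feat] - mean) / sd
    df.attrs["normalized"] = True
    return df


def contact_average(features: pd.DataFrame) -> pd.DataFrame:
    """Mean over windows per (patient, channel, period, band); the
    contact-level values used by the paired statistics and the prediction
    features. Expects the normalized table."""
    if not features.attrs.get("normalized", False):
        logger.warning("contact_average called on a non-normalized table")
    out = (
        features.groupby(["patient_id", "channel_name", "period", "band"],
                         as_index=False)[list(FEATURE_NAMES)]
        .mean()
    )
    out.attrs["normalized"] = features.attrs.get("normalized", False)
    return out
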