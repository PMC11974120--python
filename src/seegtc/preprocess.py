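"""Preprocessing of interictal SEEG segments.

Fixed pipeline order (logged in provenance, deterministic):

    average reference -> artifact masking -> resample -> notch -> band
    filter -> windowing

Design notes
------------
* Resampling precedes filtering so that every patient's band filters share
  one design at 500 Hz; 1000 and 2000 Hz inputs are polyphase-resampled,
  512 Hz inputs pass through at their native rate (Nyquist 256 Hz still
  covers the 80-250 Hz ripple band).
* Filters are zero-phase forward-backward IIR: 4th-order Butterworth
  band-passes, second-order notches with Q = 30 at 50 Hz and odd harmonics
  strictly below Nyquist. A band whose upper edge reaches Nyquist degrades
  to a high-pass at its lower edge (a band-pass edge at Nyquist is
  unrealizable).
* Artifact rejection is an input span list (rejection was manual in the
  emulated workflow), honoured at window extraction: a window overlapping a
  masked span on a channel is dropped for that channel.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal import BandSpec, CANONICAL_BANDS, Recording, WindowedSignal

__all__ = [
    "average_reference",
    "reject_artifacts",
    "resample_to_500",
    "notch_power_line",
    "band_filter",
    "extract_windows",
    "drop_tc_channels_post",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)

TARGET_FS = 500.0
POWER_LINE_HZ = 50.0
NOTCH_Q = 30.0
BUTTER_ORDER = 4
WINDOW_S_DEFAULT = 10.0
TOTAL_S_DEFAULT = 200.0


def average_reference(rec: Recording) -> Recording:
    """Re-reference each channel against the instantaneous across-channel
    mean. Undefined (error) for fewer than two channels."""
    if rec.n_channels < 2:
        raise ValueError(
            "average reference needs >= 2 channels "
            f"(got {rec.n_channels})"
        )
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data)


def _normalize_spans(
    spans: list[tuple[float, float]], duration_s: float
) -> list[tuple[float, float]]:
    """Clip to [0, duration), drop empty, merge overlaps; intervals are
    half-open [start, end)."""
    clipped = []
    for start, end in spans:
        if end < start:
            raise ValueError(f"span end {end} before start {start}")
        s, e = max(0.0, float(start)), min(float(duration_s), float(end))
        if e > s:
            clipped.append((s, e))
    clipped.sort()
    merged: list[tuple[float, float]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def reject_artifacts(
    rec: Recording, bad_spans: list[tuple[str, float, float]]
) -> Recording:
    """Attach reviewer-marked artifact spans ``(channel, start_s, end_s)``
    to the recording; overlapping or out-of-range spans are normalized.
    The data are untouched - masked windows are dropped at extraction."""
    by_channel: dict[str, list[tuple[float, float]]] = {}
    for ch, start, end in bad_spans:
        if ch not in rec.channel_names:
            raise KeyError(f"artifact span names unknown channel {ch!r}")
        by_channel.setdefault(ch, []).append((start, end))
    spans = {ch: _normalize_spans(v, rec.duration_s)
             for ch, v in by_channel.items()}
    for ch, v in spans.items():
        covered = sum(e - s for s, e in v)
        if covered >= rec.duration_s:
            logger.warning(
                "channel %s fully masked by artifact spans; it will "
                "contribute no windows", ch)
    merged = dict(rec.artifact_spans)
    for ch, v in spans.items():
        merged[ch] = _normalize_spans(merged.get(ch, []) + v, rec.duration_s)
    return rec.copy_with(artifact_spans=merged)


def resample_to_500(rec: Recording) -> Recording:
    """Polyphase anti-aliased resampling of 1000/2000 Hz inputs to 500 Hz;
    inputs already at <= 512 Hz pass through at their native rate."""
    fs = rec.fs
    if fs in (1000.0, 2000.0):
        frac = Fraction(int(TARGET_FS), int(fs))
        data = sps.resample_poly(rec.data, frac.numerator, frac.denominator,
                                 axis=1)
        return rec.copy_with(data=data, fs=TARGET_FS)
    if fs <= 512.0:
        return rec
    warnings.warn(
        f"unexpected sampling rate {fs} Hz; resampling to {TARGET_FS} Hz",
        stacklevel=2,
    )
    frac = Fraction(int(TARGET_FS), int(fs)).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.copy_with(data=data, fs=TARGET_FS)


def notch_power_line(
    rec: Recording,
    base_hz: float = POWER_LINE_HZ,
    q: float = NOTCH_Q,
) -> Recording:
    """Zero-phase notches at ``base_hz`` and its odd harmonics strictly
    below Nyquist (50/150/250 Hz where realizable)."""
    nyq = rec.fs / 2.0
    freqs = [base_hz * k for k in (1, 3, 5) if base_hz * k < nyq]
    data = rec.data.astype(np.float64, copy=True)
    for f0 in freqs:
        b, a = sps.iirnotch(f0, q, fs=rec.fs)
        data = sps.filtfilt(b, a, data, axis=1)
    return rec.copy_with(data=data)


def band_filter(rec: Recording, band: BandSpec) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass for ``band``.

    If the band's upper edge reaches Nyquist the filter degrades to a
    high-pass at the lower edge. A band lying entirely above Nyquist is an
    error naming the band and sampling rate.
    """
    nyq = rec.fs / 2.0
    if band.low_hz >= nyq:
        raise ValueError(
            f"band {band.name!r} [{band.low_hz}, {band.high_hz}] Hz is "
            f"above Nyquist ({nyq} Hz) at fs={rec.fs}"
        )
    if band.high_hz >= nyq:
        sos = sps.butter(BUTTER_ORDER, band.low_hz, btype="highpass",
                         fs=rec.fs, output="sos")
    else:
        sos = sps.butter(BUTTER_ORDER, [band.low_hz, band.high_hz],
                         btype="bandpass", fs=rec.fs, output="sos")
    data = sps.sosfiltfilt(sos, rec.data.astype(np.float64, copy=False),
                           axis=1)
    return rec.copy_with(data=data)


def extract_windows(
    rec: Recording,
    band: BandSpec,
    window_s: float = WINDOW_S_DEFAULT,
    total_s: float = TOTAL_S_DEFAULT,
) -> WindowedSignal:
    """Cut non-overlapping ``window_s`` windows from the start of usable
    signal, up to ``total_s / window_s`` windows per channel.

    The recording is tiled into consecutive windows from t = 0; windows
    overlapping an artifact span on a channel are dropped for that channel;
    the first ``total_s/window_s`` surviving windows are kept. Channels with
    no surviving window are dropped with a warning; channels with fewer than
    the full count are kept short with a warning. No channel left -> error.
    """
    n_target = int(round(total_s / window_s))
    wlen = int(round(window_s * rec.fs))
    n_avail = rec.n_samples // wlen
    windows: dict[str, np.ndarray] = {}
    indices: dict[str, np.ndarray] = {}
    for ci, ch in enumerate(rec.channel_names):
        spans = rec.artifact_spans.get(ch, [])
        keep = []
        for w in range(n_avail):
            t0, t1 = w * window_s, (w + 1) * window_s
            if any(s < t1 and e > t0 for s, e in spans):
                continue
            keep.append(w)
            if len(keep) == n_target:
                break
        if not keep:
            logger.warning("channel %s has no usable windows; dropped", ch)
            continue
        if len(keep) < n_target:
            logger.warning(
                "channel %s yields %d/%d windows", ch, len(keep), n_target)
        idx = np.asarray(keep)
        windows[ch] = np.stack(
            [rec.data[ci, w * wlen:(w + 1) * wlen] for w in keep])
        indices[ch] = idx
    if not windows:
        raise ValueError("no channel has usable signal for windowing")
    return WindowedSignal(windows=windows, window_indices=indices, fs=rec.fs,
                          window_s=window_s, band=band)


def drop_tc_channels_post(rec: Recording, contacts: pd.DataFrame) -> Recording:
    """Remove thermocoagulated channels from a post-operative recording
    (only noise remains on them); pre-operative recordings pass unchanged."""
    if rec.period != "post":
        return rec
    pat = contacts[contacts.patient_id == rec.patient_id]
    tc_names = set(pat.loc[pat.is_tc, "channel_name"])
    missing = sorted(tc_names - set(rec.channel_names))
    if missing:
        raise ValueError(
            f"TC-flagged channels absent from recording {rec.patient_id}/"
            f"{rec.period}: {missing}"
        )
    keep = [ch for ch in rec.channel_names if ch not in tc_names]
    return rec.pick(keep)


def preprocess_recording(
    rec: Recording,
    contacts: pd.DataFrame,
    bad_spans: list[tuple[str, float, float]] | None = None,
    bands: dict[str, BandSpec] | None = None,
    window_s: float = WINDOW_S_DEFAULT,
    total_s: float = TOTAL_S_DEFAULT,
) -> dict[str, WindowedSignal]:
    """Run the fixed pipeline on one recording; returns one
    :class:`WindowedSignal` per analysis band."""
    bands = bands or CANONICAL_BANDS
    rec = drop_tc_channels_post(rec, contacts)
    rec = average_reference(rec)
    if bad_spans:
        rec = reject_artifacts(rec, bad_spans)
    rec = resample_to_500(rec)
    rec = notch_power_line(rec)
    out = {}
    for name, band in bands.items():
        filtered = band_filter(rec, band)
        out[name] = extract_windows(filtered, band, window_s=window_s,
                                    total_s=total_s)
    return out
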