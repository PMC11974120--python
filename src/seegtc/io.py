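"""File interchange: EDF recordings, tab-separated metadata, feature CSV.

EDF writing is implemented here directly against the EDF specification
(256-byte fixed header + 256 bytes per signal + 16-bit little-endian data
records): the format's fixed ASCII layout makes a self-contained writer
straightforward, and round-trips are tested against mne's independent EDF
reader. Reading goes through :func:`mne.io.read_raw_edf`.

Channel metadata travels as TSV with columns (patient_id, channel_name,
electrode, contact_index, is_tc); outcomes as TSV (patient_id, outcome);
artifact spans as TSV (channel_name, start_s, end_s) with half-open
[start, end) second intervals. Feature tables round-trip through CSV with
the normalization flag in a leading comment line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import Recording

__all__ = [
    "write_edf",
    "read_edf",
    "write_contacts_tsv",
    "read_contacts_tsv",
    "write_outcomes_tsv",
    "read_outcomes_tsv",
    "read_artifact_spans_tsv",
    "write_features_csv",
    "read_features_csv",
    "save_cohort_bundle",
    "load_cohort_bundle",
]

_DIG_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a :class:`Recording` as 16-bit EDF (one record per second).

    The sampling rate must be a positive integer and the duration is
    truncated to whole seconds. Per-channel physical scaling spans the
    channel's observed range.
    """
    path = Path(path)
    fs = int(rec.fs)
    if fs != rec.fs or fs <= 0:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {rec.fs}")
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record (1 s)")
    n_sig = rec.n_channels
    data = np.asarray(rec.data, dtype=np.float64)[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    scale = _DIG_MAX / phys_max
    digital = np.round(data * scale[:, None]).astype("<i2")

    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(f"{rec.patient_id} X X X", 80),
        _ascii_field(f"Startdate X {rec.period}", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(256 * (1 + n_sig), 8),
        _ascii_field("", 44),
        _ascii_field(n_records, 8),
        _ascii_field(1, 8),
        _ascii_field(n_sig, 4),
    ])
    fields: list[bytes] = []
    for getter, width in (
        (lambda i: rec.channel_names[i], 16),
        (lambda i: "SEEG depth", 80),
        (lambda i: "uV", 8),
        (lambda i: f"{-phys_max[i]:.6g}"[:8], 8),
        (lambda i: f"{phys_max[i]:.6g}"[:8], 8),
        (lambda i: -_DIG_MAX, 8),
        (lambda i: _DIG_MAX, 8),
        (lambda i: "", 80),
        (lambda i: fs, 8),
        (lambda i: "", 32),
    ):
        fields.append(b"".join(_ascii_field(getter(i), width)
                               for i in range(n_sig)))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        # records: per second, each signal's fs samples back to back
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path, patient_id: str, period: str) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts) via mne."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        period=period,
        patient_id=patient_id,
    )


def write_contacts_tsv(contacts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    contacts.to_csv(path, sep="\t", index=False)
    return path


def read_contacts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "channel_name", "electrode", "contact_index",
                "is_tc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contacts TSV missing columns: {sorted(missing)}")
    df["is_tc"] = df.is_tc.astype(bool)
    return df


def write_outcomes_tsv(outcomes: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    outcomes.rename("outcome").to_csv(path, sep="\t")
    return path


def read_outcomes_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("patient_id")["outcome"]


def read_artifact_spans_tsv(path: str | Path) -> list[tuple[str, float, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(r.channel_name, float(r.start_s), float(r.end_s))
            for r in df.itertuples()]


def write_features_csv(features: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    normalized = bool(features.attrs.get("normalized", False))
    with open(path, "w") as fh:
        fh.write(f"# normalized={str(normalized).lower()}\n")
        features.to_csv(fh, index=False)
    return path


def read_features_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        normalized = first.strip() == "# normalized=true"
        df = pd.read_csv(fh)
    df.attrs["normalized"] = normalized
    return df


def save_cohort_bundle(cohort, path: str | Path) -> Path:
    """Self-contained compressed-array bundle of a synthetic cohort
    (signals + metadata), for fast reloading in tests and reruns."""
    path = Path(path)
    arrays = {}
    meta = {"keys": [], "outcomes": cohort.outcomes.to_dict()}
    for (pid, period), rec in cohort.recordings.items():
        key = f"{pid}__{period}"
        arrays[f"data_{key}"] = rec.data
        meta["keys"].append({
            "patient_id": pid, "period": period, "fs": rec.fs,
            "channels": rec.channel_names,
        })
    meta["contacts"] = cohort.contacts.to_dict(orient="list")
    meta["truth"] = cohort.truth.to_dict(orient="list")
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def load_cohort_bundle(path: str | Path):
    from .simulate import SyntheticCohort

    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        contacts = pd.DataFrame(meta["contacts"])
        truth = pd.DataFrame(meta["truth"])
        recordings = {}
        for entry in meta["keys"]:
            key = f"{entry['patient_id']}__{entry['period']}"
            recordings[(entry["patient_id"], entry["period"])] = Recording(
                data=npz[f"data_{key}"], fs=entry["fs"],
                channel_names=[str(c) for c in entry["channels"]],
                period=entry["period"], patient_id=entry["patient_id"],
            )
    outcomes = pd.Series(meta["outcomes"], name="outcome")
    outcomes.index.name = "patient_id"
    return SyntheticCohort(recordings=recordings, contacts=contacts,
                           outcomes=outcomes, truth=truth, config=None)
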