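"""Core containers for multichannel SEEG segments.

A :class:`Recording` is one patient-period block of intracranial EEG:
a channels x samples array with a sampling rate, ordered channel names
and a period tag (``"pre"`` or ``"post"`` relative to thermocoagulation).
Artifact spans rejected by the reviewer travel with the recording as a
per-channel list of half-open ``[start_s, end_s)`` intervals and are
honoured when fixed-length analysis windows are cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BandSpec",
    "Recording",
    "WindowedSignal",
    "CANONICAL_BANDS",
    "BAND_ORDER",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(
                f"invalid band edges for {self.name!r}: "
                f"[{self.low_hz}, {self.high_hz}] Hz"
            )


#: The four analysis bands: the full filtered band plus its three sub-bands
#: (conventional low frequencies, high-gamma, and the ripple range of
#: high-frequency oscillations).
CANONICAL_BANDS: dict[str, BandSpec] = {
    "filtered": BandSpec("filtered", 0.5, 250.0),
    "low": BandSpec("low", 0.5, 50.0),
    "high_gamma": BandSpec("high_gamma", 50.0, 80.0),
    "ripple": BandSpec("ripple", 80.0, 250.0),
}

#: Canonical band ordering used in feature vectors and reports.
BAND_ORDER: tuple[str, ...] = ("filtered", "low", "high_gamma", "ripple")


@dataclass
class Recording:
    """One patient-period block of multichannel SEEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique, ordered channel labels; one per data row.
    period : {"pre", "post"}
    patient_id : str
    artifact_spans : dict
        Optional ``channel_name -> [(start_s, end_s), ...]`` rejection mask,
        half-open intervals in seconds from segment start.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    period: str
    patient_id: str
    artifact_spans: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.period not in ("pre", "post"):
            raise ValueError(f"period must be 'pre' or 'post', got {self.period!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a shallow-modified copy (dataclasses.replace wrapper)."""
        return replace(self, **changes)

    def pick(self, names: list[str]) -> "Recording":
        """Return a copy restricted to ``names`` (recording order kept)."""
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        keep = [i for i, n in enumerate(self.channel_names) if n in set(names)]
        return self.copy_with(
            data=self.data[keep],
            channel_names=[self.channel_names[i] for i in keep],
            artifact_spans={
                n: v
                for n, v in self.artifact_spans.items()
                if n in set(names)
            },
        )


@dataclass
class WindowedSignal:
    """Fixed-length non-overlapping analysis windows for one band.

    ``windows[channel]`` is an (n_windows, window_samples) array;
    ``window_indices[channel]`` gives each row's position in the original
    window tiling (gaps arise where artifact-masked windows were dropped).
    """

    windows: dict[str, np.ndarray]
    window_indices: dict[str, np.ndarray]
    fs: float
    window_s: float
    band: BandSpec

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs))

    def n_windows(self, channel: str) -> int:
        return self.windows[channel].shape[0]
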