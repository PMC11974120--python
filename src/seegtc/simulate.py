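"""Synthetic interictal SEEG cohorts for exercising the analysis pipeline.

The study this package re-implements analysed ten patients who underwent
SEEG-guided radiofrequency thermocoagulation (RF-TC): eight responders and
two non-responders, with 834 responder and 163 non-responder non-TC contacts
entering the prediction stage, recorded at 512/1000/2000 Hz. No recordings
were shared, so this module synthesises cohorts with that design and with
the band-specific biomarker structure the downstream statistics look for:

* each contact is a sum of three band-limited Gaussian noise components
  (low 0.5-50 Hz, high-gamma 50-80 Hz, ripple 80-250 Hz) with 1/f^alpha
  in-band spectral slope and configurable per-band RMS;
* line length is steered through per-band amplitude multipliers;
* approximate entropy is steered through a multiplicative slow log-normal
  burst envelope exp(kappa*s - kappa^2/2) (s a slow unit-variance Gaussian):
  larger burstiness kappa makes the signal intermittent - locally quiet
  relative to its global SD - which lowers ApEn while E[envelope] = 1 keeps
  the expected line length fixed.  Effects are expressed as signed
  ``apen_shift`` values with kappa_eff = kappa_base - shift.

Effect direction defaults mirror the study's reported group patterns:
responder TC contacts show pre-operatively elevated LL (high-gamma, ripple,
hence also the full filtered band) and elevated ApEn (low, ripple, filtered);
post-operatively, responder non-TC contacts lose LL in all bands and ApEn in
high-gamma/ripple, while non-responder non-TC contacts gain LL in
low/ripple/filtered and lose ApEn in low/ripple/filtered.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal import Recording

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "spectral_noise",
    "band_limited_noise",
    "burst_envelope",
    "plan_cohort",
    "generate_cohort",
    "generate_recording",
    "scaled_config",
]

#: Sub-bands that are synthesised additively (the "filtered" analysis band
#: is their union and is never generated separately).
GEN_BANDS: dict[str, tuple[float, float]] = {
    "low": (0.5, 50.0),
    "high_gamma": (50.0, 80.0),
    "ripple": (80.0, 250.0),
}

# Per-patient surgical layout of the emulated cohort: sampling rate (Hz) and
# thermocoagulated-contact count for patients 1..10; patients 3 and 9 are the
# non-responders.
_DEFAULT_RATES = (1000, 2000, 512, 2000, 2000, 1000, 2000, 1000, 1000, 2000)
_DEFAULT_TC_COUNTS = (14, 26, 39, 17, 16, 26, 39, 62, 36, 76)
_DEFAULT_NONRESPONDERS = (2, 8)  # 0-based patient indices


def _band_dict(default: float, **overrides: float) -> dict[str, float]:
    d = {b: default for b in GEN_BANDS}
    d.update(overrides)
    return d


@dataclass(frozen=True)
class EffectSpec:
    """Per-band effect applied to a class of contacts in one period.

    ``ll_mult`` multiplies the band amplitude (moves line length);
    ``apen_shift`` is subtracted from the burstiness kappa (positive shift =
    less bursty = higher approximate entropy).
    """

    ll_mult: Mapping[str, float]
    apen_shift: Mapping[str, float]

    def validate(self) -> None:
        for d in (self.ll_mult, self.apen_shift):
            unknown = set(d) - set(GEN_BANDS)
            if unknown:
                raise ValueError(f"unknown bands in effect spec: {sorted(unknown)}")


def _default_tc_effect() -> EffectSpec:
    return EffectSpec(
        ll_mult=_band_dict(1.0, high_gamma=1.5, ripple=1.5),
        apen_shift=_band_dict(0.0, low=0.30, ripple=0.30),
    )


def _default_post_responder() -> EffectSpec:
    return EffectSpec(
        ll_mult=_band_dict(0.80),
        apen_shift=_band_dict(0.0, high_gamma=-0.30, ripple=-0.30),
    )


def _default_post_nonresponder() -> EffectSpec:
    return EffectSpec(
        ll_mult=_band_dict(1.0, low=1.25, ripple=1.25),
        apen_shift=_band_dict(0.0, low=-0.30, ripple=-0.30),
    )


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic RF-TC cohort.

    Defaults reproduce the emulated study's design: 10 patients
    (8 responders), per-group non-TC contact totals 834/163, per-patient TC
    contact counts spanning 7-76, sampling rates in {512, 1000, 2000} Hz and
    200 s of interictal signal per period.
    """

    n_patients: int = 10
    n_responders: int = 8
    #: group totals of non-thermocoagulated contacts (responders, non-resp.)
    nontc_totals: tuple[int, int] = (834, 163)
    #: per-patient TC contact counts, or a (lo, hi) range drawn per patient
    tc_counts: Sequence[int] | tuple[int, int] = _DEFAULT_TC_COUNTS
    #: per-patient sampling rates (Hz); cycled if shorter than n_patients
    sampling_rates: Sequence[int] = _DEFAULT_RATES
    #: 0-based indices of non-responder patients
    nonresponder_indices: Sequence[int] = _DEFAULT_NONRESPONDERS
    duration_s: float = 200.0
    #: baseline per-band RMS amplitude, microvolts
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"low": 20.0, "high_gamma": 5.0, "ripple": 2.5}
    )
    #: baseline burst-envelope kappa per band
    burstiness: Mapping[str, float] = field(default_factory=lambda: _band_dict(0.45))
    #: in-band spectral slope of the background (power ~ 1/f^alpha)
    noise_exponent: float = 1.0
    tc_effect: EffectSpec = field(default_factory=_default_tc_effect)
    post_shift_responder: EffectSpec = field(default_factory=_default_post_responder)
    post_shift_nonresponder: EffectSpec = field(
        default_factory=_default_post_nonresponder
    )
    #: log-SD of the per-patient global scale (removed by within-subject
    #: z-scoring downstream; present for realism)
    patient_scale_sigma: float = 0.30
    #: log-SD of the persistent per-(contact, band) amplitude jitter
    contact_jitter_sigma: float = 0.10
    #: log-SD of the per-period amplitude jitter (noise on pre/post deltas)
    period_jitter_sigma: float = 0.05
    #: SD of additive jitter on kappa (persistent and per-period)
    kappa_jitter_sigma: float = 0.05
    #: RMS (microvolts) of the white noise left on coagulated contacts post-op
    coagulated_amplitude: float = 5.0
    seed: int = 0
    #: permit duration_s < 200 for reduced-scale runs
    allow_short: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.n_responders <= self.n_patients:
            raise ValueError("need 0 < n_responders <= n_patients")
        if len(self.nonresponder_indices) != self.n_patients - self.n_responders:
            raise ValueError("nonresponder_indices inconsistent with n_responders")
        if self.duration_s < 200.0 and not self.allow_short:
            raise ValueError(
                "duration_s must be >= 200 s (set allow_short=True for "
                "reduced-scale runs)"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for eff in (self.tc_effect, self.post_shift_responder,
                    self.post_shift_nonresponder):
            eff.validate()
        for b, (lo, hi) in GEN_BANDS.items():
            for fs in self.patient_rates():
                if lo >= fs / 2:
                    raise ValueError(
                        f"band {b!r} [{lo}, {hi}] Hz entirely above Nyquist "
                        f"at fs={fs}"
                    )

    def patient_rates(self) -> list[int]:
        rates = list(self.sampling_rates)
        return [rates[i % len(rates)] for i in range(self.n_patients)]

    def is_responder(self, patient_index: int) -> bool:
        return patient_index not in set(self.nonresponder_indices)


def spectral_noise(
    length: int,
    fs: float,
    exponent: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean Gaussian noise with power spectrum ~ 1/f**exponent.

    Generated by shaping white Gaussian noise in the rFFT domain; the DC bin
    is zeroed. ``exponent = 0`` gives white noise. Output has unit sample
    variance (except in degenerate lengths < 2).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if length == 1:
        return np.zeros(1)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    freqs = np.fft.rfftfreq(length, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(z * amp, length)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def band_limited_noise(
    length: int,
    fs: float,
    low_hz: float,
    high_hz: float,
    exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to [low_hz, high_hz] with in-band
    power ~ 1/f**exponent."""
    freqs = np.fft.rfftfreq(length, 1.0 / fs)
    band = (freqs >= low_hz) & (freqs <= min(high_hz, fs / 2))
    if not band.any():
        raise ValueError(
            f"no spectral support in [{low_hz}, {high_hz}] Hz at "
            f"length={length}, fs={fs}"
        )
    amp = np.zeros_like(freqs)
    f = freqs[band]
    p = f ** (-exponent)
    amp[band] = np.sqrt(p / p.mean())
    z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(z * amp, length)
    x -= x.mean()
    return x / x.std()


def burst_envelope(
    length: int,
    fs: float,
    kappa: float,
    rng: np.random.Generator,
    env_high_hz: float = 2.0,
) -> np.ndarray:
    """Slow positive log-normal envelope with E[env] = 1.

    ``kappa = 0`` returns all-ones (stationary signal); larger kappa yields
    intermittent bursts, which lowers the approximate entropy of the
    modulated signal without changing its expected line length.
    """
    if kappa <= 0:
        return np.ones(length)
    duration = length / fs
    low = max(0.1, 1.5 / duration)
    s = band_limited_noise(length, fs, low, max(env_high_hz, low * 1.5),
                           0.0, rng)
    return np.exp(kappa * s - 0.5 * kappa ** 2)


@dataclass
class SyntheticCohort:
    """A generated cohort: recordings plus the metadata the analysis needs.

    ``truth`` carries the generative per-(contact, band, period) amplitude
    and burstiness actually used, for parameter-recovery tests.
    """

    recordings: dict[tuple[str, str], Recording]
    contacts: pd.DataFrame  # patient_id, channel_name, electrode, contact_index, is_tc
    outcomes: pd.Series  # patient_id -> "responder" | "non_responder"
    truth: pd.DataFrame
    config: SimConfig

    def patients(self) -> list[str]:
        return list(self.outcomes.index)

    def recording(self, patient_id: str, period: str) -> Recording:
        return self.recordings[(patient_id, period)]


def _electrode_labels(n_contacts: int, rng: np.random.Generator) -> pd.DataFrame:
    """Group ``n_contacts`` into electrodes of 8-18 contacts, lettered A, B, ..."""
    letters = list(string.ascii_uppercase) + [
        a + b for a in string.ascii_uppercase for b in string.ascii_uppercase
    ]
    rows = []
    e = 0
    remaining = n_contacts
    while remaining > 0:
        size = int(rng.integers(8, 19))
        size = min(size, remaining)
        # avoid a trailing stub electrode shorter than physical contact counts
        if 0 < remaining - size < 8 and size < 18:
            size = min(18, size + (remaining - size))
        for c in range(1, size + 1):
            rows.append((letters[e], c, f"{letters[e]}{c}"))
        remaining -= size
        e += 1
    return pd.DataFrame(rows, columns=["electrode", "contact_index", "channel_name"])


def _effect_for(
    config: SimConfig, responder: bool, is_tc: bool, period: str
) -> EffectSpec | None:
    if period == "pre":
        if is_tc and responder:
            return config.tc_effect
        return None
    if is_tc:
        return None  # coagulated post-op contacts handled separately
    return (config.post_shift_responder if responder
            else config.post_shift_nonresponder)


def plan_cohort(config: SimConfig, seed: int | None = None):
    """Lay out contacts, outcomes and generative truth without synthesising
    signals.

    Returns ``(contacts, outcomes, truth, seed_seq)`` where ``truth`` has one
    row per (patient, channel, band, period) with the effective amplitude and
    burstiness. Deterministic in (config, seed).
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence([int(seed), 0x5EE6])
    layout_ss, *_ = ss.spawn(1)
    rng = np.random.default_rng(layout_ss)

    n_nonresp = config.n_patients - config.n_responders
    responder_ids = [i for i in range(config.n_patients) if config.is_responder(i)]
    nonresp_ids = list(config.nonresponder_indices)

    # allocate per-group non-TC totals across patients (multinomial keeps the
    # group totals exact while making per-patient counts vary by seed);
    # every patient keeps at least 2 non-TC contacts so the post-operative
    # montage stays referenceable
    def _alloc(total: int, ids: list[int], floor: int = 2) -> dict[int, int]:
        if not ids:
            return {}
        if total < floor * len(ids):
            raise ValueError(
                f"non-TC total {total} cannot give {len(ids)} patients "
                f"{floor} contacts each")
        counts = rng.multinomial(total - floor * len(ids),
                                 np.full(len(ids), 1.0 / len(ids))) + floor
        return dict(zip(ids, counts.tolist()))

    nontc = {**_alloc(config.nontc_totals[0], responder_ids),
             **_alloc(config.nontc_totals[1], nonresp_ids)}

    if isinstance(config.tc_counts, tuple) and len(config.tc_counts) == 2 and all(
        isinstance(v, int) for v in config.tc_counts
    ) and config.n_patients != 2:
        lo, hi = config.tc_counts
        tc_counts = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_patients)]
    else:
        seq = list(config.tc_counts)
        tc_counts = [seq[i % len(seq)] for i in range(config.n_patients)]

    rates = config.patient_rates()
    contact_rows = []
    truth_rows = []
    outcome_rows = {}
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        responder = config.is_responder(p)
        outcome_rows[pid] = "responder" if responder else "non_responder"
        n_total = nontc[p] + tc_counts[p]
        labels = _electrode_labels(n_total, rng)
        tc_flags = np.zeros(n_total, dtype=bool)
        tc_flags[rng.choice(n_total, size=tc_counts[p], replace=False)] = True
        patient_scale = float(np.exp(
            rng.normal(0.0, config.patient_scale_sigma)))
        for i in range(n_total):
            ch = labels.channel_name.iloc[i]
            contact_rows.append(
                (pid, ch, labels.electrode.iloc[i],
                 int(labels.contact_index.iloc[i]), bool(tc_flags[i]))
            )
            for band, _edges in GEN_BANDS.items():
                g_jit = float(np.exp(rng.normal(0.0, config.contact_jitter_sigma)))
                k_jit = float(rng.normal(0.0, config.kappa_jitter_sigma))
                for period in ("pre", "post"):
                    p_jit = float(np.exp(rng.normal(0.0, config.period_jitter_sigma)))
                    kp_jit = float(rng.normal(0.0, config.kappa_jitter_sigma))
                    eff = _effect_for(config, responder, bool(tc_flags[i]), period)
                    ll_mult = eff.ll_mult.get(band, 1.0) if eff else 1.0
                    shift = eff.apen_shift.get(band, 0.0) if eff else 0.0
                    coagulated = bool(tc_flags[i]) and period == "post"
                    gain = (config.band_amplitudes[band] * patient_scale
                            * g_jit * p_jit * ll_mult)
                    kappa = float(np.clip(
                        config.burstiness[band] + k_jit + kp_jit - shift,
                        0.0, 1.5))
                    truth_rows.append(
                        (pid, ch, band, period, gain, kappa, coagulated)
                    )
    contacts = pd.DataFrame(
        contact_rows,
        columns=["patient_id", "channel_name", "electrode", "contact_index",
                 "is_tc"],
    )
    outcomes = pd.Series(outcome_rows, name="outcome")
    outcomes.index.name = "patient_id"
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "channel_name", "band", "period", "gain",
                 "kappa", "coagulated"],
    )
    truth["fs"] = truth.patient_id.map(
        {f"P{p + 1:02d}": rates[p] for p in range(config.n_patients)})
    return contacts, outcomes, truth, ss


def generate_recording(
    config: SimConfig,
    contacts: pd.DataFrame,
    truth: pd.DataFrame,
    seed_seq: np.random.SeedSequence,
    patient_id: str,
    period: str,
) -> Recording:
    """Synthesise one patient-period block from a cohort plan."""
    pat_contacts = contacts[contacts.patient_id == patient_id]
    pat_truth = truth[(truth.patient_id == patient_id) & (truth.period == period)]
    fs = int(pat_truth.fs.iloc[0])
    n = int(round(config.duration_s * fs))
    p_index = int(patient_id[1:]) - 1
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed), 0x5EE6, p_index, 0 if period == "pre" else 1])
    )
    channels = list(pat_contacts.channel_name)
    data = np.zeros((len(channels), n), dtype=np.float32)
    by_ch = {ch: grp for ch, grp in pat_truth.groupby("channel_name", sort=False)}
    for row_i, ch in enumerate(channels):
        grp = by_ch[ch]
        if bool(grp.coagulated.iloc[0]):
            data[row_i] = (config.coagulated_amplitude
                           * rng.standard_normal(n)).astype(np.float32)
            continue
        x = np.zeros(n)
        for _, trow in grp.iterrows():
            lo, hi = GEN_BANDS[trow.band]
            carrier = band_limited_noise(n, fs, lo, hi, config.noise_exponent,
                                         rng)
            env = burst_envelope(n, fs, trow.kappa, rng)
            x += trow.gain * env * carrier
        data[row_i] = x.astype(np.float32)
    return Recording(data=data, fs=float(fs), channel_names=channels,
                     period=period, patient_id=patient_id)


def generate_cohort(config: SimConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort (all recordings in memory).

    Deterministic in (config, seed): identical inputs give bit-identical
    cohorts. For the default full-scale configuration, prefer
    :func:`iter_recordings` / the CLI ``simulate`` stage, which stream one
    patient-period at a time.
    """
    seed = config.seed if seed is None else seed
    config = SimConfig(**{**config.__dict__, "seed": seed})
    contacts, outcomes, truth, ss = plan_cohort(config)
    recordings = {}
    for pid in outcomes.index:
        for period in ("pre", "post"):
            recordings[(pid, period)] = generate_recording(
                config, contacts, truth, ss, pid, period)
    return SyntheticCohort(recordings=recordings, contacts=contacts,
                           outcomes=outcomes, truth=truth, config=config)


def iter_recordings(
    config: SimConfig, seed: int | None = None
) -> Iterator[tuple[pd.DataFrame, pd.Series, Recording]]:
    """Yield (contacts, outcomes, recording) one patient-period at a time."""
    seed = config.seed if seed is None else seed
    config = SimConfig(**{**config.__dict__, "seed": seed})
    contacts, outcomes, truth, ss = plan_cohort(config)
    for pid in outcomes.index:
        for period in ("pre", "post"):
            yield contacts, outcomes, generate_recording(
                config, contacts, truth, ss, pid, period)


def expected_directions(config: SimConfig) -> pd.DataFrame:
    """Derive the comparison directions the configured effects imply.

    Returns one row per (group, design, band, feature) with the expected
    one-tailed direction: ``"right"``/``"left"``, or ``None`` where the
    configuration applies no effect (no direction is implied).

    The composite ``filtered`` band inherits directions from the sub-bands
    differently per feature. Line length adds in quadrature across bands
    (the default per-band amplitudes contribute comparable first-difference
    variance), so any consistent sub-band LL shift moves filtered LL: the
    consensus of the nonzero sub-band directions is used (``None`` on
    conflict). Approximate entropy of the composite is dominated by the
    band carrying most amplitude - the low band at the default RMS profile
    - so filtered ApEn inherits the low band's direction only.

    Conventions: design 1 (TC vs non-TC, pre-op) is right-tailed where the
    TC effect raises a feature; design 2 (pre vs post, non-TC) is
    right-tailed (pre > post) where the post shift lowers a feature.
    """

    def _dir_ll(eff: EffectSpec, band: str, design: int) -> str | None:
        mult = eff.ll_mult.get(band, 1.0)
        if mult == 1.0:
            return None
        if design == 1:
            return "right" if mult > 1.0 else "left"
        return "right" if mult < 1.0 else "left"

    def _dir_apen(eff: EffectSpec, band: str, design: int) -> str | None:
        shift = eff.apen_shift.get(band, 0.0)
        if shift == 0.0:
            return None
        if design == 1:
            return "right" if shift > 0 else "left"
        return "right" if shift < 0 else "left"

    def _consensus(dirs: list[str | None]) -> str | None:
        nonnull = {d for d in dirs if d is not None}
        return nonnull.pop() if len(nonnull) == 1 else None

    rows = []
    specs = {
        ("responders", "tc_vs_ntc_pre", 1): config.tc_effect,
        ("responders", "pre_vs_post_ntc", 2): config.post_shift_responder,
        ("non_responders", "tc_vs_ntc_pre", 1): None,
        ("non_responders", "pre_vs_post_ntc", 2): config.post_shift_nonresponder,
    }
    for (group, design, dnum), eff in specs.items():
        for feat, fn in (("ll", _dir_ll), ("apen", _dir_apen)):
            sub_dirs = {}
            for band in GEN_BANDS:
                sub_dirs[band] = fn(eff, band, dnum) if eff else None
            if feat == "ll":
                sub_dirs["filtered"] = _consensus(list(sub_dirs.values()))
            else:
                # composite ApEn follows the amplitude-dominant low band
                sub_dirs["filtered"] = sub_dirs["low"]
            for band in ("filtered", *GEN_BANDS):
                rows.append((group, design, band, feat, sub_dirs[band]))
    return pd.DataFrame(
        rows, columns=["group", "design", "band", "feature", "expected_tail"])


def scaled_config(
    nontc_per_responder: int = 8,
    nontc_per_nonresponder: int = 6,
    tc_per_patient: int = 3,
    duration_s: float = 14.0,
    fs: int = 512,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A reduced-scale cohort preserving the default effect sizes and the
    8:2 patient imbalance, for seed-replicated statistical suites.

    Only the problem size changes relative to :class:`SimConfig` defaults;
    effect directions and magnitudes are untouched.
    """
    kwargs = dict(
        nontc_totals=(8 * nontc_per_responder, 2 * nontc_per_nonresponder),
        tc_counts=tuple([tc_per_patient] * 10),
        sampling_rates=(fs,),
        duration_s=duration_s,
        allow_short=True,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
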