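# Methods

This note documents the models, parameters and design choices behind
`seegtc`, and what the synthetic-cohort tests do and do not demonstrate
about real recordings.

## The analysis pipeline

### Preprocessing

Stage order is fixed and deterministic: average reference → artifact
masking → resampling → notch filtering → band-pass filtering → windowing.
Post-operative recordings first lose their thermocoagulated (TC) channels,
which carry only noise after tissue ablation; the average reference is then
computed over the remaining montage.

Choices worth stating explicitly:

* **Resampling before filtering.** 1000 and 2000 Hz recordings are reduced
  to 500 Hz by polyphase anti-aliased resampling so that all patients share
  one filter design; 512 Hz recordings pass through at their native rate
  (Nyquist 256 Hz still contains the 80–250 Hz ripple band). Unexpected
  rates are resampled to 500 Hz with a warning.
* **Filter family.** Zero-phase forward–backward IIR throughout: 4th-order
  Butterworth band-passes; second-order notches with quality factor 30 at
  50 Hz and odd harmonics strictly below Nyquist (50/150 at 500 Hz, plus
  250 at 512 Hz and above). These are conventional clinical-EEG choices; no
  claim of optimality is made.
* **Band edge at Nyquist.** At 500 Hz the filtered (0.5–250 Hz) and ripple
  (80–250 Hz) bands have their upper edge at Nyquist, where a band-pass
  edge is unrealizable; the filter degrades to a high-pass at the band's
  lower edge.
* **Windows.** Non-overlapping windows tiled from t = 0; a window
  overlapping a reviewer-marked artifact span on a channel is dropped for
  that channel, and the first `total_s / window_s` surviving windows are
  kept (20 × 10 s from 200 s at full scale). Artifact rejection is an
  *input* (a span list), not a detector: the workflow this package models
  treats rejection as a manual step.

### Biomarkers

Two features per (channel, period, band, window):

* **Line length**, the summed absolute first difference (µV). Reported as
  the raw sum, not divided by N−1: all windows share one length and the
  within-subject z-scoring removes constant factors anyway.
* **Approximate entropy** (Pincus), `Φᵐ(r) − Φᵐ⁺¹(r)` with Chebyshev
  template distance and self-matches included (classic ApEn, not sample
  entropy). Parameters m = 2, r = 0.2 × window SD — the field-standard
  setting. The SD-proportional tolerance makes ApEn invariant to affine
  amplitude changes, which is why the synthetic generator needs a
  non-amplitude lever to move it (below). A flat window is assigned
  ApEn = 0 (and LL = 0) with a logged warning. The production kernel is an
  O(N²) pair loop (numba-compiled, with a numpy fallback) counting m and
  m+1 matches in one pass; tests pin it to an independent distance-matrix
  reference at 1e-10.

* **Normalization.** Within-subject z-scoring per (patient, band, feature)
  over *all* of that patient's rows — both periods, all contacts, all
  windows (sample SD, ddof = 1). Pooling the two periods is essential:
  normalizing each period separately would zero out exactly the pre/post
  contrasts the paired statistics and the delta features measure. Each
  (band, feature) pair is normalized separately; pooling across bands
  would let high-amplitude bands dominate the scale.

### Group statistics

Two designs per outcome group (responders / non-responders), contacts
pooled across patients within a group, on z-scored contact means (mean
over windows):

1. **TC vs non-TC, pre-op** — Mann–Whitney U, one-tailed for TC > non-TC
   (elevated interictal activity marking the ablated tissue).
2. **Pre vs post, non-TC** — Wilcoxon signed-rank on paired contact means;
   both one-tailed directions are evaluated and the smaller p is reported
   with its direction label, since either direction is meaningful.

Exact enumeration is used for small tie-free samples (≤8 per arm for U,
≤20 informative pairs for the signed-rank), tie-corrected normal
approximation otherwise; zero differences are discarded and fewer than 5
informative pairs is treated as no information. Bonferroni correction uses
the family of 2 features × 4 bands = 8 tests within each group × design —
the most conservative reading of the multiple-comparison structure — and
significance is adjusted p < 0.05.

### Two-level outcome prediction

Each non-TC contact contributes one sample: the 8-vector of pre-minus-post
z-scored contact means (LL then ApEn, in band order filtered, low,
high-gamma, ripple), labelled positive when the patient is a responder.
The model surface follows the statsmodels convention — `OutcomeModel`
(data + plan) → `fit()` → `OutcomeResults` (selection grid, test metrics,
patient table, `summary()`).

* **Split** — class-stratified at 1/6 (rounded to nearest per class),
  contact-level and deliberately ignoring patient boundaries; at the
  emulated study scale this reproduces 695/139 positive and 136/27
  negative train/test counts exactly. Contact-level splitting leaks
  patient identity between train and test; the summary output states this.
* **Imbalance** — the positive training samples are randomly partitioned
  into five near-equal subsets (each comparable to the negative training
  count); each subset ∪ all negatives forms one candidate training pool.
* **Selection** — RBF support-vector classifier over a grid of
  C ∈ {0.1, 1, 10, 100} × γ ∈ {scale, 0.01, 0.1, 1}, scored by mean AUC of
  decision scores under stratified 25-fold cross-validation (folds reduced
  with a warning when a class is smaller than the fold count; single-class
  validation folds are skipped). Ties break to the smallest subset index,
  then the grid order (ascending C). The chosen subset ∪ negatives is
  refitted and evaluated on the held-out test contacts (accuracy,
  precision, recall, F1 at the default decision threshold; AUC by rank
  statistic).
* **Individual level** — a patient's response possibility is the fraction
  of *all* their non-TC contacts (train and test) the classifier marks
  positive — scoring training contacts is required for every patient to
  receive a possibility — and the patient is predicted a responder when it
  strictly exceeds 0.5. No additional feature scaling is applied: the
  deltas are already in within-subject z units.

## The synthetic cohort generator

No recordings of this kind are publicly available, so the generator is a
first-class module that emulates the *statistical design*, not the
physiology:

* 10 patients (8 responders, patients 3 and 9 non-responders), sampling
  rates (1000, 2000, 512, 2000, 2000, 1000, 2000, 1000, 1000, 2000) Hz,
  200 s per period; per-patient TC contact counts default to the emulated
  study's values (span 7–76); per-group non-TC totals default to 834
  (responders) and 163 (non-responders), allocated per patient by a
  seeded multinomial with a floor of 2 so every post montage remains
  referenceable. Only the group totals are constrained by the emulated
  design; per-patient counts are not reported anywhere and are treated as
  free.
* Each contact is a sum of three independent band-limited Gaussian noise
  components (low 0.5–50, high-gamma 50–80, ripple 80–250 Hz) with 1/f
  in-band spectral slope and per-band RMS defaults of 20/5/2.5 µV. This
  profile makes the three bands contribute comparable first-difference
  variance, so broadband line length responds to every band's amplitude.
* **Line-length lever:** per-band multiplicative amplitude effects.
* **ApEn lever:** a multiplicative slow (≲2 Hz) log-normal burst envelope
  `exp(κ·s − κ²/2)` with E[env] = 1. ApEn of a stationary Gaussian process
  is essentially determined by its spectrum, and within these narrow bands
  spectral reshaping moves ApEn by only a few percent — measured, not
  assumed — so irregularity is steered through intermittency instead:
  larger burstiness κ makes the signal locally quiet relative to its
  global SD, lowering ApEn at fixed expected LL. Effects are signed
  `apen_shift` values with κ_eff = κ_base − shift (baseline κ = 0.45).
* Effect direction defaults mirror the reported group patterns: responder
  TC contacts get ×1.5 amplitude in high-gamma/ripple and +0.3 ApEn shift
  in low/ripple pre-op; post-op, responder non-TC contacts lose 20%
  amplitude in all bands and 0.3 ApEn shift in high-gamma/ripple;
  non-responder non-TC contacts gain 25% amplitude in low/ripple and lose
  0.3 ApEn shift in low/ripple. Non-responder TC contacts carry no effect.
  Log-normal jitter (patient scale 0.30, per-contact 0.10, per-period
  0.05, κ jitter 0.05) provides between-contact variability; TC post-op
  channels become low-amplitude white noise ("coagulated") and are removed
  by preprocessing anyway.
* `expected_directions(config)` derives the comparison pattern a
  configuration implies. The composite filtered band inherits LL direction
  from the consensus of shifted sub-bands (their diff-variance
  contributions are comparable) and ApEn direction from the
  amplitude-dominant low band alone; with the defaults this reproduces the
  full 2-groups × 2-designs × 4-bands target pattern.

### What the generator does *not* model

Stationary filtered Gaussian noise with burst envelopes contains no
spikes, high-frequency-oscillation events, seizures, electrode geometry,
volume conduction or non-stationarity beyond the slow envelope. Passing
recovery tests therefore shows that the *pipeline* detects the configured
amplitude/irregularity structure through the full preprocessing and
statistics chain — it does not validate the biomarkers against real
epileptic electrophysiology.

## Problem sizes of the statistical suites

The seed-replicated suites run on reduced cohorts that preserve the
default effect sizes and the 8:2 patient imbalance while shrinking contact
counts and window lengths (the ApEn kernel is the dominant cost, scaling
as the squared window length):

* end-to-end recovery and the acceptance script: 8 + 3 (responders) and
  6 + 2 (non-responders) non-TC + TC contacts per patient, 14 s at 512 Hz,
  five 2 s windows per contact;
* family-wise error under the null: 4 all-responder patients, 6 + 2
  contacts each, four 1 s windows, pre-op period only, 200 replicates.

## Known limitations

* **Reduced-montage reference crosstalk.** The average reference mixes
  ~1/C of the other channels into each channel. At desk scale (C ≈ 11)
  this mixture is a few percent of signal power and *differs between
  periods* because TC channels leave the post montage, which can nudge
  ApEn in unshifted bands across the pre/post comparison. At a realistic
  montage (C ≳ 100) the effect is negligible. Recovery checks therefore
  constrain configured directions (all must be significant with the
  matching tail, and nothing may oppose them) but leave zero-shift bands
  unconstrained in the paired design.
* The contact-level train/test split leaks patient identity; it is kept
  because it is the design whose arithmetic the package reproduces, and
  the leakage is disclosed in the results summary. The leakage is
  measurable: under patient-level label permutation the null test AUC
  stays well above 0.5 when patients contribute few contacts, because the
  within-subject z-scoring scale is then estimated from few rows and
  clusters a patient's delta vectors, which the classifier memorizes
  across the split. With more contacts and windows per patient the effect
  shrinks (non-identity permutations average ≈0.54 at 24 contacts/patient
  in the test suite). Identity relabellings — a shuffle that restores the
  original labelling — are excluded from null summaries.
* Exact nonparametric enumeration is limited to tie-free small samples;
  z-scored contact means make exact ties vanishingly rare.
* EDF output quantizes to 16 bits over each channel's observed range
  (relative error ≤ ~3 × 10⁻⁵ of the channel maximum).
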