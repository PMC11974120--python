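# seegtc

Interictal SEEG biomarkers and surgical-outcome prediction for
SEEG-guided radiofrequency thermocoagulation (RF-TC).

Stereo-electroencephalography (SEEG) records brain activity through depth
electrodes; in drug-resistant focal epilepsy whose epileptogenic zone lies
in functional cortex, thermocoagulation through those same electrode
contacts is an alternative to resection. A clinically important question is
whether short-term interictal recordings taken before and shortly after the
procedure can predict the long-term outcome. `seegtc` implements that
analysis end to end for researchers in clinical neurophysiology:

* **Preprocessing** — average-reference montage, manual-artifact masking,
  polyphase resampling of 1000/2000 Hz recordings to 500 Hz, zero-phase
  notches at 50 Hz and odd harmonics, and zero-phase Butterworth
  decomposition into four bands: filtered (0.5–250 Hz), low (0.5–50 Hz),
  high-gamma (50–80 Hz) and ripple (80–250 Hz), cut into non-overlapping
  10 s windows (20 windows from 200 s by default).
* **Biomarkers** — per window and band, line length
  `LL = Σᵢ |xᵢ − xᵢ₋₁|` and Pincus approximate entropy
  `ApEn = Φᵐ(r) − Φᵐ⁺¹(r)` (Chebyshev template matching, self-matches
  included, m = 2, r = 0.2 × window SD), normalized by within-subject
  z-scoring pooled over both periods.
* **Group statistics** — one-tailed Mann–Whitney U (pre-op
  thermocoagulated vs other contacts, TC > non-TC) and Wilcoxon
  signed-rank (pre vs post on non-TC contact means, both tails evaluated),
  Bonferroni-corrected within each 2-features × 4-bands family,
  separately for responders and non-responders.
* **Outcome prediction** — a two-level predictor: each non-TC contact
  contributes an 8-dimensional pre-minus-post feature vector; the class
  imbalance is handled by partitioning the positive (responder) training
  contacts into five subsets; an RBF support-vector classifier is selected
  by mean AUC under stratified 25-fold cross-validation; a patient's
  *response possibility* is the fraction of their contacts classified
  positive, and the patient is predicted a responder when it exceeds 0.5.
* **Synthetic cohorts** — because such clinical recordings are not
  publicly shareable, a first-class generator synthesises cohorts with the
  study design this package targets (10 patients, 8 responders, ≈834/163
  non-TC contacts, mixed 512/1000/2000 Hz rates) and band-specific effect
  directions, so the whole pipeline is testable from a seed.

## Worked example

```python
from seegtc import generate_cohort, scaled_config, analyze_cohort

cohort = generate_cohort(scaled_config(seed=1))        # reduced-scale cohort
res = analyze_cohort(cohort, window_s=2.0, total_s=10.0, seed=1)
print(res.outcome.summary())
```

prints

```
Two-level RF-TC outcome prediction
======================================================
samples: 76 non-TC contacts (64 pos / 12 neg)
split:   train 53+/10- | test 11+/2-  (seed 1)
chosen:  subset 0, params {'C': 0.1, 'gamma': 'scale'}, CV mean AUC 1.000
------------------------------------------------------
sensor-level test metrics
  accuracy   1.000
  precision  1.000
  recall     1.000
  f1         1.000
  auc        1.000
------------------------------------------------------
individual-level predictions (response possibility > 0.5)
patient_id       outcome  response_possibility     predicted
       P01     responder                 1.000     responder
       P02     responder                 1.000     responder
       P03 non_responder                 0.000 non_responder
       ...
individual accuracy: 1.00
```

The sensor-level metrics score the held-out test contacts; the
individual-level table applies the strict >0.5 response-possibility rule
per patient. `res.comparisons` holds the Bonferroni-corrected group
comparisons (here the configured effect directions — e.g. elevated
pre-operative LL and ApEn on thermocoagulated contacts of responders, and
the diverging post-operative LL shifts between responders and
non-responders — come out significant with the right tails).

The same stages run from the shell against EDF + TSV inputs or a simulated
cohort:

```bash
seegtc run --out myrun --seed 1          # simulate → features → stats → predict → report
seegtc stats --config myrun/run_config.yaml
```

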