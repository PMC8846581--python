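# erpbci

Closed-loop auditory ERP brain–computer-interface training for language
rehabilitation, simulated end to end.

In the training task a listener hears a sentence whose final word is
missing, then attends to that target word inside a rapid sequence of six
words (15 presentations each, 15 + 75 = 90 stimuli per trial, SOA
250–1000 ms, spatial loudspeaker or mono headphone presentation).
Attended (target) words evoke a larger P300 — and an N200 shared by both
classes — and a classifier decodes from the EEG which word was attended,
returning graded feedback within seconds. This package implements that
entire loop on a built-in synthetic EEG simulator, plus the offline ERP
readouts and the clinical effect-size statistics used to evaluate such
trainings, so every stage is testable without any recording hardware or
data download.

## What's inside

- **`paradigm`** — reproducible word-oddball schedules (blockwise
  pseudo-random, no immediate repeats, target roles balanced across each
  six-trial run) and the 50/250 tone-oddball control.
- **`simulate`** — continuous multichannel EEG: rank-1 Gaussian ERP
  templates (N200 at Fz, P300 at Cz) in 1/f + alpha background noise,
  with patient-like degradation (attenuation, latency delay, missed
  targets, artefact bursts, lateralized topographies).
- **`preprocessing`** — zero-phase 0.5–8 Hz band-pass, −200…800 ms
  epochs with baseline correction, peak-to-peak artefact rejection,
  interval-mean features (6 windows × 31 channels = 186 dimensions).
- **`decoder`** — shrinkage-regularized LDA: Σ(γ) = (1−γ)Σ̂ + γνI with
  ν the mean empirical eigenvalue and γ from Ledoit–Wolf;
  w = Σ(γ)⁻¹(μ₊ − μ₋). Supervised adaptation
  μ_c ← (1−η₁)μ_c + η₁x, Σ ← (1−η₂)Σ + η₂(x−μ̄)(x−μ̄)ᵀ
  (defaults η₁ = 0.005, η₂ = 0.001); transfer initialization from prior
  sessions; 5-fold *chronological* cross-validation scored as AUC.
- **`closed_loop`** — per-word evidence accumulation, argmax word
  selection, dynamic stopping (best-vs-rest Welch t-test after ≥5
  blocks, p < 0.01) and three-level feedback (very positive / positive
  / neutral).
- **`erp_metrics`** — grand averages, bootstrap peak amplitude/latency
  (10 resamples of 80% of epochs), the pointwise-t P300 onset rule with
  its 1000 ms fallback, interval topographies.
- **`clinical_stats`** — d_s = (mean(z_post) − mean(z_pre))/10 for
  T-scored tests, Hedges g_s with pooled SD and small-sample correction,
  paired t / Wilcoxon tests, Benjamini–Hochberg FDR, and the
  maximal-possible-change metric 100·(post − pre)/(530 − pre); the
  published assessment tables ship as CSV fixtures.
- **`cli`** — `erpbci simulate | decode-offline | run-closed-loop |
  erp-report | clinical-stats`, all seeded and manifest-logged.

## Worked example

```sh
$ erpbci decode-offline --seed 3
mean AUC 1.000 (folds: 1.000, 1.000, 1.000, 1.000, 1.000)
```

The default healthy profile (P300 +5 µV, noise 4 µV RMS) is easy after
filtering — the decoder separates the classes perfectly. The patient
regime (halved amplitude, +150 ms delay, 20% missed targets, artefacts)
is the interesting one; with `profile: {kind: patient}` in a YAML config:

```sh
$ erpbci decode-offline --config patient.yaml --seed 3
mean AUC 0.724 (folds: 0.701, 0.720, 0.778, 0.780, 0.641)
$ erpbci run-closed-loop --config patient.yaml --seed 3
accuracy 0.50 over 6 trials, mean stimuli 63.0
```

So the impaired decoder still finds the attended word in half the
trials (chance is 1/6) while dynamic stopping cuts the mean sequence
from 90 to 63 stimuli. The clinical statistics reproduce the published
assessment arithmetic from the bundled tables:

```sh
$ erpbci clinical-stats
d_s[token] = 0.44
d_s[repetition] = 0.38
d_s[written_language] = 0.66
d_s[naming] = 1.10
d_s[comprehension] = 0.57
overall SMD = 0.63
hedges_gs[cal_quantitative] = 0.46
hedges_gs[cal_qualitative] = 0.29
max change realized: mean 49% (range 11-88%, SD 26.85%)
```

Here d_s is the mean T-score change over the fixed scale SD of 10, the
overall SMD is the mean across the five subtests, and "max change
realized" expresses each patient's raw-point gain as a percentage of
the improvement still available on the 530-point scale.

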