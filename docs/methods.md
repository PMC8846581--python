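# Methods

## Paradigm model

A trial presents each of six words `repetitions_per_word` times (default
15; 90 stimuli) at a fixed stimulus onset asynchrony (SOA, 250–1000 ms).
Sequences are generated blockwise: 15 successive random permutations of
the six words, resampled so no word repeats across a block boundary.
This is stricter than the minimal "no identical consecutive stimuli"
constraint, and was chosen deliberately: it makes the per-word
presentation counts advance in lockstep (the closed-loop iteration count
is well defined after every sixth stimulus) and guarantees that a trial
stopped after *k* blocks has presented exactly 6·k stimuli. Within a run
the six sentences (each cueing its paired target word) appear in a
uniformly random order, so every word is the target exactly once per
run. In the loudspeaker condition a fresh word→direction permutation
(1–6) is drawn per trial; the headphone condition maps everything to
mono (direction 0). Onsets are continuous-time seconds with a 2 s
lead-in per trial and a 5 s inter-trial gap (stand-ins for the sentence
cue and feedback periods, which are not modelled). The tone-oddball
control is a shuffled multiset of 50 high (target) and 250 low
(non-target) tones at 1 s SOA.

## Synthetic EEG

Each ERP component is a rank-1 space–time template: a Gaussian temporal
envelope (parameterized by latency and width = the Gaussian SD) times a
fixed scalp topography, `exp(-d²/2s²)` around a peak electrode on an
approximate 2-D 10–20 layout (31 channels, spread s = 0.6 head radii).
Defaults: N200 −3 µV at 200 ms (SD 40 ms, Fz-max, identical for both
classes) and P300 +5 µV at 400 ms (SD 90 ms, Cz-max, target-specific).
These magnitudes, and the patient profile (attenuation 0.5, +150 ms
delay, miss probability 0.2, 2 artefact bursts/min, 0.3 lateral
topography shift, 6 µV noise), are simulator fixtures chosen to be
physiologically plausible — they are not measured values from any
patient group.

Background noise is spectrally shaped white noise (1/√f amplitude, no
DC) mixed with a 10 Hz oscillation carrying 30% of the variance,
rescaled exactly to the requested per-channel RMS (default 4 µV).
Artefacts are Poisson-timed 100–500 ms Hann bursts of ±100–500 µV on
frontal channels. Target stimuli drop their target-specific components
independently with the profile's miss probability (attention lapses);
non-targets always receive the shared components. Sampling rate defaults
to 100 Hz — ample for the ≥40 ms envelopes; a Nyquist-style check
rejects rates below ~3 samples per narrowest envelope SD.

What the simulator does *not* emulate: biophysical volume conduction,
ocular/EMG artefact morphology, inter-trial ERP variability beyond
misses, habituation, or any real aphasic physiology. Passing tests
demonstrate the correctness and calibration of the pipeline, not
clinical performance on real patients.

## Preprocessing

Zero-phase Butterworth (order 4, applied forward–backward) band-pass,
default 0.5–8 Hz. Epochs span [−200, 800) ms with the t = 0 sample on
the marker; baseline is the mean over [−200, 0). Artefact rejection
masks epochs whose any-channel peak-to-peak exceeds 150 µV (after
filtering). Features are mean amplitudes over six half-open windows —
[50,150), [150,250), [250,350), [350,450), [450,600), [600,800) ms —
per channel, ordered interval-major. All of these are config-exposed
choices: the later windows track the canonical P300 analysis intervals
(191–240 / 301–420 / 421–670 / 671–800 ms), the earlier ones cover the
N200.

## Decoder

Pooled within-class covariance (maximum-likelihood divisor n, matching
the analytic-shrinkage derivation) shrunk toward ν·I with ν the mean
empirical eigenvalue; shrinkage intensity γ from the Ledoit–Wolf
analytic formula on class-centered rows, clipped to [0, 1].
w solves Σ(γ)w = μ₊ − μ₋; the bias puts the boundary midway between
projected class means (equal priors — the 15:85 class imbalance is
acknowledged, but AUC and argmax word selection are prior-free).
Supervised adaptation applies the exponential updates per epoch in
chronological order and recomputes (w, b) once per batch ("after each
run"), keeping γ fixed at its initial estimate; the covariance update
deviates from the pooled (equal-prior) mean of the *current* class
means. Chronological cross-validation splits rows into k = 5 contiguous
blocks; the headline AUC is the mean of per-fold AUCs (the pooled
variant is also reported).

## Closed loop and dynamic stopping

The original early-stopping criterion is not public; we adopt a
standard evidence test: after every complete block (and at least
`min_iterations` = 5 of them), a one-sided Welch t-test of the current
best word's outputs against the pooled outputs of the other five words;
stop at p < 0.01. "Insufficient ERP difference" for neutral feedback is
operationalized as best-vs-rest AUC < 0.65. Both thresholds and the
very-positive trigger (correct *and* stopped early) are config-exposed
reconstructions, not published values. Note the best-vs-rest selection
inflates the nominal test level, so the realized early-stop rate under
the null is above 1% per test but stays far below 1 per trial; the null
calibration test bounds it empirically.

## ERP readouts

Peak estimation averages 10 readouts from random 80% subsamples (drawn
without replacement) of the target epochs: subsample-average, then
signed extremum within the search window — 150–300 ms at Fz (negative)
for the N200, 250–800 ms at Cz (positive) for the P300; the windows are
our defaults, only the channels are conventional. The P300 onset is the
first sample in (0, 1000] ms where a pointwise two-sided two-sample
t-test across epochs is significant at α = 0.05, with 1000 ms returned
when none is — exactly that rule, with no multiple-comparison
correction and no consecutive-sample requirement. Zero-variance samples
count as significant iff the class means differ.

Two consequences of taking the rule literally, both visible in tests:
(1) with class-independent noise the pre-onset scan false-positives
with probability ≈ 1 − 0.95^k over k scanned samples, biasing the
estimate early at *any* SNR — onset-recovery tests therefore use a
paired construction in which both classes share the background noise,
so the pre-onset difference is exactly zero and detection occurs at the
true onset; (2) with Gaussian-envelope components the class contrast
has unbounded support, so on large simulated sessions the detected
"onset" can legitimately precede the nominal component onset. Whether
the original analysis tested single epochs or subject-level averages is
ambiguous; epoch-level input is implemented (`p300_onset` accepts raw
epoch matrices, so any aggregation can be applied upstream).

The default two-component simulation also superposes the P300's
positive tail onto the N200 window at Fz, reducing the combined N200
readout by ~11%; exact recovery holds for single-component data.

## Clinical statistics

d_s divides the mean T-score change by the scale's fixed SD of 10.
Hedges g_s uses the two-group pooled SD over df = n_pre + n_post − 2
and J = 1 − 3/(4df − 1); this variant reproduces both published CAL
effect sizes from their printed means/SDs, which is the evidence for
adopting it over a paired-denominator variant. The
maximal-possible-change metric is 100·(post − pre)/(530 − pre) per
patient (530 = the scale maximum), summarized by mean/range/SD; this
implied formula reproduces the printed summary exactly. Wilcoxon uses
the exact null distribution for ≤25 untied pairs, otherwise the normal
approximation with continuity correction; zero differences are dropped.
Benjamini–Hochberg is the standard step-up procedure.

## Problem sizes and numerics

Default simulated sessions are one six-trial run (540 epochs, ~2.5 min
of 31-channel EEG at 100 Hz) — large enough for stable CV folds and
fast enough to average over tens of seeds in the test suite; the chance
calibration uses 50 label permutations of one such session. Covariance
solves use LAPACK `solve` on the shrunk matrix (γ > 0 guarantees
positive definiteness; γ = 0 on singular data raises). Ties in word
selection break toward the lowest word id. EEG round-trips through a
float32 array container with a JSON sidecar (fs, channels, markers);
events through BIDS-style TSV.

## Known limitations

Simulator realism as above; the stopping statistic and feedback
thresholds are reconstructions; adaptation recomputes weights per run,
not per epoch; no ocular-artifact correction or re-referencing; the
published clinical outcomes themselves (patient effect sizes on real
assessments) are inputs to the statistics modules, not quantities this
package can re-derive.
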