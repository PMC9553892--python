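# Methods

## The question the package operationalizes

EEG-based person identification can rest on two kinds of signal: stable,
task-independent spectral structure ("brainprints", plausibly anatomical in
origin) or task-dependent cognitive activity ("mindprints"). A longitudinal
monozygotic-twin design separates the two: if a classifier trained on one
week and one task identifies the same person in another week and another
task, the identifying component must be a stationary *base signal*; and if
that base signal is partly inherited, twin siblings should be confused with
each other far more often than unrelated people, least so on late-maturing
(frontal) scalp regions.

The raw recordings behind the original twin study are not publicly
deposited, so this package ships a synthetic twin-cohort generator with a
known planted base signal, plus the full analysis battery. Every claim the
battery tests on synthetic data is a claim about the *pipeline* —
sensitivity, calibration, orderings — not new evidence about real brains.

## Signal model

Each channel of a recording is spectrum-shaped Gaussian noise: white
Gaussian noise is drawn in the frequency domain, scaled so that its
one-sided power spectral density equals a target, and inverse-FFT'd. This
is the simplest generative model whose PSD — the only statistic the
analysis pipeline consumes — is exactly controllable. There are no
oscillator banks, evoked responses, or within-task nonstationarities.

The target PSD of subject *s*, channel *c* factors as

    log S_s(c, f) = log S0(f) + u_p(f) + v_p(c, f)
                    + d_sh * z_s(f) + d_reg(c) * z_s(c, f)     (base signal)
    S_target = exp(log S_s + drift_w(f)) * task_gain(c, f) + noise(f)

* `S0(f)` — population mean: `20/(1+f)^1.5` background, a Gaussian alpha
  peak at 10 Hz (height 1.5, width 2 Hz), floor 0.02 (arbitrary power
  units; downstream z-scoring removes scale).
* All deviations are smooth Gaussian-process draws over frequency
  (squared-exponential kernel, length scale 2 Hz, sampled on the 0.5 Hz
  analysis grid), in natural-log power units.
* `u_p` (sd 0.5, shared across channels) and `v_p` (sd 0.3, per channel)
  are the **pair template**: what both twins inherit.
* `z_s` terms are the **within-pair divergence**: a channel-shared part
  (`d_sh = 0.04`) and a per-channel part scaled by region,
  `d_reg = 0.07 x {frontal 1.0, central 0.6, temporal 0.6, parietal 0.5,
  occipital 0.2, unassigned 0.5}`. Frontal-dominant divergence is the
  planted analog of the developmental hypothesis the regional experiment
  probes; the channel-shared parts (of both template and divergence) are
  what the cross-channel experiment detects.
* `drift_w` — per-subject random walk over weeks (increment sd 0.1 per
  week, smooth over frequency, shared across channels and tasks within a
  week; zero in week 1). This produces the slow cross-week degradation.
* `task_gain` — narrow-band multiplicative gains: eyes-closed rest boosts
  posterior alpha x2.0 (Berger effect); executed movement scales central
  alpha x0.6 and motor imagery x0.75 (mu suppression). All other tasks,
  including the free task, share the unmodulated base spectrum.
* `noise(f) = 0.05 + 0.5/(1+f)` — subject-independent floor.
* Blinks: Poisson events (12/min) of a smooth 120-ms Gaussian pulse,
  amplitude 60 units on VEO (0.3x on HEO), coupled into the scalp at
  `0.4 x` a front-to-back topography (1.0 at FP1/2 decaying to 0 behind
  the central row).

### Calibration of the divergence scales

The divergence defaults are knobs, not estimates of the real cohort. They
were set once so that the default cohort sits in the qualitative regime the
original study reports: non-twin 10-person identification nearly perfect,
twin identification high but imperfect, with the residual confusion
concentrated inside twin pairs. Divergence much above these values makes
twins as separable as strangers (all orderings collapse to 100% vs 100%);
much below, twin identification approaches the coin-flip limit. The chosen
values leave raw twin discrimination at roughly 80% so that session-level
drift occasionally flips a sibling decision even after voting — the
phenomenon the cross-twin experiment exists to measure.

## Study design constants

10 twin pairs (subjects 1..20, consecutive ids = one pair), 4 weekly
sessions, eleven task conditions per session (`rce roe mli mri ili iri mbi
mbe ibi ibe fre`), 65 s per task at 500 Hz, 30 scalp + 2 EOG channels.
One block per session is generated (the original design has several); the
free task is trimmed from 5 min to 65 s at desk scale. Missing cells (the
study lost one block) are supported via `CohortConfig.missing` and simply
absent from outputs.

## Pipeline

1. **QC** — a sample is extreme when it deviates from the instantaneous
   cross-channel mean by > 5 cross-channel sds; a channel is flagged when
   its extreme fraction strictly exceeds 15%. Report-only: flags are
   surfaced, never auto-excluded (the emulated study excluded nothing).
2. **EOG removal** — per subject, recordings are concatenated, FastICA
   (fixed seed, components = scalp channel count) is fitted on the scalp
   channels, and components whose EOG correlation is an adaptive-z outlier
   (z > 3.0 across components) are projected out. Because every non-blink
   source here is Gaussian, FastICA can only meaningfully converge on the
   blink direction; iterations are capped at 100, which isolates it at a
   fraction of the cost. The streaming pipeline fits the ICA on the
   eyes-closed-rest recordings of each week (~4 min of signal) and applies
   it to everything — estimating one blink component does not need the full
   session. ICA precedes z-scoring; the ordering is a convention of this
   package.
3. **z-scoring** — per channel within one recording (the narrowest reading
   of per-channel standardization; scope configurable upstream).
4. **Features** — 2-s Hann-tapered periodogram (0.5 Hz grid) per sliding
   window (1000 samples, 50% overlap), keeping theta 4–8 Hz (8 bins, upper
   edge open), alpha 8–12 Hz (8 bins), beta 12–29 Hz (35 bins, upper edge
   kept). log10 power with a 1e-12 floor stabilizes the linear model
   (configurable off). Concatenated mode: 30 x 51 = 1530 features per
   window (64 windows per 65-s task). Channel-wise mode: 51 features per
   channel per window at 0% overlap (960 rows per task, 15x the
   concatenated count; 30x at 50% overlap). The estimator is a plain
   per-segment periodogram — a spectrogram column — rather than
   within-segment Welch averaging; it is pluggable behind `compute_psd`.
5. **Classifier** — one-vs-all L2 logistic regression (scikit-learn
   defaults: lbfgs, tol 1e-4, no class weights, max_iter raised to 1000 for
   determinism of the converged optimum). C is grid-searched over
   {1e-2, 1e-1, 1, 10, 100} by 10-fold CV in which whole recordings
   (~64 segments) are shuffled and assigned to folds as groups; ties go to
   the smallest C.
6. **Voting** — majority over a sliding window of 15 consecutive raw
   predictions, stride 1, never crossing recording boundaries; modal ties
   go to the lowest subject id (any deterministic rule works; this one is
   the simplest). 64 raws become 50 finals.

## Experiment protocols

Multi-repetition protocols draw 10 subjects per repetition — one per pair
("non-twin") or 5 whole pairs ("twin") — train on weeks 1–3 and test on
week 4 unless stated, and report mean ± se of final-vote accuracy over
repetitions. Specific choices that were genuinely open:

* **Chance calibration** permutes training labels at the *segment* level
  (the exchangeability null). Permuting whole recordings instead leaves
  each permutation's accuracy with very heavy tails — final votes within a
  session are strongly correlated, so a handful of effectively independent
  decisions per session dominate — and a mean near 10% would need ~100
  refits. Recording-level permutation remains available
  (`unit="recording"`).
* **Indistinguishable-twin limit** (divergence 0): evaluated on raw-level
  confusion with week drift also zeroed. Drift is itself person-specific —
  with it on, "identical" twins remain distinguishable in principle and
  every week-4 row collapses to whichever sibling the session drift
  resembles. Raw predictions give ~700 exchangeable decisions per row
  where 550 overlapping votes give ~10 effectively independent ones.
* **Cross-task matrix** trains on a single task's weeks 1–3 per cell.
* **Single-day protocol** splits each recording's segments 2:1 in time
  (earlier segments train) within one week.
* **Weight-spectrum similarity of twins** is computed from two
  complementary non-twin models (each sibling discriminated only against
  unrelated people). When both siblings are trained in one model, their
  one-vs-all discriminators are forced to separate the pair and anti-align
  — the similarity of the underlying base signals shows only when the
  sibling is out of the training set.

## Numerical and degenerate-input conventions

Zero-variance channels abort z-scoring by name; all-constant QC input is an
error (fractions undefined), never silently zero. A QC extreme fraction of
exactly 0.15 passes (strict inequality). Synthesis rejects negative PSDs;
the DC bin is never excited. Voting rejects groups shorter than the window.
Accuracy of an empty prediction set is an error, not 0. Cohorts are
bit-reproducible: every recording's random stream is derived from
(seed, subject, week, task) independently of generation order, so streaming
and materialized generation agree exactly.

## Problem sizes

The default battery — the one `scripts/acceptance.py` runs — uses the full
default cohort (20 subjects x 4 weeks x 11 tasks, 56,320 concatenated
feature vectors), 5 repetitions of person sampling for headline accuracies
(2–3 for the regional and cross-task grids), one tuned C shared across
protocols, and channel-wise features restricted to the four representative
tasks (rest closed/open, move both fists, imagine both fists). These sizes
keep a full run in the tens of minutes on one CPU; repetition counts are
arguments everywhere.

## Known limitations

* No volume conduction, head geometry, or channel covariance: channels are
  statistically independent given their PSDs, so inter-electrode
  correlation structure cannot contribute to identification here, by
  construction.
* Stationary within a recording; no evoked dynamics, no 1/f knee, no line
  noise.
* Task modulations are hard band-edge gains, not smooth spectral bumps.
* EDF export is not provided; recordings interoperate via
  `Recording.to_mne_raw()` and a float32 `.dat` + JSON sidecar container.
* Accuracies on this synthetic cohort are regression anchors for the
  pipeline, not estimates of real-world identification rates; the
  divergence knobs were set by the calibration argument above, not fitted
  to data.
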