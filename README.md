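# brainprint

Synthetic twin-cohort EEG and spectral person identification: a fully
testable re-implementation of the "base signal" analysis — can a linear
classifier identify who is wearing the EEG cap from band-power features
alone, across weeks, across tasks, and between monozygotic twins?

## The problem

EEG spectra are strikingly person-specific. If the identifying component is
a stationary, task-independent *base signal* (a brainprint), a classifier
trained on one week's resting data should recognize the same person a month
later while they play with their phone. If that base signal is partly
inherited, identical twins should be the hardest people to tell apart — and
least so over late-maturing frontal cortex. Testing a pipeline for these
questions requires data with known ground truth; the original twin
recordings are not public. This package therefore pairs

* a **generator** that synthesizes a 10-pair twin cohort (20 subjects, 4
  weekly sessions, eleven 65-s tasks, 30 scalp + 2 EOG channels at 500 Hz)
  as spectrum-shaped Gaussian noise with planted, heritable, frontal-
  divergent per-person spectra, weekly drift, task band-gains (Berger
  effect, mu suppression) and blink artifacts, with
* the full **analysis battery**: channel QC, ICA-based EOG removal,
  per-channel z-scoring, 2-s Hann periodogram band-power features (theta
  4–8, alpha 8–12, beta 12–29 Hz; 30 x 51 = 1530 features per segment),
  one-vs-all L2 logistic identification with grouped 10-fold tuning of C,
  and sliding-window majority voting (15 raw predictions per final vote),

plus the experiment protocols: cross-week, cross-task, cross-twin
(20-person confusion), cross-channel (channel-wise features), regional
(single scalp areas), chance calibration by label permutation, and
weight-spectrum inspection. `docs/methods.md` has the model and every
protocol decision.

Audience: anyone building or reviewing EEG biometrics / individual-
differences pipelines who wants a ground-truthed sandbox rather than a
download.

## A worked example

```python
from brainprint import (CohortConfig, VotingScheme, accuracy,
                        cohort_features, fit, predict_raw, tune_C, vote)

config = CohortConfig(n_pairs=3, weeks=2, tasks=("rce", "roe", "mbi"), seed=42)
features, _ = cohort_features(config, use_ica=False)

train = features.subset(weeks=[1])
C = tune_C(train, grid=(0.01, 1.0), n_folds=10)   # grouped 10-fold CV
model = fit(train, C=C)

raw = predict_raw(model, features.subset(weeks=[2]))
final = vote(raw, VotingScheme(window=15))
print(accuracy(raw), accuracy(final))
```

prints (`examples/03_identify_and_vote.py`):

```
raw predictions:   1152 segments,  68.49% correct
final predictions:  900 votes,     89.44% correct
```

Six subjects (three twin pairs), trained on week 1, tested on week 2: each
2-s segment alone identifies the right person 68% of the time (chance
17%), and majority voting over 15 consecutive segments lifts that to 89% —
the residual errors are almost entirely twin-sibling swaps. The
`examples/` directory walks through every capability: cohort generation
and ground truth (01), preprocessing and the Berger/mu sanity effects
(02), identification and voting (03), twin vs non-twin protocols and
confusion structure (04), regional identification and weight spectra (05).

There is also a thin CLI (`brainprint generate | features | train |
predict | experiment`) over the same functions.

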