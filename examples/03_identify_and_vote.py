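"""Train a person identifier and watch majority voting sharpen it.

Small cohort (3 pairs, 2 weeks): band-power features from week 1 train a
one-vs-all logistic model, week 2 is the held-out test. The voting step
turns each task's 64 raw per-segment predictions into 50 final ones.
"""

from brainprint import (
    CohortConfig, VotingScheme, accuracy, cohort_features, fit,
    predict_raw, tune_C, vote,
)

config = CohortConfig(n_pairs=3, weeks=2, tasks=("rce", "roe", "mbi"), seed=42)
features, _ = cohort_features(config, use_ica=False)
print(f"features: {features.n_samples} segments x {features.n_features} "
      f"(30 channels x 51 band bins)")

train = features.subset(weeks=[1])
C = tune_C(train, grid=(0.01, 1.0), n_folds=10)
model = fit(train, C=C)
print(f"tuned C = {C} by grouped 10-fold CV (whole recordings per fold)")

raw = predict_raw(model, features.subset(weeks=[2]))
final = vote(raw, VotingScheme(window=15))
print(f"raw predictions:   {len(raw):4d} segments, {accuracy(raw):6.2f}% correct")
print(f"final predictions: {len(final):4d} votes,    {accuracy(final):6.2f}% correct")
print("each 64-segment task contributes 64 - 15 + 1 = 50 final votes; "
      "voting integrates 30 s of evidence per decision.")
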