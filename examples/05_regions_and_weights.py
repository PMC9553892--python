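"""Regional identification and the classifier's weight spectra.

Restricting features to single scalp regions shows where twin-separating
information lives (frontal, by construction); the per-subject logistic
weight vectors are the readable 'cartoon' of each person's base signal.
"""

import numpy as np

from brainprint import CohortConfig, cohort_features
from brainprint.experiments import (
    complementary_nontwin_weights, run_regional, sample_persons,
    sibling_vs_nonsibling_correlation, weight_similarity,
)

config = CohortConfig(n_pairs=4, weeks=4, tasks=("rce",), seed=23)
features, _ = cohort_features(config, use_ica=False)

twin = sample_persons(config.n_pairs, "twin", n_reps=3, seed=23)
regions = {"frontal": ("FP1", "FP2", "F3", "F4", "F7", "F8", "FZ"),
           "occipital": ("O1", "OZ", "O2")}
res = run_regional(features, {"twin": twin}, region_map=regions, tasks=("rce",))
table = res.extra["table"]["mean"]
print("twin identification from a single region (rce, mean of 3 samplings):")
for region in ("frontal", "occipital"):
    print(f"  {region:9s}: {table[region].iloc[0]:6.2f}%")
print("frontal wins: the generator plants 5x larger within-pair divergence "
      "on frontal than occipital channels.")

sample = sample_persons(config.n_pairs, "nontwin", n_reps=1, seed=23)[0]
weights = complementary_nontwin_weights(features, sample)
sib, non = sibling_vs_nonsibling_correlation(weight_similarity(weights))
print(f"\nweight-spectrum correlation (sibling-free models): "
      f"twins {sib:+.2f}, unrelated {non:+.2f}")
print("twin weight spectra resemble each other because the base signals "
      "they caricature are largely shared within a pair.")
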