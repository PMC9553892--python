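"""Render the confusion matrix and twin weight spectra as figures.

Writes two PNGs next to the script's working directory: the row-normalized
confusion matrix of a small all-subjects run (twin pairs on consecutive
ids, so sibling confusion shows up just off the diagonal) and one panel of
per-subject weight spectra for a twin pair.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from brainprint import CohortConfig, cohort_features
from brainprint.experiments import (
    evaluate_split, extract_base_signal_weights, run_confusion,
)

config = CohortConfig(n_pairs=4, weeks=4, tasks=("rce", "roe", "mbi"), seed=19)
features, _ = cohort_features(config, use_ica=False)

res = run_confusion(features)
fig, ax = plt.subplots(figsize=(5, 4.5))
im = ax.imshow(res.confusion.to_numpy(), cmap="Greens", vmin=0, vmax=1)
ax.set_xlabel("predicted subject")
ax.set_ylabel("true subject")
ax.set_xticks(range(8), res.confusion.columns)
ax.set_yticks(range(8), res.confusion.index)
ax.set_title("row-normalized confusion (consecutive ids = twins)")
fig.colorbar(im, ax=ax)
fig.tight_layout()
fig.savefig("confusion.png", dpi=120)
print(f"wrote confusion.png ({res.per_rep['final'].iloc[0]:.1f}% final accuracy)")

model = evaluate_split(features, features.subjects, [1, 2, 3], [4])["model"]
weights = extract_base_signal_weights(model)
fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
for ax, subject in zip(axes, (1, 2)):
    w = weights["weights"][subject]  # channels x frequency bins
    ax.plot(weights["freqs"], w.mean(axis=0))
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_title(f"subject {subject} (twin pair 1)")
    ax.set_xlabel("frequency (Hz)")
axes[0].set_ylabel("mean weight across channels")
fig.suptitle("per-subject weight spectra: the classifier's 'base signal' caricature")
fig.tight_layout()
fig.savefig("weight_spectra.png", dpi=120)
print("wrote weight_spectra.png")
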