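"""Generate a small twin cohort and inspect its planted spectral truth.

Builds 2 twin pairs x 2 weeks x 3 tasks, prints the recording inventory and
shows that twin siblings' base spectra are closer to each other than to
unrelated subjects — the ground truth every downstream experiment probes.
"""

import numpy as np

from brainprint import CohortConfig, generate_cohort

config = CohortConfig(n_pairs=2, weeks=2, tasks=("rce", "roe", "mbi"), seed=7)
recordings, truth = generate_cohort(config)

print(f"{len(recordings)} recordings "
      f"({config.n_subjects} subjects x {config.weeks} weeks x {len(config.tasks)} tasks)")
rec = recordings[0]
print(f"each: {rec.n_channels} channels x {rec.n_samples} samples "
      f"@ {rec.sampling_rate:.0f} Hz ({rec.duration:.0f} s)")

logp = {s: np.log(p) for s, p in truth.base_profiles.items()}
print("\nlog-spectral distance between subject 1 and ...")
for other in (2, 3, 4):
    d = np.linalg.norm(logp[1] - logp[other])
    tag = "sibling" if other == 2 else "unrelated"
    print(f"  subject {other} ({tag:9s}): {d:6.1f}")
print("the sibling distance is smallest: twins share their pair template "
      "and differ only by the (frontal-dominant) divergence terms.")
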