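"""QC, blink removal and the two physiological sanity effects.

Runs the preprocessing chain on one subject and checks that the planted
Berger effect (posterior alpha rises with closed eyes) and mu suppression
(central alpha falls during movement) survive it — the standard evidence
that a pipeline is looking at EEG-like signal rather than artifact.
"""

import warnings

import numpy as np

from brainprint import (
    CohortConfig, build_dataset, make_ground_truth, generate_recording,
    qc_bad_channels, remove_eog_components, sanity_berger, sanity_mu,
    zscore_channels,
)

warnings.filterwarnings("ignore")

config = CohortConfig(n_pairs=1, weeks=1, tasks=("rce", "roe", "mbi"),
                      task_duration=40.0, blink_rate=15.0, seed=3)
truth = make_ground_truth(config)
recs = [generate_recording(config, truth, 1, 1, t) for t in config.tasks]

qc = qc_bad_channels(recs[0])
print(f"QC: {int(qc.flagged.sum())} flagged channels, "
      f"max extreme fraction {qc.fractions.max():.3f} (threshold 0.15)")

def fp1_veo_corr(r):
    return abs(np.corrcoef(r.get_data(['FP1'])[0], r.get_data(['VEO'])[0])[0, 1])

before = max(fp1_veo_corr(r) for r in recs)
cleaned, info = remove_eog_components(recs)
after = max(fp1_veo_corr(r) for r in cleaned)
print(f"ICA removed component(s) {info['excluded']}; "
      f"max |corr(FP1, VEO)| {before:.2f} -> {after:.2f}")

features = build_dataset([zscore_channels(r) for r in cleaned])
berger = sanity_berger(features)["summary"]["mean_difference"]
mu = sanity_mu(features)["summary"]["mean_difference"]
print(f"Berger rce-roe = {berger:+.2f} log10 power (expect > 0), "
      f"mu move-rest = {mu:+.2f} (expect < 0)")
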