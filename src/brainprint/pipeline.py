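"""End-to-end helpers: stream a synthetic cohort through preprocessing and
feature extraction without ever holding the raw cohort in memory."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import features as feat
from . import preprocess, synth
from .features import BandScheme, FeatureSet, SegmentationScheme


def preprocess_recording(rec, ica=None, zscore: bool = True):
    if ica is not None:
        rec = preprocess.apply_eog_ica(ica, rec)
    if zscore:
        rec = preprocess.zscore_channels(rec)
    return rec


def cohort_features(
    config: synth.CohortConfig,
    mode: str = "concatenated",
    tasks=None,
    weeks=None,
    bands: BandScheme | None = None,
    segmentation: SegmentationScheme | None = None,
    use_ica: bool = True,
    ica_fit_tasks=("rce",),
    ica_config: preprocess.ICACleanConfig | None = None,
    zscore: bool = True,
    zscore_scope: str = "recording",
    log_power: bool = True,
    qc: bool = True,
) -> tuple[FeatureSet, dict]:
    """Generate the cohort and return its FeatureSet plus a QC/ICA report.

    Recordings are generated, cleaned and reduced to features one at a
    time, subject by subject: only features survive, keeping memory flat.
    The per-subject ICA is fitted on the ``ica_fit_tasks`` recordings from
    every week (a few minutes of signal suffice to isolate the blink
    components) and then applied to all of that subject's recordings.

    ``tasks`` / ``weeks`` optionally restrict generation; QC reports are
    collected per recording and any flagged channel is recorded (never
    auto-excluded). ``zscore_scope`` standardizes each channel within one
    recording (default) or with statistics pooled over a whole session
    ("session": one subject-week's tasks together).
    """
    if zscore_scope not in ("recording", "session"):
        raise ValueError("zscore_scope must be 'recording' or 'session'")
    tasks = tuple(tasks) if tasks is not None else config.tasks
    weeks = tuple(weeks) if weeks is not None else tuple(range(1, config.weeks + 1))
    unknown = set(tasks) - set(config.tasks)
    if unknown:
        raise ValueError(f"tasks not in cohort config: {sorted(unknown)}")
    gt = synth.make_ground_truth(config)
    report: dict = {"qc_flags": [], "ica": {}}
    parts: list[FeatureSet] = []
    for subject in config.subjects:
        ica = None
        if use_ica and config.eog_channels:
            fit_recs = [
                synth.generate_recording(config, gt, subject, w, t)
                for w in weeks
                for t in ica_fit_tasks
                if (subject, w, t) not in config.missing and t in config.tasks
            ]
            if fit_recs:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ica, info = preprocess.fit_eog_ica(fit_recs, ica_config)
                report["ica"][subject] = info
        for w in weeks:
            recs = []
            for t in tasks:
                if (subject, w, t) in config.missing:
                    continue
                rec = synth.generate_recording(config, gt, subject, w, t)
                if qc:
                    qcr = preprocess.qc_bad_channels(rec)
                    if qcr.any_flagged:
                        flagged = [
                            c for c, b in zip(qcr.channel_names, qcr.flagged) if b
                        ]
                        report["qc_flags"].append(
                            {"subject": subject, "week": w, "task": t,
                             "channels": flagged}
                        )
                recs.append(
                    preprocess_recording(
                        rec, ica, zscore and zscore_scope == "recording"
                    )
                )
            if recs and zscore and zscore_scope == "session":
                recs = preprocess.zscore_channels_session(recs)
            if recs:
                parts.append(
                    feat.build_dataset(recs, mode=mode, bands=bands,
                                       segmentation=segmentation,
                                       log_power=log_power)
                )
    if not parts:
        raise ValueError("no recordings generated (check tasks/weeks/missing)")
    fs = parts[0]
    combined = FeatureSet(
        X=np.vstack([p.X for p in parts]),
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
        mode=fs.mode,
        bands=fs.bands,
        channel_names=fs.channel_names,
        feature_channels=fs.feature_channels,
        feature_freqs=fs.feature_freqs,
        segmentation=fs.segmentation,
    )
    report["ground_truth"] = gt
    return combined, report
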