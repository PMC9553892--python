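"""Channel QC, ICA-based EOG artifact removal, per-channel standardization,
and the Berger/mu physiological sanity checks.

The preprocessing contract mirrors a conventional resting/motor EEG
pipeline: recordings are screened for channels that deviate wildly from the
instantaneous cross-channel distribution, all of a subject's sessions are
concatenated and decomposed with ICA so that blink-driven components (those
most correlated with the EOG channels) can be projected out, and each
channel is finally z-scored so that absolute amplitude carries no identity
information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import DEFAULT_REGIONS, EOG_CHANNELS, IMAGERY_TASKS, MOTOR_TASKS
from .recording import Recording


@dataclass
class QCReport:
    """Per-channel extreme-sample fractions and flags for one recording."""

    channel_names: tuple[str, ...]
    fractions: np.ndarray
    flagged: np.ndarray
    z_threshold: float
    fraction_threshold: float

    @property
    def any_flagged(self) -> bool:
        return bool(self.flagged.any())

    def to_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "fraction_threshold": self.fraction_threshold,
            "channels": {
                c: {"fraction": float(f), "flagged": bool(b)}
                for c, f, b in zip(self.channel_names, self.fractions, self.flagged)
            },
        }


def qc_bad_channels(
    recording: Recording, z: float = 5.0, frac: float = 0.15
) -> QCReport:
    """Flag scalp channels with too many excessively fluctuating samples.

    A sample is extreme for a channel when it deviates from the
    instantaneous cross-channel mean by more than ``z`` cross-channel
    standard deviations; a channel is flagged when its extreme fraction
    strictly exceeds ``frac`` (a fraction exactly at the threshold passes).
    """
    scalp = recording.scalp_names
    if len(scalp) < 2:
        raise ValueError("QC needs at least two scalp channels")
    x = recording.get_data(scalp)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(
            "cross-channel standard deviation is zero at some samples; "
            "extreme fractions are undefined"
        )
    extreme = np.abs(x - mu) > z * sd
    fractions = extreme.mean(axis=1)
    return QCReport(
        channel_names=scalp,
        fractions=fractions,
        flagged=fractions > frac,
        z_threshold=z,
        fraction_threshold=frac,
    )


@dataclass
class ICACleanConfig:
    """Settings for ICA-based EOG component removal."""

    correlation_z_threshold: float = 3.0
    eog_channel_names: tuple[str, ...] = EOG_CHANNELS
    n_components: int | None = None  # default: all scalp channels
    # the cohort's scalp sources are Gaussian except the blink component, so
    # FastICA finds the artifact direction early and never formally
    # converges on the rest; a tight iteration cap keeps the fit cheap
    max_iter: int = 100
    random_state: int = 97

    def __post_init__(self) -> None:
        if self.correlation_z_threshold <= 0:
            raise ValueError("correlation_z_threshold must be positive")


def fit_eog_ica(recordings: list[Recording], config: ICACleanConfig | None = None):
    """Fit an ICA on concatenated recordings and mark EOG components.

    Returns ``(ica, info)`` where ``ica`` (an :class:`mne.preprocessing.ICA`
    with ``exclude`` set, or None if the fit failed) can be applied to any
    recording with the same montage via :func:`apply_eog_ica`. Components
    are marked when their correlation with an EOG channel is an outlier
    under adaptive z-scoring across components (z above the configured
    threshold — the usual convention for automated EOG detection).
    """
    import mne

    config = config or ICACleanConfig()
    if not recordings:
        raise ValueError("no recordings to fit on")
    first = recordings[0]
    for rec in recordings:
        if rec.channel_names != first.channel_names:
            raise ValueError("recordings do not share a montage")
        if rec.subject_id != first.subject_id:
            raise ValueError("recordings belong to different subjects")
    missing = set(config.eog_channel_names) - set(first.channel_names)
    if missing:
        raise ValueError(f"EOG channels missing from montage: {sorted(missing)}")
    n_scalp = len(first.scalp_names)
    if sum(r.n_samples for r in recordings) < n_scalp:
        raise ValueError("fewer samples than scalp channels; ICA is underdetermined")

    fit_data = np.concatenate([r.data for r in recordings], axis=1)
    raw_fit = first.copy(data=fit_data).to_mne_raw()

    ica = mne.preprocessing.ICA(
        n_components=config.n_components or n_scalp,
        method="fastica",
        rng=config.random_state,
        max_iter=config.max_iter,
    )
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ica.fit(raw_fit, picks="eeg", verbose="error")
        converged = not any("did not converge" in str(w.message) for w in caught)
    except Exception as err:  # pragma: no cover - defensive fallback
        warnings.warn(f"ICA failed ({err}); recordings will pass through unchanged")
        return None, {"excluded": [], "scores": {}, "converged": False}

    scores: dict[str, list] = {}
    excluded: set[int] = set()
    for eog in config.eog_channel_names:
        if not np.isfinite(config.correlation_z_threshold):
            continue
        bads, sc = ica.find_bads_eog(
            raw_fit,
            ch_name=eog,
            measure="zscore",
            threshold=config.correlation_z_threshold,
            verbose="error",
        )
        scores[eog] = np.atleast_1d(sc).tolist()
        excluded.update(bads)
    ica.exclude = sorted(excluded)
    return ica, {"excluded": sorted(excluded), "scores": scores, "converged": converged}


def apply_eog_ica(ica, recording: Recording) -> Recording:
    """Reconstruct a recording from the ICA's non-excluded components.

    EOG channels pass through untouched. ``ica=None`` (failed fit) returns
    a copy.
    """
    if ica is None:
        return recording.copy()
    raw = ica.apply(recording.to_mne_raw(), verbose="error")
    return recording.copy(data=raw.get_data())


def remove_eog_components(
    recordings: list[Recording],
    config: ICACleanConfig | None = None,
    fit_on: list[int] | None = None,
) -> tuple[list[Recording], dict]:
    """Remove eye-movement components from one subject's recordings.

    All recordings (which must share subject and montage) are concatenated
    in time, an ICA is fitted on the scalp channels, EOG-correlated
    components are dropped, and the scalp signals are reconstructed per
    recording. ``fit_on`` optionally restricts the ICA *fit* to a subset of
    recording indices (the unmixing is still applied to all) — a large
    cohort does not need every sample to estimate a handful of blink
    components.
    """
    config = config or ICACleanConfig()
    if not recordings:
        return [], {"excluded": [], "scores": {}}
    fit_idx = list(range(len(recordings))) if fit_on is None else list(fit_on)
    ica, info = fit_eog_ica([recordings[i] for i in fit_idx], config)
    return [apply_eog_ica(ica, rec) for rec in recordings], info


def zscore_channels(recording: Recording) -> Recording:
    """Standardize every channel to zero mean, unit variance."""
    mu = recording.data.mean(axis=1, keepdims=True)
    sd = recording.data.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        names = [recording.channel_names[i] for i in flat]
        raise ValueError(f"zero-variance channel(s): {names}")
    return recording.copy(data=(recording.data - mu) / sd)


def zscore_channels_session(recordings: list[Recording]) -> list[Recording]:
    """Standardize channels with statistics pooled over several recordings
    (e.g. one session's tasks), preserving between-task amplitude ratios."""
    if not recordings:
        return []
    pooled = np.concatenate([r.data for r in recordings], axis=1)
    mu = pooled.mean(axis=1, keepdims=True)
    sd = pooled.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        names = [recordings[0].channel_names[i] for i in flat]
        raise ValueError(f"zero-variance channel(s): {names}")
    return [r.copy(data=(r.data - mu) / sd) for r in recordings]


# --------------------------------------------------------------------------
# physiological sanity checks on extracted features


def _paired_effect(per_subject: pd.DataFrame, col_a: str, col_b: str) -> dict:
    from scipy import stats

    diff = per_subject[col_a] - per_subject[col_b]
    if len(diff) >= 2 and np.ptp(diff.to_numpy()) > 0:
        t, p = stats.ttest_rel(per_subject[col_a], per_subject[col_b])
    else:
        t, p = np.nan, np.nan
    return {
        "mean_difference": float(diff.mean()),
        "fraction_positive": float((diff > 0).mean()),
        "t": float(t),
        "p": float(p),
    }


def sanity_berger(features, regions: dict | None = None) -> dict:
    """Berger-effect check: posterior alpha power, eyes closed vs open.

    ``features`` is a concatenated-mode FeatureSet containing 'rce' and
    'roe' rows. Returns per-subject mean posterior alpha for each task plus
    a paired summary; a positive rce - roe difference for (nearly) every
    subject is the expected physiological signature.
    """
    regions = regions or DEFAULT_REGIONS
    chans = [c for c in regions["occipital"] + regions["parietal"]
             if c in features.channel_names]
    table = _alpha_by_task(features, chans, ("rce", "roe"))
    return {
        "per_subject": table,
        "summary": _paired_effect(table, "rce", "roe"),
        "channels": chans,
    }


def sanity_mu(features, regions: dict | None = None,
              movement_tasks: tuple[str, ...] = MOTOR_TASKS + IMAGERY_TASKS) -> dict:
    """Mu-suppression check: central alpha power, movement vs rest.

    A negative movement - rest difference indicates the expected
    sensorimotor alpha drop during executed or imagined movement.
    """
    regions = regions or DEFAULT_REGIONS
    chans = [c for c in regions["central"] if c in features.channel_names]
    tasks = [t for t in features.meta["task"].unique() if t in movement_tasks]
    sub = features.band_channel_mean(chans, (8.0, 12.0))
    df = pd.DataFrame(
        {"subject": features.meta["subject"], "task": features.meta["task"], "alpha": sub}
    )
    rest = (
        df[df["task"] == "roe"].groupby("subject")["alpha"].mean().rename("rest")
    )
    move = (
        df[df["task"].isin(tasks)].groupby("subject")["alpha"].mean().rename("movement")
    )
    table = pd.concat([move, rest], axis=1).dropna()
    if table.empty:
        raise ValueError("need both 'roe' and movement-task rows")
    return {
        "per_subject": table,
        "summary": _paired_effect(table, "movement", "rest"),
        "channels": chans,
    }


def _alpha_by_task(features, chans, tasks) -> pd.DataFrame:
    vals = features.band_channel_mean(chans, (8.0, 12.0))
    df = pd.DataFrame(
        {"subject": features.meta["subject"], "task": features.meta["task"], "alpha": vals}
    )
    missing = [t for t in tasks if t not in set(df["task"])]
    if missing:
        raise ValueError(f"missing task(s) {missing} in feature set")
    out = (
        df[df["task"].isin(tasks)]
        .groupby(["subject", "task"])["alpha"]
        .mean()
        .unstack("task")
    )
    return out
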