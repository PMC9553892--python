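"""Twin-cohort EEG synthesis with planted person-specific spectral signatures.

The generator emulates a longitudinal monozygotic-twin study: ``n_pairs``
twin pairs, each subject recorded in weekly sessions of short task
conditions (rest with eyes closed/open, executed and imagined movement, and
a free task). Every subject carries a stationary "base" power spectrum that
is shared across tasks and weeks — the ground-truth person-identifying
signal — while tasks only re-gain narrow bands (occipital alpha boost with
eyes closed, central mu suppression during movement) and weeks add a slow
random-walk drift.

The signal model is spectrum-shaped Gaussian noise: each channel is the
inverse FFT of white noise whose amplitude follows a target power spectral
density, so the planted PSD is exactly controllable. Spectra are
parameterized as smooth Gaussian-process deviations (in log power, over
frequency) from a common 1/f-plus-alpha-peak shape:

    log S_subject(c, f) = log S0(f) + u_pair(f) + v_pair(c, f)
                          + d_shared * z_subj(f) + d_region(c) * z_subj(c, f)

Twin siblings share ``u_pair`` and ``v_pair`` and differ only in the two
``z`` terms, so within-pair spectral distance is controlled by the
divergence scales and is largest on frontal channels via the regional map.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .montage import (
    ALL_CHANNELS,
    BLINK_TOPOGRAPHY,
    EOG_CHANNELS,
    IMAGERY_TASKS,
    MOTOR_TASKS,
    TASKS,
    region_of,
)
from .recording import Recording

ALPHA_BAND = (8.0, 12.0)

#: Relative within-pair divergence per region; frontal largest, occipital
#: smallest, matching the developmental frontal-divergence hypothesis the
#: cohort is designed to probe. "other" covers unassigned channels (P7/P8).
DEFAULT_REGION_DIVERGENCE: dict[str, float] = {
    "frontal": 1.0,
    "central": 0.6,
    "parietal": 0.5,
    "temporal": 0.6,
    "occipital": 0.2,
    "other": 0.5,
}


def default_task_modulation() -> dict[str, list[tuple[tuple[str, ...], tuple[float, float], float]]]:
    """Task -> [(channels, (low, high) Hz, PSD gain)] narrow-band re-gains.

    Eyes-closed rest boosts posterior alpha (Berger effect); executed and
    imagined movement suppress central alpha (mu suppression), imagery less
    strongly than execution.
    """
    posterior = ("O1", "OZ", "O2", "P3", "PZ", "P4")
    central = ("FC3", "FCZ", "FC4", "C3", "CZ", "C4")
    mod: dict[str, list] = {"rce": [(posterior, ALPHA_BAND, 2.0)]}
    for t in MOTOR_TASKS:
        mod[t] = [(central, ALPHA_BAND, 0.6)]
    for t in IMAGERY_TASKS:
        mod[t] = [(central, ALPHA_BAND, 0.75)]
    return mod


@dataclass
class CohortConfig:
    """Study-design and signal-model parameters for one synthetic cohort.

    Defaults encode the emulated study: 10 twin pairs (20 subjects), 4
    weekly sessions, eleven 65-s task conditions at 500 Hz on a 30-channel
    scalp montage plus two EOG channels. Spectral parameters are natural-log
    power units on a 0.5 Hz frequency grid.
    """

    n_pairs: int = 10
    weeks: int = 4
    tasks: tuple[str, ...] = TASKS
    task_duration: float = 65.0
    free_task_duration: float = 65.0  # study free block is 5 min; desk default trims it
    sampling_rate: float = 500.0
    channels: tuple[str, ...] = ALL_CHANNELS
    # base spectrum and inter-individual structure (log-power units)
    base_spectrum_scale: float = 1.0
    pair_sd: float = 0.5
    pair_channel_sd: float = 0.3
    twin_divergence_shared: float = 0.04
    twin_divergence_scale: float = 0.07
    twin_divergence_by_region: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_DIVERGENCE)
    )
    freq_smoothness: float = 2.0  # GP length scale over frequency, Hz
    week_drift_sd: float = 0.1
    task_modulation: dict = field(default_factory=default_task_modulation)
    noise_white: float = 0.05
    noise_pink: float = 0.5
    blink_rate: float = 12.0  # events per minute
    blink_frontal_gain: float = 0.4
    missing: tuple[tuple[int, int, str], ...] = ()  # (subject, week, task) cells to skip
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        for name, val in [
            ("base_spectrum_scale", self.base_spectrum_scale),
            ("blink_rate", self.blink_rate),
            ("blink_frontal_gain", self.blink_frontal_gain),
            ("week_drift_sd", self.week_drift_sd),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.channels) - set(ALL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown montage channel names: {sorted(unknown)}")
        if min(self.task_duration, self.free_task_duration) < 2.0:
            raise ValueError("task duration shorter than one 2-s analysis window")
        top = max(
            (band[1] for mods in self.task_modulation.values() for _, band, _ in mods),
            default=0.0,
        )
        if self.sampling_rate <= 2 * top:
            raise ValueError("sampling_rate must exceed twice the highest band edge")
        for task, mods in self.task_modulation.items():
            for chans, _, gain in mods:
                if gain < 0:
                    raise ValueError(f"negative gain for task {task!r}")
                if not set(chans) <= set(self.channels):
                    raise ValueError(f"modulated channels for {task!r} not in montage")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_pairs

    @property
    def subjects(self) -> list[int]:
        return list(range(1, self.n_subjects + 1))

    def pair_of(self, subject: int) -> int:
        return (subject + 1) // 2

    def duration_of(self, task: str) -> float:
        return self.free_task_duration if task == "fre" else self.task_duration

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c not in EOG_CHANNELS)

    @property
    def eog_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c in EOG_CHANNELS)


@dataclass
class GroundTruth:
    """Planted spectral truth of a cohort, on the 0.5 Hz analysis grid.

    ``base_profiles[s]`` is the linear-power base PSD of subject ``s``
    (scalp channels x frequencies); ``pair_templates[p]`` the shared pair
    spectrum; ``drift[s][w-1]`` the log-power drift offset of week ``w``
    (zero in week 1).
    """

    freqs: np.ndarray
    scalp_channels: tuple[str, ...]
    base_profiles: dict[int, np.ndarray]
    pair_templates: dict[int, np.ndarray]
    drift: dict[int, np.ndarray]


# --------------------------------------------------------------------------
# spectral building blocks


def mean_log_spectrum(freqs: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Population-mean log PSD: 1/f background + 10 Hz alpha peak + floor."""
    s = scale * (
        20.0 / (1.0 + freqs) ** 1.5
        + 1.5 * np.exp(-0.5 * ((freqs - 10.0) / 2.0) ** 2)
        + 0.02
    )
    return np.log(s)


def eog_spectrum(freqs: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Linear PSD of the EOG channels (low-frequency dominated)."""
    return scale * (40.0 / (1.0 + freqs) ** 1.5 + 0.05)


@functools.lru_cache(maxsize=8)
def _gp_cholesky(n: int, df: float, length_scale: float) -> np.ndarray:
    f = np.arange(n) * df
    k = np.exp(-0.5 * ((f[:, None] - f[None, :]) / length_scale) ** 2)
    k[np.diag_indices_from(k)] += 1e-8
    return np.linalg.cholesky(k)


def _smooth_deviation(rng: np.random.Generator, n: int, df: float, ls: float,
                      size: int = 1) -> np.ndarray:
    """Draw `size` unit-variance GP samples over the frequency grid."""
    chol = _gp_cholesky(n, df, ls)
    return (chol @ rng.standard_normal((n, size))).T


def synthesize_channel(
    target_psd: np.ndarray,
    n_samples: int,
    sampling_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise whose one-sided PSD equals ``target_psd``.

    ``target_psd`` must be sampled on the half-spectrum grid
    ``rfftfreq(n_samples, 1/sampling_rate)`` in power-per-Hz units; the
    segment-averaged periodogram of the output converges to it. The DC bin
    is ignored (the output is zero-mean).
    """
    target_psd = np.asarray(target_psd, dtype=float)
    nf = n_samples // 2 + 1
    if target_psd.shape != (nf,):
        raise ValueError(f"target_psd must have {nf} bins for n_samples={n_samples}")
    if np.any(target_psd < 0) or not np.all(np.isfinite(target_psd)):
        raise ValueError("target_psd must be finite and non-negative")
    # E|X_k|^2 = S_k * fs * n / 2 on interior bins gives a density-scaled
    # one-sided periodogram with expectation S_k.
    amp = np.sqrt(target_psd * sampling_rate * n_samples / 4.0)
    spec = amp * (rng.standard_normal(nf) + 1j * rng.standard_normal(nf))
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = np.sqrt(target_psd[-1] * sampling_rate * n_samples / 2.0) * \
            rng.standard_normal()
    return np.fft.irfft(spec, n=n_samples)


# --------------------------------------------------------------------------
# ground truth and recordings


def analysis_freqs(sampling_rate: float, resolution: float = 0.5) -> np.ndarray:
    return np.arange(0.0, sampling_rate / 2 + resolution / 2, resolution)


def _rng_for(config: CohortConfig, *key: int) -> np.random.Generator:
    """Independent, order-invariant random stream for one generation step."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(key))
    )


def make_ground_truth(config: CohortConfig) -> GroundTruth:
    """Draw the cohort's base spectra, pair templates and weekly drifts."""
    freqs = analysis_freqs(config.sampling_rate)
    nf = freqs.size
    df = float(freqs[1] - freqs[0])
    ls = config.freq_smoothness
    scalp = config.scalp_channels
    n_scalp = len(scalp)
    m = mean_log_spectrum(freqs, config.base_spectrum_scale)

    region_scale = np.array(
        [
            config.twin_divergence_scale
            * config.twin_divergence_by_region.get(
                region_of(c) or "other", config.twin_divergence_by_region.get("other", 0.5)
            )
            for c in scalp
        ]
    )

    templates: dict[int, np.ndarray] = {}
    profiles: dict[int, np.ndarray] = {}
    drifts: dict[int, np.ndarray] = {}
    for pair in range(1, config.n_pairs + 1):
        rng = _rng_for(config, 0, pair)
        u = config.pair_sd * _smooth_deviation(rng, nf, df, ls)[0]
        v = config.pair_channel_sd * _smooth_deviation(rng, nf, df, ls, size=n_scalp)
        log_template = m[None, :] + u[None, :] + v
        templates[pair] = np.exp(log_template)
        for subject in (2 * pair - 1, 2 * pair):
            srng = _rng_for(config, 1, subject)
            z_shared = config.twin_divergence_shared * _smooth_deviation(srng, nf, df, ls)[0]
            z_chan = _smooth_deviation(srng, nf, df, ls, size=n_scalp)
            log_profile = log_template + z_shared[None, :] + region_scale[:, None] * z_chan
            profiles[subject] = np.exp(log_profile)
            # random-walk drift over weeks, shared across channels and tasks
            steps = config.week_drift_sd * _smooth_deviation(
                srng, nf, df, ls, size=max(config.weeks - 1, 1)
            )
            walk = np.zeros((config.weeks, nf))
            if config.weeks > 1:
                walk[1:] = np.cumsum(steps[: config.weeks - 1], axis=0)
            drifts[subject] = walk
    return GroundTruth(
        freqs=freqs,
        scalp_channels=scalp,
        base_profiles=profiles,
        pair_templates=templates,
        drift=drifts,
    )


def _target_psds(
    config: CohortConfig, gt: GroundTruth, subject: int, week: int, task: str,
    out_freqs: np.ndarray,
) -> np.ndarray:
    """Per-channel linear target PSD on ``out_freqs`` for one recording."""
    scalp = config.scalp_channels
    log_prof = np.log(gt.base_profiles[subject]) + gt.drift[subject][week - 1][None, :]
    lin = np.exp(log_prof)
    for chans, (lo, hi), gain in config.task_modulation.get(task, []):
        idx = [i for i, c in enumerate(scalp) if c in chans]
        band = (gt.freqs >= lo) & (gt.freqs < hi)
        lin[np.ix_(idx, band)] *= gain
    noise = config.noise_white + config.noise_pink / (1.0 + gt.freqs)
    lin = lin + noise[None, :]
    eog = eog_spectrum(gt.freqs)

    psds = np.empty((len(config.channels), out_freqs.size))
    scalp_pos = {c: i for i, c in enumerate(scalp)}
    for row, ch in enumerate(config.channels):
        src = eog if ch in EOG_CHANNELS else lin[scalp_pos[ch]]
        psds[row] = np.interp(out_freqs, gt.freqs, src)
    return psds


def generate_recording(
    config: CohortConfig, gt: GroundTruth, subject: int, week: int, task: str
) -> Recording:
    """Synthesize one subject x week x task recording (blinks included)."""
    if task not in config.tasks:
        raise ValueError(f"unknown task {task!r}")
    fs = config.sampling_rate
    n = int(round(config.duration_of(task) * fs))
    out_freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psds = _target_psds(config, gt, subject, week, task, out_freqs)
    rng = _rng_for(config, 2, subject, week, config.tasks.index(task))
    data = np.empty((len(config.channels), n))
    for row in range(len(config.channels)):
        data[row] = synthesize_channel(psds[row], n, fs, rng)
    rec = Recording(
        subject_id=subject,
        pair_id=config.pair_of(subject),
        week=week,
        task=task,
        channel_names=config.channels,
        sampling_rate=fs,
        data=data,
    )
    if config.blink_rate > 0 and config.eog_channels:
        rec = inject_blinks(rec, config.blink_rate, config.blink_frontal_gain, rng)
    return rec


def iter_cohort(config: CohortConfig) -> Iterator[Recording]:
    """Stream the cohort one recording at a time (constant memory).

    Ordering is subject-major, then week, then the config's task order.
    Output is bit-reproducible for a given seed and independent of how many
    recordings are consumed.
    """
    gt = make_ground_truth(config)
    for subject in config.subjects:
        for week in range(1, config.weeks + 1):
            for task in config.tasks:
                if (subject, week, task) in config.missing:
                    continue
                yield generate_recording(config, gt, subject, week, task)


def generate_cohort(config: CohortConfig) -> tuple[list[Recording], GroundTruth]:
    """Materialize the whole cohort in memory.

    Intended for reduced configs; a full default cohort held in memory is
    several GB — use :func:`iter_cohort` or the pipeline helpers instead.
    """
    gt = make_ground_truth(config)
    return list(iter_cohort(config)), gt


# --------------------------------------------------------------------------
# artifacts


def blink_pulse(sampling_rate: float, width: float = 0.06, half_span: float = 0.25) -> np.ndarray:
    """Smooth Gaussian blink waveform (unit peak amplitude)."""
    t = np.arange(-half_span, half_span + 1.0 / sampling_rate / 2, 1.0 / sampling_rate)
    return np.exp(-0.5 * (t / width) ** 2)


def inject_blinks(
    recording: Recording,
    rate: float,
    frontal_gain: float,
    rng: np.random.Generator,
    amplitude: float = 60.0,
) -> Recording:
    """Add eye-blink pulses to the EOG channels and, attenuated, to the
    front of the scalp.

    ``rate`` is events per minute (Poisson); each blink is a smooth pulse
    at full ``amplitude`` on VEO (0.3x on HEO) and at
    ``frontal_gain * topography`` on scalp channels, where the topography
    decays from the forehead to zero over posterior channels.
    """
    if not recording.eog_names:
        raise ValueError("recording has no EOG channels")
    if rate == 0:
        return recording.copy()
    n = recording.n_samples
    fs = recording.sampling_rate
    n_events = rng.poisson(rate * (n / fs) / 60.0)
    pulse = blink_pulse(fs) * amplitude
    half = pulse.size // 2
    train = np.zeros(n)
    if n_events > 0:
        times = rng.integers(half, n - half, size=n_events)
        for t0 in times:
            train[t0 - half: t0 - half + pulse.size] += pulse
    gains = np.zeros(recording.n_channels)
    for i, ch in enumerate(recording.channel_names):
        if ch == "VEO":
            gains[i] = 1.0
        elif ch == "HEO":
            gains[i] = 0.3
        else:
            gains[i] = frontal_gain * BLINK_TOPOGRAPHY.get(ch, 0.0)
    out = recording.copy()
    out.data = out.data + gains[:, None] * train[None, :]
    return out
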