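"""Spectral band-power feature extraction.

Recordings are cut into 2-s segments (1000 samples at 500 Hz, 50%
overlap by default), each segment's per-channel PSD is estimated with a
Hann-tapered periodogram on a 0.5 Hz grid, and the theta (4-8 Hz), alpha
(8-12 Hz) and beta (12-29 Hz) bins are kept as features. In concatenated
mode the 30 scalp channels' band bins are joined into one 1530-dimensional
vector per segment; in channel-wise mode every channel contributes its own
51-dimensional vector (and segmentation defaults to 0% overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal

from .recording import Recording

LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands; half-open [low, high) except the final band,
    which keeps its upper edge."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("beta", 12.0, 29.0),
    )

    def __post_init__(self) -> None:
        prev_high = -np.inf
        prev_low = -np.inf
        for name, lo, hi in self.bands:
            if hi <= lo:
                raise ValueError(f"band {name!r} has high <= low")
            if lo < prev_high or lo <= prev_low:
                raise ValueError("bands must be ascending and non-overlapping")
            prev_low, prev_high = lo, hi

    @property
    def highest_edge(self) -> float:
        return self.bands[-1][2]

    def bin_mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of retained frequency bins."""
        mask = np.zeros(freqs.shape, dtype=bool)
        for i, (_, lo, hi) in enumerate(self.bands):
            if i == len(self.bands) - 1:
                mask |= (freqs >= lo) & (freqs <= hi)
            else:
                mask |= (freqs >= lo) & (freqs < hi)
        return mask

    def restrict(self, low: float, high: float) -> "BandScheme":
        """Clip the scheme to [low, high] (e.g. a 4-20 Hz control range)."""
        kept = []
        for name, lo, hi in self.bands:
            lo2, hi2 = max(lo, low), min(hi, high)
            if hi2 > lo2:
                kept.append((name, lo2, hi2))
        if not kept:
            raise ValueError("band restriction leaves no bins")
        return BandScheme(tuple(kept))


@dataclass(frozen=True)
class SegmentationScheme:
    """Sliding-window segmentation in samples."""

    window_samples: int = 1000
    step_samples: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.step_samples <= self.window_samples:
            raise ValueError("need 0 < step <= window")

    def n_segments(self, n_samples: int) -> int:
        if n_samples < self.window_samples:
            return 0
        return (n_samples - self.window_samples) // self.step_samples + 1


def segment_signal(recording: Recording, scheme: SegmentationScheme) -> np.ndarray:
    """Cut a recording into (n_segments, n_channels, window) windows; a
    trailing partial window is dropped."""
    n = recording.n_samples
    if n < scheme.window_samples:
        raise ValueError(
            f"recording of {n} samples is shorter than one "
            f"{scheme.window_samples}-sample window"
        )
    n_seg = scheme.n_segments(n)
    idx = np.arange(scheme.window_samples)[None, :] + \
        scheme.step_samples * np.arange(n_seg)[:, None]
    return recording.data[:, idx].transpose(1, 0, 2)


def compute_psd(segment: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered periodogram of one segment (channels x window).

    Returns (freqs, psd) with psd in power-per-Hz units on the
    ``sampling_rate / window`` grid (0.5 Hz for the default 2-s window).
    A stacked (segments x channels x window) array is transformed along its
    last axis in one call.
    """
    segment = np.atleast_2d(segment)
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite values")
    freqs, psd = signal.periodogram(
        segment, fs=sampling_rate, window="hann", scaling="density", axis=-1
    )
    return freqs, psd


def extract_band_features(
    psd: np.ndarray,
    freqs: np.ndarray,
    bands: BandScheme | None = None,
    log_transform: bool = True,
) -> np.ndarray:
    """Concatenate the in-band PSD bins (channel-major, band-minor).

    ``psd`` may be (n_freqs,) or (channels, n_freqs); the result is 1-D.
    """
    bands = bands or BandScheme()
    if bands.highest_edge > freqs[-1]:
        raise ValueError("band edges exceed the frequency grid")
    mask = bands.bin_mask(freqs)
    vals = np.atleast_2d(psd)[:, mask]
    if log_transform:
        vals = np.log10(np.maximum(vals, LOG_FLOOR))
    return vals.ravel()


@dataclass
class FeatureSet:
    """Per-segment spectral feature matrix with row metadata.

    ``meta`` has one row per feature vector with columns subject, pair,
    week, task, block, segment (and channel in channel-wise mode).
    ``feature_channels`` / ``feature_freqs`` describe each column, enabling
    regional column subsetting and weight-vector reshaping.
    """

    X: np.ndarray
    meta: pd.DataFrame
    mode: str  # "concatenated" | "channelwise"
    bands: BandScheme
    channel_names: tuple[str, ...]
    feature_channels: np.ndarray | None
    feature_freqs: np.ndarray
    segmentation: SegmentationScheme

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.meta):
            raise ValueError("feature matrix and metadata row counts differ")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def subjects(self) -> list[int]:
        return sorted(self.meta["subject"].unique())

    GROUP_COLS = ("subject", "week", "task", "block")

    @property
    def group_cols(self) -> tuple[str, ...]:
        cols = self.GROUP_COLS
        if "channel" in self.meta.columns:
            cols = cols + ("channel",)
        return cols

    def subset(self, subjects=None, weeks=None, tasks=None, mask=None) -> "FeatureSet":
        keep = np.ones(self.n_samples, dtype=bool)
        if subjects is not None:
            keep &= self.meta["subject"].isin(list(subjects)).to_numpy()
        if weeks is not None:
            keep &= self.meta["week"].isin(list(weeks)).to_numpy()
        if tasks is not None:
            keep &= self.meta["task"].isin(list(tasks)).to_numpy()
        if mask is not None:
            keep &= np.asarray(mask)
        return replace(
            self, X=self.X[keep], meta=self.meta.loc[keep].reset_index(drop=True)
        )

    def select_channels(self, channels: Iterable[str]) -> "FeatureSet":
        """Restrict concatenated-mode columns to the given channels."""
        channels = list(channels)
        if not channels:
            raise ValueError("empty channel subset")
        unknown = set(channels) - set(self.channel_names)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if self.mode != "concatenated":
            raise ValueError("column subsetting applies to concatenated mode only")
        col = np.isin(self.feature_channels, channels)
        return replace(
            self,
            X=self.X[:, col],
            channel_names=tuple(c for c in self.channel_names if c in channels),
            feature_channels=self.feature_channels[col],
            feature_freqs=self.feature_freqs[col],
        )

    def save(self, path) -> None:
        """Serialize to a single ``.npz`` archive."""
        meta_cols = {f"meta_{c}": self.meta[c].to_numpy() for c in self.meta.columns}
        np.savez_compressed(
            path,
            X=self.X,
            mode=np.array(self.mode),
            bands=np.array([(n, lo, hi) for n, lo, hi in self.bands.bands], dtype=object),
            channel_names=np.array(self.channel_names),
            feature_channels=np.array([]) if self.feature_channels is None
            else self.feature_channels,
            feature_freqs=self.feature_freqs,
            segmentation=np.array([self.segmentation.window_samples,
                                   self.segmentation.step_samples]),
            **meta_cols,
        )

    @classmethod
    def load(cls, path) -> "FeatureSet":
        with np.load(path, allow_pickle=True) as z:
            meta = pd.DataFrame(
                {k[5:]: z[k] for k in z.files if k.startswith("meta_")}
            )
            bands = BandScheme(
                tuple((str(n), float(lo), float(hi)) for n, lo, hi in z["bands"])
            )
            fc = z["feature_channels"]
            win, step = (int(v) for v in z["segmentation"])
            return cls(
                X=z["X"],
                meta=meta,
                mode=str(z["mode"]),
                bands=bands,
                channel_names=tuple(str(c) for c in z["channel_names"]),
                feature_channels=None if fc.size == 0 else fc.astype(str),
                feature_freqs=z["feature_freqs"],
                segmentation=SegmentationScheme(win, step),
            )

    def band_channel_mean(self, channels: Iterable[str], band: tuple[float, float]) -> np.ndarray:
        """Per-row mean feature over the given channels and [low, high) band."""
        lo, hi = band
        freq_ok = (self.feature_freqs >= lo) & (self.feature_freqs < hi)
        if self.mode == "concatenated":
            col = freq_ok & np.isin(self.feature_channels, list(channels))
            if not col.any():
                raise ValueError("no feature columns match the requested channels/band")
            return self.X[:, col].mean(axis=1)
        col = freq_ok
        vals = self.X[:, col].mean(axis=1)
        in_ch = self.meta["channel"].isin(list(channels)).to_numpy()
        out = np.full(self.n_samples, np.nan)
        out[in_ch] = vals[in_ch]
        return out


def default_segmentation(mode: str) -> SegmentationScheme:
    if mode == "channelwise":
        return SegmentationScheme(1000, 1000)  # 0% overlap
    return SegmentationScheme(1000, 500)


def build_dataset(
    recordings: Iterable[Recording],
    mode: str = "concatenated",
    bands: BandScheme | None = None,
    segmentation: SegmentationScheme | None = None,
    channel_subset: Iterable[str] | None = None,
    log_power: bool = True,
) -> FeatureSet:
    """Extract a FeatureSet from (an iterable of) recordings.

    Only scalp channels enter the feature space; ``channel_subset``
    restricts them further (e.g. to one scalp region). Rows are tagged with
    full (subject, pair, week, task, block, segment) metadata.
    """
    if mode not in ("concatenated", "channelwise"):
        raise ValueError("mode must be 'concatenated' or 'channelwise'")
    bands = bands or BandScheme()
    segmentation = segmentation or default_segmentation(mode)

    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    channels: tuple[str, ...] | None = None
    freqs = None
    for rec in recordings:
        scalp = rec.scalp_names
        if channel_subset is not None:
            subset = list(channel_subset)
            unknown = set(subset) - set(scalp)
            if unknown:
                raise ValueError(f"unknown channels in subset: {sorted(unknown)}")
            scalp = tuple(c for c in scalp if c in subset)
        if channels is None:
            channels = scalp
        elif channels != scalp:
            raise ValueError("recordings do not share a channel layout")
        segs = segment_signal(rec.copy(data=rec.get_data(scalp),
                                       channel_names=scalp), segmentation)
        # one periodogram call over all segments at once
        freqs, psd = compute_psd(segs, rec.sampling_rate)
        if bands.highest_edge > freqs[-1]:
            raise ValueError("band edges exceed the frequency grid")
        mask = bands.bin_mask(freqs)
        vals = psd[..., mask]
        if log_power:
            vals = np.log10(np.maximum(vals, LOG_FLOOR))
        n_seg, n_ch, n_bins = vals.shape
        base = {
            "subject": rec.subject_id,
            "pair": rec.pair_id,
            "week": rec.week,
            "task": rec.task,
            "block": rec.block,
        }
        if mode == "concatenated":
            blocks.append(vals.reshape(n_seg, n_ch * n_bins).astype(np.float32))
            meta_rows.append(pd.DataFrame({**base, "segment": np.arange(n_seg)}))
        else:
            blocks.append(vals.reshape(n_seg * n_ch, n_bins).astype(np.float32))
            meta_rows.append(
                pd.DataFrame(
                    {
                        **base,
                        "segment": np.repeat(np.arange(n_seg), n_ch),
                        "channel": np.tile(np.array(channels), n_seg),
                    }
                )
            )
    if channels is None or not blocks:
        raise ValueError("no recordings provided")
    mask = bands.bin_mask(freqs)
    band_freqs = freqs[mask]
    if mode == "concatenated":
        feature_channels = np.repeat(np.array(channels), band_freqs.size)
        feature_freqs = np.tile(band_freqs, len(channels))
    else:
        feature_channels = None
        feature_freqs = band_freqs
    return FeatureSet(
        X=np.vstack(blocks),
        meta=pd.concat(meta_rows, ignore_index=True),
        mode=mode,
        bands=bands,
        channel_names=channels,
        feature_channels=feature_channels,
        feature_freqs=feature_freqs,
        segmentation=segmentation,
    )
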