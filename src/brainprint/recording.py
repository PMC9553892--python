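"""The in-memory container for one subject x week x task EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import EOG_CHANNELS


@dataclass
class Recording:
    """Multichannel EEG time series with identity and session labels.

    ``data`` is channels x samples in arbitrary microvolt-like units
    (downstream z-scoring removes scale). Two consecutive ``subject_id``
    values form one twin pair.
    """

    subject_id: int
    pair_id: int
    week: int
    task: str
    channel_names: tuple[str, ...]
    sampling_rate: float
    data: np.ndarray
    block: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names were given"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def eog_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_names if c in EOG_CHANNELS)

    @property
    def scalp_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_names if c not in EOG_CHANNELS)

    def channel_index(self, names) -> np.ndarray:
        """Row indices of the given channel names, in the given order."""
        lookup = {c: i for i, c in enumerate(self.channel_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in recording") from None

    def get_data(self, names) -> np.ndarray:
        return self.data[self.channel_index(names)]

    def copy(self, **changes) -> "Recording":
        new = replace(self, **changes)
        if "data" not in changes:
            new.data = self.data.copy()
        return new

    def to_mne_raw(self):
        """Convert to an :class:`mne.io.RawArray` (scalp -> eeg, EOG -> eog)."""
        import mne

        ch_types = ["eog" if c in EOG_CHANNELS else "eeg" for c in self.channel_names]
        info = mne.create_info(
            list(self.channel_names), sfreq=self.sampling_rate, ch_types=ch_types
        )
        return mne.io.RawArray(self.data.astype(np.float64), info, verbose="error")


def recording_key(rec: Recording) -> tuple:
    """Unique (subject, week, task, block) identity of a recording."""
    return (rec.subject_id, rec.week, rec.task, rec.block)
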