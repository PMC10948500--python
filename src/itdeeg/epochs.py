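"""Labelled EEG epoch container: trials x channels x samples plus metadata.

An :class:`EpochSet` is the universal pipeline input. The study geometry it
emulates is 19-channel, 1000 Hz, 1-second action epochs with six balanced
classes (five finger-movement imageries plus a no-mental-task class), but
the container itself is shape-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochSet"]


def _default_channel_names(n: int) -> list[str]:
    return [f"ch{i + 1:02d}" for i in range(n)]


@dataclass
class EpochSet:
    """Epoched multichannel recording with integer class labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Epoch waveforms. Must be finite.
    labels : ndarray of int, shape (n_trials,)
        Class label per trial (1-based).
    fs : float
        Sampling rate in Hz.
    subject_ids : ndarray, optional
        Subject identifier per trial; defaults to a single subject 1.
    channel_names : list of str, optional
        Channel labels; defaults to ``ch01..chNN``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    subject_ids: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite samples")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match {self.data.shape[0]} trials"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.subject_ids is None:
            self.subject_ids = np.ones(self.n_trials, dtype=np.int64)
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
            if self.subject_ids.shape != (self.n_trials,):
                raise ValueError("subject_ids length must match trial count")
        if not self.channel_names:
            self.channel_names = _default_channel_names(self.n_channels)
        elif len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def for_subject(self, subject_id: int) -> "EpochSet":
        """Sub-view restricted to one subject's trials."""
        mask = self.subject_ids == subject_id
        if not mask.any():
            raise KeyError(f"no trials for subject {subject_id}")
        return EpochSet(
            data=self.data[mask],
            labels=self.labels[mask],
            fs=self.fs,
            subject_ids=self.subject_ids[mask],
            channel_names=list(self.channel_names),
        )

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        return EpochSet(
            data=self.data[index],
            labels=self.labels[index],
            fs=self.fs,
            subject_ids=self.subject_ids[index],
            channel_names=list(self.channel_names),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EpochSet(n_trials={self.n_trials}, n_channels={self.n_channels}, "
            f"n_samples={self.n_samples}, fs={self.fs}, "
            f"classes={self.classes.tolist()}, subjects={self.subjects.tolist()})"
        )
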