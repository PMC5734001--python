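"""Epoched multichannel EEG container and sliding-window segmentation.

The :class:`EpochSet` is the universal input of the package: a block of
labelled trials (trials x channels x samples) with its sampling rate and the
cue time that separates the preparation period from the imagery task.
Segmentation cuts every trial into overlapping windows; a segment is stamped
by the time at which its window *ends*, which is the earliest moment a causal
system could have observed it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

LEFT = "L"
RIGHT = "R"
CLASS_LABELS = (LEFT, RIGHT)


def _as_label_array(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    return arr


@dataclass
class EpochSet:
    """Labelled, epoched two-class EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal block; all trials share channel order and sample count.
    sampling_rate : float
        Sampling rate in Hz.
    cue_time : float
        Cue onset in seconds relative to trial start (the preparation
        period is ``[0, cue_time)``).
    labels : sequence of {"L", "R"} or None
        Per-trial class labels; ``None`` for unlabelled data.
    channel_names : tuple of str
        Ordered channel labels, e.g. ``("C3", "C4")``.
    """

    data: np.ndarray
    sampling_rate: float
    cue_time: float
    labels: np.ndarray | None = None
    channel_names: tuple[str, ...] = ("C3", "C4")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        self.channel_names = tuple(str(c) for c in self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.cue_time < self.duration:
            raise ValueError(
                f"cue_time {self.cue_time} must lie inside the trial (0, {self.duration})"
            )
        if self.labels is not None:
            self.labels = _as_label_array(self.labels)
            if len(self.labels) != self.n_trials:
                raise ValueError("labels length does not match trial count")
            bad = set(self.labels) - set(CLASS_LABELS)
            if bad:
                raise ValueError(f"unknown class labels {sorted(bad)}; expected {CLASS_LABELS}")

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
    def duration(self) -> float:
        return self.data.shape[2] / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def subset(self, indices) -> "EpochSet":
        """Return a new EpochSet restricted to the given trial indices."""
        indices = np.asarray(indices)
        labels = None if self.labels is None else self.labels[indices]
        return replace(self, data=self.data[indices], labels=labels)

    def class_indices(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("EpochSet has no labels")
        return np.flatnonzero(self.labels == label)


@dataclass(frozen=True)
class SegmentationScheme:
    """Sliding-window segmentation: window length and step in seconds.

    Segments tile the trial from its start; a window must lie fully inside
    the trial. Timestamps follow the window-end convention.
    """

    window_length: float = 1.0
    step: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_length:
            raise ValueError("require 0 < step <= window_length")

    def window_samples(self, sampling_rate: float) -> int:
        w = self.window_length * sampling_rate
        w_int = int(round(w))
        if abs(w - w_int) > 1e-9 * max(1.0, w) or w_int < 2:
            raise ValueError(
                f"window_length x sampling_rate must be an integer >= 2; got {w}"
            )
        return w_int

    def step_samples(self, sampling_rate: float) -> int:
        s = self.step * sampling_rate
        s_int = int(round(s))
        if abs(s - s_int) > 1e-9 * max(1.0, s) or s_int < 1:
            raise ValueError(f"step x sampling_rate must be an integer >= 1; got {s}")
        return s_int

    def segment_starts(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        w = self.window_samples(sampling_rate)
        s = self.step_samples(sampling_rate)
        if w > n_samples:
            raise ValueError(
                f"window of {w} samples does not fit in a trial of {n_samples} samples"
            )
        n_seg = (n_samples - w) // s + 1
        return np.arange(n_seg) * s


class Segments(NamedTuple):
    """Segmented view of an EpochSet."""

    data: np.ndarray  # (n_trials, n_segments, n_channels, window_samples)
    timestamps: np.ndarray  # window-end times, seconds
    start_times: np.ndarray  # window-start times, seconds


def segment_trials(epochs: EpochSet, scheme: SegmentationScheme) -> Segments:
    """Cut every trial into overlapping windows.

    Returns segment data of shape (trials, segments, channels, window samples)
    together with window start/end times. Start indices are
    ``0, step, 2*step, ...`` while ``start + window <= n_samples``.
    """
    fs = epochs.sampling_rate
    w = scheme.window_samples(fs)
    starts = scheme.segment_starts(epochs.n_samples, fs)
    s = scheme.step_samples(fs)
    view = np.lib.stride_tricks.sliding_window_view(epochs.data, w, axis=2)
    view = view[:, :, ::s, :][:, :, : len(starts), :]
    data = np.ascontiguousarray(np.swapaxes(view, 1, 2))
    start_times = starts / fs
    timestamps = (starts + w) / fs
    return Segments(data=data, timestamps=timestamps, start_times=start_times)
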