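"""Power projective base extraction.

A projective base is a unit-norm temporal filter ``u`` (one window long)
chosen so that the ratio of the two classes' mean projected power

    F(u) = (u' R_L u) / (u' R_R u)

is extremal, where ``R_k`` is the average outer product of class ``k``'s
windowed signal vectors. Simultaneously diagonalising the pair
``(R_L, R_R)`` gives a matrix ``T`` with ``T' R_L T = diag(lambda)`` and
``T' R_R T = I``; ``F`` then ranges over ``[lambda_min, lambda_max]`` and the
extremal filters are the first and last columns of ``T``. Whether the
maximising or the minimising branch is more discriminative depends on which
of ``lambda_1`` and ``1/lambda_M`` is larger. The squared projection of a
window onto the chosen base is its projective power; the C3 and C4 powers
are stacked into the 2-dimensional feature vector used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import scipy.linalg

from .epochs import CLASS_LABELS, EpochSet, SegmentationScheme, segment_trials

DEFAULT_RIDGE_SCALE = 1e-6


@dataclass
class ProjectiveBasis:
    """A fitted per-channel projective base with its eigenvalue context."""

    u: np.ndarray
    lambda_max: float
    lambda_min: float
    branch: str  # "max" or "min"
    channel: str = ""

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 1:
            raise ValueError("basis vector must be 1-D")
        if self.branch not in ("max", "min"):
            raise ValueError(f"branch must be 'max' or 'min', got {self.branch!r}")
        nrm = np.linalg.norm(self.u)
        if not np.isclose(nrm, 1.0, atol=1e-10):
            raise ValueError(f"basis vector must be unit norm; got {nrm}")


@dataclass
class FeatureSeries:
    """Per-trial sequences of 2-D projective-power vectors.

    ``values`` has shape (n_trials, n_segments, n_features); entries are
    squared projections, hence nonnegative, in signal-units squared.
    ``timestamps`` are window-end times in seconds.
    """

    values: np.ndarray
    timestamps: np.ndarray
    labels: np.ndarray | None = None
    channels: tuple[str, ...] = ("C3", "C4")
    window_length: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (trials, segments, features)")
        if self.values.shape[1] != len(self.timestamps):
            raise ValueError("timestamps length must match segment count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]

    def restrict(self, min_timestamp: float) -> "FeatureSeries":
        """Keep only segments whose window-end time is >= ``min_timestamp``."""
        mask = self.timestamps >= min_timestamp - 1e-9
        return replace(self, values=self.values[:, mask, :], timestamps=self.timestamps[mask])

    def subset(self, indices) -> "FeatureSeries":
        indices = np.asarray(indices)
        labels = None if self.labels is None else self.labels[indices]
        return replace(self, values=self.values[indices], labels=labels)


def projective_power(u: np.ndarray, x: np.ndarray) -> float:
    """Squared projection ``(u . x)**2`` of a window onto a base."""
    u = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    if u.shape != x.shape:
        raise ValueError(f"length mismatch: basis {u.shape} vs window {x.shape}")
    return float(np.dot(u, x) ** 2)


def autocorrelation(segments: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Average outer product of window vectors, plus ``ridge * I``.

    ``segments`` is (n_vectors, window_samples); the result is symmetric
    positive semidefinite by construction (before the ridge).
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    if segments.size == 0:
        raise ValueError("autocorrelation needs at least one segment")
    if not np.all(np.isfinite(segments)):
        raise ValueError("segments contain non-finite samples")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    n, m = segments.shape
    r = segments.T @ segments / n
    r = (r + r.T) / 2.0
    if ridge:
        r = r + ridge * np.eye(m)
    return r


def simultaneous_diagonalization(
    r_l: np.ndarray, r_r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Congruence transform ``T`` with ``T' R_L T = diag(lambda)``, ``T' R_R T = I``.

    Solved as a generalized symmetric-definite eigenproblem (Cholesky
    whitening of ``R_R`` internally via LAPACK). Eigenvalues are returned in
    descending order with the columns of ``T`` aligned.
    """
    r_l = np.asarray(r_l, dtype=float)
    r_r = np.asarray(r_r, dtype=float)
    if r_l.shape != r_r.shape or r_l.ndim != 2 or r_l.shape[0] != r_l.shape[1]:
        raise ValueError("R_L and R_R must be square matrices of equal size")
    try:
        lambdas, t = scipy.linalg.eigh(r_l, r_r)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise np.linalg.LinAlgError(
            "generalized eigendecomposition failed; the class autocorrelation "
            "matrix is singular - increase the ridge regularization"
        ) from exc
    order = np.argsort(lambdas)[::-1]
    return t[:, order], lambdas[order]


def _fix_sign(u: np.ndarray) -> np.ndarray:
    # reproducibility across eigensolvers: first non-negligible component positive
    tol = 1e-12 * np.max(np.abs(u))
    for v in u:
        if abs(v) > tol:
            return u if v > 0 else -u
    return u


def select_basis(t: np.ndarray, lambdas: np.ndarray, channel: str = "") -> ProjectiveBasis:
    """Pick the maximising or minimising extremal column of ``T``.

    The max branch is taken when ``lambda_1 >= 1/lambda_M`` (ties go to max),
    the min branch otherwise. The returned filter is rescaled to unit norm,
    which leaves the power ratio unchanged.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    lam_max, lam_min = float(lambdas[0]), float(lambdas[-1])
    if lam_min <= 0:
        raise ValueError(
            f"smallest generalized eigenvalue {lam_min} is not positive; "
            "the class autocorrelation is not positive definite on its span"
        )
    if lam_max >= 1.0 / lam_min:
        u, branch = t[:, 0], "max"
    else:
        u, branch = t[:, -1], "min"
    u = _fix_sign(u / np.linalg.norm(u))
    return ProjectiveBasis(u=u, lambda_max=lam_max, lambda_min=lam_min, branch=branch, channel=channel)


def power_ratio(u: np.ndarray, r_l: np.ndarray, r_r: np.ndarray) -> float:
    """The objective ``F(u) = (u' R_L u) / (u' R_R u)``; scale-invariant in u."""
    u = np.asarray(u, dtype=float)
    return float(u @ r_l @ u) / float(u @ r_r @ u)


def _training_segment_matrix(
    epochs: EpochSet,
    scheme: SegmentationScheme,
    channel: str,
    label: str,
    train_window: str,
) -> np.ndarray:
    seg = segment_trials(epochs, scheme)
    ch = epochs.channel_index(channel)
    idx = epochs.class_indices(label)
    if len(idx) == 0:
        raise ValueError(f"no trials of class {label!r} available for fitting")
    if train_window == "post_cue":
        mask = seg.start_times >= epochs.cue_time - 1e-9
        if not mask.any():
            raise ValueError("no segment lies fully after the cue; shorten the window")
    elif train_window == "all":
        mask = np.ones(len(seg.start_times), dtype=bool)
    else:
        raise ValueError("train_window must be 'post_cue' or 'all'")
    block = seg.data[idx][:, mask, ch, :]  # (trials, segments, window)
    return block.reshape(-1, block.shape[-1])


def fit_bases(
    epochs: EpochSet,
    scheme: SegmentationScheme | None = None,
    channels: tuple[str, str] = ("C3", "C4"),
    ridge: float | None = None,
    train_window: str = "post_cue",
) -> dict[str, ProjectiveBasis]:
    """Fit one projective base per channel from labelled training epochs.

    For each channel independently: build the two class autocorrelation
    matrices from the training segments (post-cue windows by default, the
    discriminative task period), ridge-regularize, simultaneously
    diagonalize, and select the extremal branch. The per-class average runs
    over all of that class's training segments.

    ``ridge=None`` uses the default ``1e-6 * trace(R_R) / M`` added to both
    matrices' diagonals.
    """
    if epochs.labels is None:
        raise ValueError("fitting requires labelled epochs")
    scheme = scheme or SegmentationScheme()
    bases: dict[str, ProjectiveBasis] = {}
    for channel in channels:
        mats = {}
        for label in CLASS_LABELS:
            x = _training_segment_matrix(epochs, scheme, channel, label, train_window)
            mats[label] = autocorrelation(x)
        m = mats["R"].shape[0]
        rv = ridge if ridge is not None else DEFAULT_RIDGE_SCALE * np.trace(mats["R"]) / m
        r_l = mats["L"] + rv * np.eye(m)
        r_r = mats["R"] + rv * np.eye(m)
        t, lambdas = simultaneous_diagonalization(r_l, r_r)
        bases[channel] = select_basis(t, lambdas, channel=channel)
    return bases


def extract_features(
    epochs: EpochSet,
    scheme: SegmentationScheme,
    bases: Mapping[str, ProjectiveBasis],
) -> FeatureSeries:
    """Project every segment of every trial onto the per-channel bases.

    Returns the stacked projective powers ``z_i = [e_ch1, e_ch2, ...]`` per
    segment, with window-end timestamps carried through.
    """
    seg = segment_trials(epochs, scheme)
    w = scheme.window_samples(epochs.sampling_rate)
    cols = []
    channels = tuple(bases.keys())
    for channel in channels:
        basis = bases[channel]
        if len(basis.u) != w:
            raise ValueError(
                f"basis for {channel!r} has length {len(basis.u)}; window has {w} samples"
            )
        ch = epochs.channel_index(channel)
        proj = seg.data[:, :, ch, :] @ basis.u  # (trials, segments)
        cols.append(proj**2)
    values = np.stack(cols, axis=-1)
    return FeatureSeries(
        values=values,
        timestamps=seg.timestamps,
        labels=epochs.labels,
        channels=channels,
        window_length=scheme.window_length,
    )
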