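"""Per-segment-index Gaussian class models and the segment log probability ratio.

Features at segment index ``i`` are modelled as class-conditional Gaussians
``g_ki = N(m_ki, S_ki)`` fitted independently per index (the rhythm is
nonstationary across the trial, so means and covariances are allowed to
drift with ``i``). The per-segment log probability ratio is

    J_i = 1/2 [ log(|S_Ri| / |S_Li|) + D2(z_i, m_Ri) - D2(z_i, m_Li) ]

with ``D2`` the Mahalanobis distance under each class's own covariance;
positive ``J_i`` favours class L. Its class-conditional expectations have
the closed forms

    E[J_i | L] =  1/2 [ log(|S_R|/|S_L|) + tr((S_L + dd') S_R^-1 - I) ]
    E[J_i | R] =  1/2 [ log(|S_R|/|S_L|) - tr((S_R + dd') S_L^-1 - I) ]

with ``d = m_L - m_R``; these equal the Gaussian Kullback-Leibler
divergences KL(g_L || g_R) and -KL(g_R || g_L), hence E[J|L] >= 0 >= E[J|R]
for any pair of distinct classes. Covariances are shrunk toward a scaled
identity, ``(1-gamma) S + gamma (tr S / 2) I``, to keep them invertible at
small per-index sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import CLASS_LABELS
from .features import FeatureSeries

_LOG_EPS_SCALE = 1e-12


@dataclass
class SegmentGaussianModel:
    """Per-(segment index, class) Gaussian parameters.

    ``means`` has shape (2, Q, d) and ``covs`` (2, Q, d, d) with class axis
    ordered (L, R). ``transform`` is "raw" or "log"; for "log" the features
    are mapped ``log(z + eps)`` before fitting and scoring, with ``eps``
    frozen at fit time.
    """

    means: np.ndarray
    covs: np.ndarray
    shrinkage: float = 0.0
    transform: str = "raw"
    eps: float = 0.0
    n_train: tuple[int, int] = (0, 0)
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        if self.means.ndim != 3 or self.means.shape[0] != 2:
            raise ValueError("means must have shape (2, Q, d)")
        if self.covs.shape != self.means.shape + (self.means.shape[-1],):
            raise ValueError("covs must have shape (2, Q, d, d)")
        if self.transform not in ("raw", "log"):
            raise ValueError("transform must be 'raw' or 'log'")
        eig = np.linalg.eigvalsh(self.covs)
        if np.any(eig <= 0):
            raise ValueError(
                "a class covariance is singular; increase the shrinkage"
            )
        self._inv = np.linalg.inv(self.covs)
        sign, logdet = np.linalg.slogdet(self.covs)
        if np.any(sign <= 0):
            raise ValueError("covariance determinant not positive")
        self._logdet = logdet

    @property
    def n_segments(self) -> int:
        return self.means.shape[1]

    @property
    def n_features(self) -> int:
        return self.means.shape[2]

    def apply_transform(self, values: np.ndarray) -> np.ndarray:
        if self.transform == "log":
            return np.log(values + self.eps)
        return values

    def params(self, label: str, index: int):
        """(mean, covariance) for class ``label`` at 0-based segment ``index``."""
        k = CLASS_LABELS.index(label)
        return self.means[k, index], self.covs[k, index]

    def log_pr(self, z: np.ndarray, index: int) -> float:
        """Segment log probability ratio J_i for one (already raw) feature vector."""
        z = np.asarray(z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("feature vector contains non-finite values")
        zt = self.apply_transform(z)
        dl = zt - self.means[0, index]
        dr = zt - self.means[1, index]
        d2l = dl @ self._inv[0, index] @ dl
        d2r = dr @ self._inv[1, index] @ dr
        return 0.5 * (self._logdet[1, index] - self._logdet[0, index] + d2r - d2l)

    def log_pr_matrix(self, values: np.ndarray) -> np.ndarray:
        """Vectorized J for a block of trials: (n, Q, d) -> (n, Q)."""
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("features contain non-finite values")
        zt = self.apply_transform(values)
        dl = zt - self.means[0][None]  # (n, Q, d)
        dr = zt - self.means[1][None]
        d2l = np.einsum("nqd,qde,nqe->nq", dl, self._inv[0], dl)
        d2r = np.einsum("nqd,qde,nqe->nq", dr, self._inv[1], dr)
        return 0.5 * (self._logdet[1] - self._logdet[0] + d2r - d2l)

    def expected_log_pr(self, index: int) -> tuple[float, float]:
        """Closed-form (E[J_i | L], E[J_i | R]) at 0-based segment ``index``."""
        m_l, s_l = self.means[0, index], self.covs[0, index]
        m_r, s_r = self.means[1, index], self.covs[1, index]
        d = m_l - m_r
        eye = np.eye(self.n_features)
        logdets = self._logdet[1, index] - self._logdet[0, index]
        ej_l = 0.5 * (
            logdets + np.trace((s_l + np.outer(d, d)) @ self._inv[1, index] - eye)
        )
        ej_r = 0.5 * (
            logdets - np.trace((s_r + np.outer(d, d)) @ self._inv[0, index] - eye)
        )
        return float(ej_l), float(ej_r)

    def expected_sequences(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-index expectation sequences (E[J_i|L], E[J_i|R]), i = 1..Q."""
        pairs = [self.expected_log_pr(i) for i in range(self.n_segments)]
        arr = np.asarray(pairs)
        return arr[:, 0], arr[:, 1]

    def swapped(self) -> "SegmentGaussianModel":
        """Model with the two class roles exchanged (for symmetry checks)."""
        return SegmentGaussianModel(
            means=self.means[::-1].copy(),
            covs=self.covs[::-1].copy(),
            shrinkage=self.shrinkage,
            transform=self.transform,
            eps=self.eps,
            n_train=self.n_train[::-1],
            timestamps=self.timestamps,
        )


def mahalanobis_sq(z: np.ndarray, m: np.ndarray, s: np.ndarray) -> float:
    """Squared Mahalanobis distance ``(z-m)' S^-1 (z-m)``."""
    z = np.asarray(z, dtype=float)
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    d = z - m
    try:
        sol = np.linalg.solve(s, d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("covariance matrix is singular") from exc
    return float(d @ sol)


def _shrink(s: np.ndarray, gamma: float) -> np.ndarray:
    d = s.shape[0]
    return (1 - gamma) * s + gamma * (np.trace(s) / d) * np.eye(d)


def fit_models(
    features: FeatureSeries,
    shrinkage: float = 0.05,
    transform: str = "raw",
) -> SegmentGaussianModel:
    """Fit per-index class Gaussians from labelled features.

    Means are per-class sample means at each segment index; covariances are
    unbiased (n-1) sample covariances shrunk toward ``(tr S / d) I`` with
    weight ``shrinkage``. Requires at least two trials per class.
    """
    if features.labels is None:
        raise ValueError("fitting requires labelled features")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must lie in [0, 1]")
    if transform not in ("raw", "log"):
        raise ValueError("transform must be 'raw' or 'log'")
    values = features.values
    eps = 0.0
    if transform == "log":
        eps = _LOG_EPS_SCALE * float(values.mean())
        values = np.log(values + eps)
    q, d = values.shape[1], values.shape[2]
    means = np.empty((2, q, d))
    covs = np.empty((2, q, d, d))
    counts = []
    for k, label in enumerate(CLASS_LABELS):
        idx = np.flatnonzero(features.labels == label)
        if len(idx) < 2:
            raise ValueError(
                f"class {label!r} has {len(idx)} trial(s); need >= 2 to fit covariances"
            )
        counts.append(len(idx))
        block = values[idx]  # (n_k, Q, d)
        mu = block.mean(axis=0)
        centered = block - mu[None]
        cov = np.einsum("nqd,nqe->qde", centered, centered) / (len(idx) - 1)
        for i in range(q):
            tr = np.trace(cov[i])
            if tr <= 0:
                raise ValueError(
                    f"zero-variance features for class {label!r} at segment {i}; "
                    "the Gaussian model is degenerate"
                )
            cov[i] = _shrink(cov[i], shrinkage)
        means[k], covs[k] = mu, cov
    try:
        return SegmentGaussianModel(
            means=means,
            covs=covs,
            shrinkage=shrinkage,
            transform=transform,
            eps=eps,
            n_train=tuple(counts),
            timestamps=features.timestamps.copy(),
        )
    except ValueError as exc:
        raise ValueError(f"{exc}; refit with shrinkage > 0") from exc


def log_pr_segment(z: np.ndarray, model: SegmentGaussianModel, index: int) -> float:
    """Thin wrapper: J_i for one feature vector at 0-based segment ``index``."""
    return model.log_pr(z, index)


def expected_log_pr(model: SegmentGaussianModel, index: int) -> tuple[float, float]:
    """Thin wrapper: closed-form (E[J_i|L], E[J_i|R]) at 0-based ``index``."""
    return model.expected_log_pr(index)
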