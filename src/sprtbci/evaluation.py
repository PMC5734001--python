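"""Performance metrics and the cross-validated evaluation protocol.

Accuracy, the two-class Wolpaw mutual information
``MI(p) = 1 + p log2 p + (1-p) log2 (1-p)`` bits, its steepness
``SMI(t) = MI(t) / (t - origin)`` (an information rate over the time elapsed
since the end of the preparation period), paired t statistics, per-time
classification curves, and a leakage-free stratified ten-fold
cross-validation that refits the entire pipeline inside every training
split.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .epochs import CLASS_LABELS, EpochSet
from .features import FeatureSeries
from .model import SegmentGaussianModel
from .sprt import _stratified_assignments


def accuracy(decisions, truth) -> float:
    """Fraction of decisions matching the true labels; ties count as errors."""
    decisions = np.asarray(decisions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if decisions.shape != truth.shape:
        raise ValueError("decisions and truth must have equal length")
    if decisions.size == 0:
        raise ValueError("cannot compute accuracy of an empty decision set")
    return float(np.mean(decisions == truth))


def wolpaw_mi(p: float) -> float:
    """Two-class Wolpaw information transfer at accuracy ``p``, in bits.

    Symmetric about 0.5, zero at chance, one bit at p = 0 or 1.
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1]; got {p}")
    if p in (0.0, 1.0):
        return 1.0
    return 1.0 + p * np.log2(p) + (1 - p) * np.log2(1 - p)


def smi(mi: float, t: float, origin: float = 3.0, min_elapsed: float = 0.5) -> float:
    """Steepness of MI: ``mi / (t - origin)`` bits/s, defined for ``t > origin + min_elapsed``.

    ``origin`` is the end of the preparation period; times at or before
    ``origin + min_elapsed`` are outside the measure's domain.
    """
    if t <= origin + min_elapsed:
        raise ValueError(
            f"SMI is undefined for t <= {origin + min_elapsed} s (got t = {t})"
        )
    return float(mi) / (t - origin)


@dataclass
class TimeCourses:
    """Per-time accuracy / MI / SMI of the sign-of-evidence classifier."""

    timestamps: np.ndarray
    accuracy: np.ndarray
    mi: np.ndarray
    smi: np.ndarray  # nan outside the SMI domain


def time_courses(
    features: FeatureSeries,
    model: SegmentGaussianModel,
    truth,
    origin: float = 3.0,
    min_elapsed: float = 0.5,
) -> TimeCourses:
    """Classify by the sign of the accumulated evidence at every segment time.

    An exactly zero statistic carries no information and is scored as half
    credit (the expectation of a fair tie-break).
    """
    truth = np.asarray(truth, dtype=object)
    traces = np.cumsum(model.log_pr_matrix(features.values), axis=1)
    decided_l = traces > 0
    truth_is_l = (truth == "L")[:, None]
    correct = np.where(decided_l == truth_is_l, 1.0, 0.0)
    correct[traces == 0] = 0.5
    acc = correct.mean(axis=0)
    mi = np.array([wolpaw_mi(a) for a in acc])
    t = features.timestamps
    smi_vals = np.full_like(mi, np.nan)
    ok = t > origin + min_elapsed
    smi_vals[ok] = mi[ok] / (t[ok] - origin)
    return TimeCourses(timestamps=t.copy(), accuracy=acc, mi=mi, smi=smi_vals)


def paired_t(a, b) -> tuple[float, int]:
    """Paired t statistic and degrees of freedom for matched samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: the paired t statistic is undefined")
    t = d.mean() / (sd / np.sqrt(len(d)))
    return float(t), len(d) - 1


@dataclass
class EvaluationReport:
    """Cross-validated pipeline metrics (fold averages plus per-fold rows)."""

    accuracy: float
    mi_bits: float
    smi: float
    mean_decision_time: float
    forced_fraction: float
    per_fold: list[dict] = field(default_factory=list)
    n_folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "mi_bits": self.mi_bits,
            "smi": self.smi,
            "mean_decision_time": self.mean_decision_time,
            "forced_fraction": self.forced_fraction,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "per_fold": self.per_fold,
        }


def _model_fingerprint(clf) -> str:
    h = hashlib.sha256()
    for channel in sorted(clf.bases_):
        h.update(clf.bases_[channel].u.tobytes())
    h.update(clf.model_.means.tobytes())
    h.update(clf.model_.covs.tobytes())
    return h.hexdigest()


def tenfold_cv(
    epochs: EpochSet,
    n_folds: int = 10,
    seed: int = 0,
    estimator=None,
    test_transform=None,
    **estimator_params,
) -> EvaluationReport:
    """Stratified k-fold evaluation of the full pipeline.

    Folds are assigned per class by round-robin after a seeded shuffle. The
    entire pipeline (basis fit, model fit, thresholds) is refit on each
    training split; no information flows from the held-out trials.
    ``test_transform``, if given, is applied to the held-out data block
    before prediction (a diagnostics hook, e.g. for leakage probes).
    Reported metrics are averages over folds; MI is the Wolpaw transform of
    the fold-averaged accuracy.
    """
    from sklearn.base import clone

    from .estimators import SPRTClassifier

    if epochs.labels is None:
        raise ValueError("cross-validation requires labelled epochs")
    for label in CLASS_LABELS:
        if len(epochs.class_indices(label)) < n_folds:
            raise ValueError(
                f"class {label!r} has fewer trials than folds ({n_folds})"
            )
    if estimator is None:
        estimator = SPRTClassifier(
            sampling_rate=epochs.sampling_rate,
            cue_time=epochs.cue_time,
            channel_names=epochs.channel_names,
            random_state=seed,
            **estimator_params,
        )
    folds = _stratified_assignments(epochs.labels, n_folds, seed)
    per_fold = []
    correct = total = forced_n = 0
    time_sum = 0.0
    for f in range(n_folds):
        train = epochs.subset(np.flatnonzero(folds != f))
        test = epochs.subset(np.flatnonzero(folds == f))
        clf = clone(estimator).fit(train, train.labels)
        test_data = test.data if test_transform is None else test_transform(test.data)
        test_eval = EpochSet(
            data=test_data,
            sampling_rate=test.sampling_rate,
            cue_time=test.cue_time,
            labels=test.labels,
            channel_names=test.channel_names,
        )
        paths = clf.decision_paths(test_eval)
        decisions = np.array([p.decision for p in paths], dtype=object)
        stop_times = np.array([p.stop_time for p in paths]) - epochs.cue_time
        fold_acc = accuracy(decisions, test.labels)
        fold_forced = float(np.mean([p.forced for p in paths]))
        per_fold.append(
            {
                "fold": f,
                "n_test": test.n_trials,
                "accuracy": fold_acc,
                "mi_bits": wolpaw_mi(fold_acc),
                "mean_decision_time": float(stop_times.mean()),
                "forced_fraction": fold_forced,
                "fingerprint": _model_fingerprint(clf),
            }
        )
        correct += int(fold_acc * test.n_trials + 0.5)
        total += test.n_trials
        forced_n += int(fold_forced * test.n_trials + 0.5)
        time_sum += stop_times.sum()
    acc = correct / total
    mi = wolpaw_mi(acc)
    mean_t = time_sum / total
    # SMI on the trial-relative mean stopping time, when inside its domain
    abs_t = mean_t + epochs.cue_time
    smi_val = (
        smi(mi, abs_t, origin=epochs.cue_time) if abs_t > epochs.cue_time + 0.5 else float("nan")
    )
    return EvaluationReport(
        accuracy=acc,
        mi_bits=mi,
        smi=smi_val,
        mean_decision_time=mean_t,
        forced_fraction=forced_n / total,
        per_fold=per_fold,
        n_folds=n_folds,
        seed=seed,
    )
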