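"""Truncated sequential probability ratio test with stopping-time thresholds.

The accumulated evidence after ``q`` segments is ``L_q = sum_{i<=q} J_i``.
The classical test decides L when ``L_q >= xi_L``, R when ``L_q <= xi_R``
and otherwise takes another segment; on the ratio scale the thresholds obey
Wald's inequalities ``p(L|R) <= 1/eta_L`` and ``p(R|L) <= eta_R``. Here the
two log thresholds are instead *derived from a target expected stopping
time*: the expected number of segments to a correct decision is forced to a
common value ``q_E`` for both classes, which fixes

    xi_L = sum_{i=1}^{q_E} E[J_i | L],    xi_R = sum_{i=1}^{q_E} E[J_i | R].

The test is truncated at ``q_E``: an undecided trial is resolved by the sign
of ``L_{q_E}`` (an exact zero falls to the tie policy). The stopping-time
grid can be swept under internal cross-validation to optimize accuracy,
mutual information, its steepness, or mean decision time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.special
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .epochs import CLASS_LABELS, LEFT, RIGHT
from .features import FeatureSeries
from .model import SegmentGaussianModel, fit_models


@dataclass(frozen=True)
class WaldThresholds:
    """Ratio-scale decision thresholds (upper eta_L, lower eta_R)."""

    eta_L: float
    eta_R: float

    def __post_init__(self) -> None:
        if self.eta_L <= 0 or self.eta_R <= 0:
            raise ValueError("thresholds must be positive")
        if not self.eta_R < self.eta_L:
            raise ValueError("require eta_R < eta_L")


@dataclass(frozen=True)
class StoppingThresholds:
    """Log-scale thresholds tied to an expected stopping segment count."""

    xi_L: float
    xi_R: float
    q_E: int

    def __post_init__(self) -> None:
        if self.q_E < 1:
            raise ValueError("q_E must be >= 1")


@dataclass
class DecisionPath:
    """One trial's evidence trace and decision."""

    trace: np.ndarray  # cumulative L_q up to the stopping segment
    decision: str  # "L", "R" or "tie"
    stop_segment: int  # 1-based segment index at decision
    stop_time: float  # window-end time of the stopping segment (s); nan if unknown
    forced: bool  # True when the truncation rule at q_E fired


def wald_error_bounds(eta_L: float, eta_R: float) -> tuple[float, float]:
    """Wald's inequalities: bounds on (p(L|R), p(R|L)) from the thresholds."""
    if eta_L <= 0 or eta_R <= 0:
        raise ValueError("thresholds must be positive")
    return min(1.0, 1.0 / eta_L), min(1.0, eta_R)


def expected_stopping_time(
    ej_l: np.ndarray, ej_r: np.ndarray, eta_L: float, eta_R: float
) -> tuple[float, float]:
    """Expected segment counts to a correct decision, per class.

    Smallest ``n`` such that the partial sum of the per-index expectations
    crosses the threshold-dependent bound:

        E(q|L): sum_{i<=n} E[J_i|L] >= (1 - eta_R) log eta_L + eta_R log eta_R
        E(q|R): sum_{i<=n} E[J_i|R] <= (1 - 1/eta_L) log eta_R + (1/eta_L) log eta_L

    Returns ``inf`` with a warning for a class whose sum never crosses
    within the available indices.
    """
    if eta_L <= 0 or eta_R <= 0:
        raise ValueError("thresholds must be positive")
    ej_l = np.asarray(ej_l, dtype=float)
    ej_r = np.asarray(ej_r, dtype=float)
    bound_l = (1 - eta_R) * np.log(eta_L) + eta_R * np.log(eta_R)
    bound_r = (1 - 1 / eta_L) * np.log(eta_R) + (1 / eta_L) * np.log(eta_L)
    cum_l = np.cumsum(ej_l)
    cum_r = np.cumsum(ej_r)
    hit_l = np.flatnonzero(cum_l >= bound_l)
    hit_r = np.flatnonzero(cum_r <= bound_r)
    q_l = float(hit_l[0] + 1) if len(hit_l) else np.inf
    q_r = float(hit_r[0] + 1) if len(hit_r) else np.inf
    if not np.isfinite(q_l) or not np.isfinite(q_r):
        warnings.warn(
            "expected evidence never crosses the stopping bound within the "
            "available segments; returning inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return q_l, q_r


def thresholds_from_stopping_time(
    ej_l: np.ndarray, ej_r: np.ndarray, q_e: int
) -> StoppingThresholds:
    """Partial-sum thresholds for a target expected stopping segment count."""
    ej_l = np.asarray(ej_l, dtype=float)
    ej_r = np.asarray(ej_r, dtype=float)
    if not 1 <= q_e <= len(ej_l):
        raise ValueError(f"q_E must lie in [1, {len(ej_l)}]; got {q_e}")
    return StoppingThresholds(
        xi_L=float(np.sum(ej_l[:q_e])),
        xi_R=float(np.sum(ej_r[:q_e])),
        q_E=int(q_e),
    )


def run_sprt_batch(
    j: np.ndarray,
    xi_l: float,
    xi_r: float,
    q_e: int | None = None,
    tie_policy: str = "random",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized truncated SPRT over a block of per-trial J sequences.

    ``j`` is (n_trials, Q). Returns (decisions, stop 1-based indices,
    forced flags, traces (n_trials, q_E)).
    """
    j = np.atleast_2d(np.asarray(j, dtype=float))
    q_e = j.shape[1] if q_e is None else int(q_e)
    if q_e < 1 or q_e > j.shape[1]:
        raise ValueError(f"trials provide {j.shape[1]} segments; q_E={q_e} is out of range")
    if tie_policy not in ("random", "undecided"):
        raise ValueError("tie_policy must be 'random' or 'undecided'")
    traces = np.cumsum(j[:, :q_e], axis=1)
    hit_l = traces >= xi_l
    hit_r = traces <= xi_r
    hit = hit_l | hit_r
    crossed = hit.any(axis=1)
    first = np.argmax(hit, axis=1)
    stop = np.where(crossed, first, q_e - 1)
    rows = np.arange(j.shape[0])
    at_stop = traces[rows, stop]
    decisions = np.empty(j.shape[0], dtype=object)
    forced = ~crossed
    # unforced: which boundary was hit (both at once only if xi_L <= xi_R;
    # then the sign of the trace arbitrates)
    both = crossed & hit_l[rows, stop] & hit_r[rows, stop]
    decisions[crossed & hit_l[rows, stop] & ~both] = LEFT
    decisions[crossed & hit_r[rows, stop] & ~both] = RIGHT
    undecided_sign = forced | both
    decisions[undecided_sign & (at_stop > 0)] = LEFT
    decisions[undecided_sign & (at_stop < 0)] = RIGHT
    zero = undecided_sign & (at_stop == 0)
    if zero.any():
        if tie_policy == "random":
            rng = rng or np.random.default_rng()
            decisions[zero] = rng.choice([LEFT, RIGHT], size=int(zero.sum()))
        else:
            decisions[zero] = "tie"
    return decisions, stop + 1, forced, traces


def run_sprt(
    j: np.ndarray,
    thresholds: StoppingThresholds,
    timestamps: np.ndarray | None = None,
    tie_policy: str = "random",
    rng: np.random.Generator | None = None,
) -> DecisionPath:
    """Truncated SPRT for one trial's J sequence (Q >= q_E values)."""
    j = np.asarray(j, dtype=float)
    if j.ndim != 1:
        raise ValueError("run_sprt expects a single trial's J sequence")
    decisions, stop, forced, traces = run_sprt_batch(
        j[None, :], thresholds.xi_L, thresholds.xi_R, thresholds.q_E, tie_policy, rng
    )
    q = int(stop[0])
    t = float(timestamps[q - 1]) if timestamps is not None else float("nan")
    return DecisionPath(
        trace=traces[0, :q].copy(),
        decision=str(decisions[0]),
        stop_segment=q,
        stop_time=t,
        forced=bool(forced[0]),
    )


@dataclass
class StoppingTimeSweep:
    """Criterion curve and optimum from a stopping-time grid sweep."""

    q_opt: int
    thresholds: StoppingThresholds
    criterion: str
    q_grid: np.ndarray
    accuracy: np.ndarray
    mi: np.ndarray
    smi: np.ndarray
    mean_decision_time: np.ndarray


def _stratified_assignments(labels: np.ndarray, n_splits: int, seed: int) -> np.ndarray:
    """Fold id per trial: per-class round-robin after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for label in CLASS_LABELS:
        idx = np.flatnonzero(labels == label)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_splits
    return folds


def optimize_stopping_time(
    features: FeatureSeries,
    q_grid,
    criterion: str = "accuracy",
    *,
    shrinkage: float = 0.05,
    transform: str = "raw",
    n_splits: int = 5,
    seed: int = 0,
    tie_policy: str = "random",
    accuracy_floor: float = 0.7,
    time_origin: float = 0.0,
    smi_origin: float | None = None,
) -> StoppingTimeSweep:
    """Select the stopping time by internal cross-validation on training data.

    For each fold, class models and thresholds are refit on the in-fold
    training trials and every grid value of ``q_E`` is scored on the held-out
    trials; decisions are pooled over folds. ``criterion`` is one of
    ``accuracy``, ``mi``, ``smi`` (maximized; ties go to the smallest
    ``q_E``) or ``mean_decision_time`` (minimized subject to the accuracy
    floor). ``smi`` uses MI divided by elapsed time past ``smi_origin``
    (default: ``time_origin``). Final thresholds are refit on all trials.
    """
    from .evaluation import wolpaw_mi

    q_grid = np.asarray(sorted(set(int(q) for q in np.atleast_1d(q_grid))))
    if len(q_grid) == 0:
        raise ValueError("q_grid is empty")
    if criterion not in ("accuracy", "mi", "smi", "mean_decision_time"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if features.labels is None:
        raise ValueError("stopping-time optimization requires labelled features")
    smi_origin = time_origin if smi_origin is None else smi_origin
    folds = _stratified_assignments(features.labels, n_splits, seed)
    rng = np.random.default_rng(seed + 1)
    n_q = len(q_grid)
    correct = np.zeros(n_q)
    total = np.zeros(n_q)
    stop_time_sum = np.zeros(n_q)
    for f in range(n_splits):
        train = features.subset(np.flatnonzero(folds != f))
        test = features.subset(np.flatnonzero(folds == f))
        if test.n_trials == 0:
            continue
        model = fit_models(train, shrinkage=shrinkage, transform=transform)
        ej_l, ej_r = model.expected_sequences()
        j = model.log_pr_matrix(test.values)
        for qi, q_e in enumerate(q_grid):
            thr = thresholds_from_stopping_time(ej_l, ej_r, q_e)
            dec, stop, _, _ = run_sprt_batch(
                j, thr.xi_L, thr.xi_R, thr.q_E, tie_policy, rng
            )
            correct[qi] += np.sum(dec == test.labels)
            total[qi] += test.n_trials
            stop_time_sum[qi] += np.sum(features.timestamps[stop - 1] - time_origin)
    acc = correct / total
    mean_t = stop_time_sum / total
    mi = np.array([wolpaw_mi(a) for a in acc])
    with np.errstate(divide="ignore", invalid="ignore"):
        elapsed = mean_t + time_origin - smi_origin
        smi = np.where(elapsed > 0, mi / elapsed, np.nan)
    if criterion == "accuracy":
        score = acc
    elif criterion == "mi":
        score = mi
    elif criterion == "smi":
        score = np.nan_to_num(smi, nan=-np.inf)
    if criterion == "mean_decision_time":
        ok = acc >= accuracy_floor
        if ok.any():
            cand = np.flatnonzero(ok)
            q_opt = int(q_grid[cand[np.argmin(mean_t[cand])]])
        else:
            warnings.warn(
                "no grid point reaches the accuracy floor; falling back to the "
                "accuracy optimum",
                RuntimeWarning,
                stacklevel=2,
            )
            q_opt = int(q_grid[int(np.argmax(acc))])
    else:
        q_opt = int(q_grid[int(np.argmax(score))])  # argmax takes the first = smallest q
    full_model = fit_models(features, shrinkage=shrinkage, transform=transform)
    ej_l, ej_r = full_model.expected_sequences()
    thresholds = thresholds_from_stopping_time(ej_l, ej_r, q_opt)
    return StoppingTimeSweep(
        q_opt=q_opt,
        thresholds=thresholds,
        criterion=criterion,
        q_grid=q_grid,
        accuracy=acc,
        mi=mi,
        smi=smi,
        mean_decision_time=mean_t,
    )


@dataclass
class SequentialBayesResult:
    """Posterior-odds traces and fixed-time decisions of the SB baseline."""

    odds: np.ndarray  # (n_trials, Q) cumulative log posterior odds for L vs R
    decision_index: int  # 1-based segment index at which decisions are read
    decisions: np.ndarray


def sequential_bayes(
    features: FeatureSeries,
    model: SegmentGaussianModel,
    priors: tuple[float, float] = (0.5, 0.5),
    decision_index: int | None = None,
) -> SequentialBayesResult:
    """Sequential Bayesian baseline: accumulate posterior odds, decide at a fixed time.

    The cumulative log posterior odds after ``q`` segments equal
    ``log(P(L)/P(R)) + L_q`` under the same Gaussian models. When
    ``decision_index`` is not given it is chosen on the (labelled) features
    as the segment with the highest mean posterior probability of the true
    class - the point of peak decision confidence. With flat priors the
    odds trace is exactly the SPRT evidence trace.
    """
    p_l, p_r = priors
    if p_l < 0 or p_r < 0 or p_l + p_r <= 0:
        raise ValueError("priors must be nonnegative and sum to a positive value")
    if p_l == 0 or p_r == 0:
        # degenerate prior: the posterior never leaves the certain class
        n, q = features.values.shape[:2]
        label = LEFT if p_r == 0 else RIGHT
        odds = np.full((n, q), np.inf if p_r == 0 else -np.inf)
        idx = decision_index or q
        return SequentialBayesResult(
            odds=odds, decision_index=idx, decisions=np.full(n, label, dtype=object)
        )
    j = model.log_pr_matrix(features.values)
    odds = np.log(p_l / p_r) + np.cumsum(j, axis=1)
    if decision_index is None:
        if features.labels is None:
            raise ValueError(
                "decision_index must be given for unlabelled features"
            )
        post_l = scipy.special.expit(odds)
        truth_is_l = (features.labels == LEFT)[:, None]
        p_true = np.where(truth_is_l, post_l, 1 - post_l)
        decision_index = int(np.argmax(p_true.mean(axis=0))) + 1
    if not 1 <= decision_index <= odds.shape[1]:
        raise ValueError(f"decision_index {decision_index} out of range")
    at = odds[:, decision_index - 1]
    decisions = np.where(at >= 0, LEFT, RIGHT).astype(object)
    return SequentialBayesResult(odds=odds, decision_index=decision_index, decisions=decisions)


class GaussianBayesClassifier(BaseEstimator, ClassifierMixin):
    """Quadratic discriminant from per-class (mean, covariance), equal priors.

    The fixed-time reference classifier: with equal priors its decision at a
    single segment equals the sign of that segment's log probability ratio.
    """

    def __init__(self, shrinkage: float = 0.0):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(CLASS_LABELS, dtype=object)
        self.means_ = []
        self.covs_ = []
        for label in CLASS_LABELS:
            block = X[y == label]
            if len(block) < 2:
                raise ValueError(f"class {label!r} needs >= 2 samples")
            mu = block.mean(axis=0)
            s = np.cov(block, rowvar=False)
            s = np.atleast_2d(s)
            d = s.shape[0]
            s = (1 - self.shrinkage) * s + self.shrinkage * (np.trace(s) / d) * np.eye(d)
            if np.linalg.eigvalsh(s).min() <= 0:
                raise ValueError(
                    f"singular covariance for class {label!r}; increase shrinkage"
                )
            self.means_.append(mu)
            self.covs_.append(s)
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        scores = []
        for mu, s in zip(self.means_, self.covs_):
            d = X - mu
            sol = np.linalg.solve(s, d.T).T
            logdet = np.linalg.slogdet(s)[1]
            scores.append(-0.5 * (np.einsum("nd,nd->n", d, sol) + logdet))
        return scores[0] - scores[1]  # positive favours L

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, LEFT, RIGHT).astype(object)


def fixed_time_baselines(
    x: np.ndarray, y: np.ndarray, kind: str = "gaussian_bayes", shrinkage: float = 0.0
):
    """Fit a fixed-time reference classifier on one segment's features.

    ``kind`` is ``gaussian_bayes`` (quadratic discriminant from per-class
    mean/covariance) or ``lda`` (pooled-covariance linear discriminant).
    Returns (fitted classifier, predictions on the training features).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=object)
    if kind == "gaussian_bayes":
        clf = GaussianBayesClassifier(shrinkage=shrinkage).fit(x, y)
    elif kind == "lda":
        clf = LinearDiscriminantAnalysis()
        try:
            clf.fit(x, np.asarray(y, dtype=str))
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular pooled covariance; add shrinkage") from exc
    else:
        raise ValueError("kind must be 'gaussian_bayes' or 'lda'")
    return clf, np.asarray(clf.predict(x), dtype=object)
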