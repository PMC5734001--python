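"""Scikit-learn style estimators composing the full pipeline.

``ProjectivePowerExtractor`` learns the per-channel projective bases and
maps raw trials to projective-power feature sequences;
``SPRTClassifier`` adds the per-segment Gaussian class models and the
truncated sequential test on top. Both accept either an
:class:`~sprtbci.epochs.EpochSet` or a raw ``(trials, channels, samples)``
array (with timing metadata supplied as constructor parameters), so they
compose with scikit-learn model selection utilities that index X along the
first axis.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .epochs import EpochSet, SegmentationScheme
from .features import extract_features, fit_bases
from .model import fit_models
from .sprt import (
    DecisionPath,
    optimize_stopping_time,
    run_sprt_batch,
    thresholds_from_stopping_time,
)


def _coerce_epochs(
    X, y, sampling_rate, cue_time, channel_names, require_labels: bool
) -> EpochSet:
    if isinstance(X, EpochSet):
        if y is not None:
            X = EpochSet(
                data=X.data,
                sampling_rate=X.sampling_rate,
                cue_time=X.cue_time,
                labels=np.asarray(y, dtype=object),
                channel_names=X.channel_names,
            )
        epochs = X
    else:
        labels = None if y is None else np.asarray(y, dtype=object)
        epochs = EpochSet(
            data=np.asarray(X, dtype=float),
            sampling_rate=sampling_rate,
            cue_time=cue_time,
            labels=labels,
            channel_names=channel_names,
        )
    if require_labels and epochs.labels is None:
        raise ValueError("labels are required for fitting (pass y or a labelled EpochSet)")
    return epochs


class ProjectivePowerExtractor(BaseEstimator, TransformerMixin):
    """Learn projective bases and transform trials to power feature sequences.

    Parameters mirror the feature-extraction stage: segmentation window and
    step (seconds), the channel pair, the ridge added to the class
    autocorrelation matrices, and whether fitting uses only post-cue
    segments. ``transform`` returns the (n_trials, n_segments, n_channels)
    block of projective powers.
    """

    def __init__(
        self,
        sampling_rate: float = 128.0,
        cue_time: float = 3.0,
        channel_names: tuple[str, ...] = ("C3", "C4"),
        channels: tuple[str, str] = ("C3", "C4"),
        window_length: float = 1.0,
        step: float = 0.25,
        ridge: float | None = None,
        train_window: str = "post_cue",
    ):
        self.sampling_rate = sampling_rate
        self.cue_time = cue_time
        self.channel_names = channel_names
        self.channels = channels
        self.window_length = window_length
        self.step = step
        self.ridge = ridge
        self.train_window = train_window

    def _scheme(self) -> SegmentationScheme:
        return SegmentationScheme(window_length=self.window_length, step=self.step)

    def fit(self, X, y=None):
        epochs = _coerce_epochs(
            X, y, self.sampling_rate, self.cue_time, self.channel_names, True
        )
        scheme = self._scheme()
        self.bases_ = fit_bases(
            epochs,
            scheme,
            channels=tuple(self.channels),
            ridge=self.ridge,
            train_window=self.train_window,
        )
        feats = extract_features(epochs, scheme, self.bases_)
        self.timestamps_ = feats.timestamps
        return self

    def transform(self, X):
        check_is_fitted(self, "bases_")
        epochs = _coerce_epochs(
            X, None, self.sampling_rate, self.cue_time, self.channel_names, False
        )
        return extract_features(epochs, self._scheme(), self.bases_).values

    def feature_series(self, X, y=None):
        """Full :class:`FeatureSeries` (values + timestamps + labels)."""
        check_is_fitted(self, "bases_")
        epochs = _coerce_epochs(
            X, y, self.sampling_rate, self.cue_time, self.channel_names, False
        )
        return extract_features(epochs, self._scheme(), self.bases_)


class SPRTClassifier(BaseEstimator, ClassifierMixin):
    """Projective-power features + truncated SPRT, end to end.

    Fitting learns the per-channel projective bases, per-segment Gaussian
    class models on the post-cue feature sequence, and the stopping-time
    thresholds ``(xi_L, xi_R)`` from the target expected stopping segment
    count ``q_e`` (default: all post-cue segments). If ``criterion`` is set,
    ``q_e`` is chosen by internal cross-validation over ``q_grid``.

    Attributes of interest after fitting: ``bases_``, ``model_``,
    ``thresholds_``, ``q_e_``, ``expected_log_pr_``, ``sweep_``.
    """

    def __init__(
        self,
        sampling_rate: float = 128.0,
        cue_time: float = 3.0,
        channel_names: tuple[str, ...] = ("C3", "C4"),
        channels: tuple[str, str] = ("C3", "C4"),
        window_length: float = 1.0,
        step: float = 0.25,
        ridge: float | None = None,
        train_window: str = "post_cue",
        shrinkage: float = 0.05,
        transform: str = "raw",
        q_e: int | None = None,
        criterion: str | None = None,
        q_grid=None,
        n_splits: int = 5,
        tie_policy: str = "random",
        accuracy_floor: float = 0.7,
        random_state: int | None = 0,
    ):
        self.sampling_rate = sampling_rate
        self.cue_time = cue_time
        self.channel_names = channel_names
        self.channels = channels
        self.window_length = window_length
        self.step = step
        self.ridge = ridge
        self.train_window = train_window
        self.shrinkage = shrinkage
        self.transform = transform
        self.q_e = q_e
        self.criterion = criterion
        self.q_grid = q_grid
        self.n_splits = n_splits
        self.tie_policy = tie_policy
        self.accuracy_floor = accuracy_floor
        self.random_state = random_state

    def _extractor(self) -> ProjectivePowerExtractor:
        return ProjectivePowerExtractor(
            sampling_rate=self.sampling_rate,
            cue_time=self.cue_time,
            channel_names=self.channel_names,
            channels=self.channels,
            window_length=self.window_length,
            step=self.step,
            ridge=self.ridge,
            train_window=self.train_window,
        )

    def fit(self, X, y=None):
        self.extractor_ = self._extractor().fit(X, y)
        self.bases_ = self.extractor_.bases_
        feats = self.extractor_.feature_series(X, y)
        # decision stage runs on segments whose window lies after the cue
        post = feats.restrict(self.cue_time + self.window_length)
        if post.n_segments == 0:
            raise ValueError("no post-cue segments available for the decision stage")
        self.decision_timestamps_ = post.timestamps
        self.model_ = fit_models(post, shrinkage=self.shrinkage, transform=self.transform)
        ej_l, ej_r = self.model_.expected_sequences()
        self.expected_log_pr_ = (ej_l, ej_r)
        self.sweep_ = None
        if self.criterion is not None:
            grid = (
                np.arange(1, post.n_segments + 1)
                if self.q_grid is None
                else np.asarray(self.q_grid)
            )
            self.sweep_ = optimize_stopping_time(
                post,
                grid,
                criterion=self.criterion,
                shrinkage=self.shrinkage,
                transform=self.transform,
                n_splits=self.n_splits,
                seed=self.random_state or 0,
                tie_policy=self.tie_policy,
                accuracy_floor=self.accuracy_floor,
                time_origin=self.cue_time,
                smi_origin=self.cue_time,
            )
            self.q_e_ = self.sweep_.q_opt
        else:
            self.q_e_ = self.q_e if self.q_e is not None else post.n_segments
        self.thresholds_ = thresholds_from_stopping_time(ej_l, ej_r, self.q_e_)
        self.classes_ = np.array(["L", "R"], dtype=object)
        return self

    def _decision_features(self, X):
        check_is_fitted(self, "model_")
        feats = self.extractor_.feature_series(X)
        return feats.restrict(self.cue_time + self.window_length)

    def log_pr_traces(self, X) -> np.ndarray:
        """Cumulative evidence L_q per trial over the post-cue segments."""
        post = self._decision_features(X)
        return np.cumsum(self.model_.log_pr_matrix(post.values), axis=1)

    def decision_paths(self, X) -> list[DecisionPath]:
        """Run the truncated test on every trial; full per-trial record."""
        post = self._decision_features(X)
        j = self.model_.log_pr_matrix(post.values)
        rng = np.random.default_rng(self.random_state)
        decisions, stops, forced, traces = run_sprt_batch(
            j,
            self.thresholds_.xi_L,
            self.thresholds_.xi_R,
            self.thresholds_.q_E,
            self.tie_policy,
            rng,
        )
        return [
            DecisionPath(
                trace=traces[i, : stops[i]].copy(),
                decision=str(decisions[i]),
                stop_segment=int(stops[i]),
                stop_time=float(post.timestamps[stops[i] - 1]),
                forced=bool(forced[i]),
            )
            for i in range(len(decisions))
        ]

    def predict(self, X):
        post = self._decision_features(X)
        j = self.model_.log_pr_matrix(post.values)
        rng = np.random.default_rng(self.random_state)
        decisions, _, _, _ = run_sprt_batch(
            j,
            self.thresholds_.xi_L,
            self.thresholds_.xi_R,
            self.thresholds_.q_E,
            self.tie_policy,
            rng,
        )
        return decisions

    def decision_function(self, X):
        """Accumulated log probability ratio at the truncation point."""
        traces = self.log_pr_traces(X)
        return traces[:, self.thresholds_.q_E - 1]
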