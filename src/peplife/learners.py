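"""Regression learners for half-life prediction.

Three techniques are exposed behind one interface:

* ``svr`` — epsilon-insensitive support-vector regression (linear,
  polynomial or RBF kernel), the workhorse model family. Backed by
  scikit-learn's libsvm wrapper. Hyperparameters can be tuned by an inner
  cross-validated grid search maximizing Pearson R.
* ``knn`` — instance-based k-nearest-neighbour regression on Euclidean
  distance in the encoded feature space, with uniform or inverse-distance
  weighting. Inverse-distance weighting is the documented stand-in for
  entropic instance-based learners, which are not reproduced here.
* ``dtable`` — a decision-table regressor: training rows are grouped by the
  equal-frequency-discretized pattern of a selected feature subset and each
  cell predicts the mean half-life of its members; queries falling in an
  empty cell fall back to the global training mean.

The regression target is raw half-life in seconds by default; set
``log_target=True`` to fit on log half-life and exponentiate predictions
(useful when half-lives span several orders of magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import joblib
import numpy as np
from scipy.stats import pearsonr
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .features import EncoderSpec, FeatureMatrix, encode_dataset
from .sequences import HalfLifeDataset, Peptide

MODEL_FORMAT_VERSION = 1

TECHNIQUES = ("svr", "knn", "dtable")

#: default tuning grid for SVR (inner CV, Pearson-R criterion)
SVR_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVR_GAMMA_GRID = tuple(2.0 ** e for e in range(-7, 4))
SVR_EPSILON_GRID = (0.01, 0.1, 0.5)
KNN_K_GRID = tuple(range(1, 11))


@dataclass(frozen=True)
class LearnerSpec:
    """Technique and hyperparameters of one regression learner."""

    technique: str = "svr"
    # svr
    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: float | str = "scale"
    degree: int = 3
    tol: float = 1e-3
    # knn
    k: int = 5
    weighting: str = "uniform"  # or "inverse-distance"
    # dtable
    n_bins: int = 3
    # shared
    tune: bool = False
    log_target: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if isinstance(self.gamma, float) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.weighting not in ("uniform", "inverse-distance"):
            raise ValueError("weighting must be 'uniform' or 'inverse-distance'")


class DecisionTableRegressor:
    """Lookup-table regression on a discretized feature subset.

    Discretization is zero-aware, which suits sparse k-mer composition
    descriptors: an exact zero ("k-mer absent") is its own category, and
    the nonzero training values of each feature are cut into ``n_bins``
    equal-frequency bins (training-set quantiles). A cell is one joint bin
    pattern; it predicts the mean target of the training rows it contains.
    Queries in empty cells — e.g. a peptide lacking a k-mer every training
    peptide contains — and any query when the subset is empty return the
    global training mean.
    """

    def __init__(self, n_bins: int = 3):
        self.n_bins = n_bins
        self.edges_: list[np.ndarray] = []
        self.table_: dict[tuple, float] = {}
        self.global_mean_: float = 0.0

    def _keys(self, X: np.ndarray) -> list[tuple]:
        if X.shape[1] == 0:
            return [() for _ in range(X.shape[0])]
        cols = []
        for j in range(X.shape[1]):
            col = X[:, j]
            binned = 1 + np.searchsorted(self.edges_[j], col, side="right")
            cols.append(np.where(col == 0.0, 0, binned))
        return list(zip(*cols))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DecisionTableRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        self.global_mean_ = float(np.mean(y))
        qs = np.linspace(0, 1, self.n_bins + 1)[1:-1]
        self.edges_ = []
        for j in range(X.shape[1]):
            nonzero = X[:, j][X[:, j] != 0.0]
            if nonzero.size:
                self.edges_.append(np.unique(np.quantile(nonzero, qs)))
            else:
                self.edges_.append(np.empty(0))
        sums: dict[tuple, list[float]] = {}
        for key, yi in zip(self._keys(X), y):
            sums.setdefault(key, []).append(yi)
        self.table_ = {k: float(np.mean(v)) for k, v in sums.items()}
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array(
            [self.table_.get(k, self.global_mean_) for k in self._keys(X)]
        )


def _pearson_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return -1.0
    return float(pearsonr(y_true, y_pred)[0])


def _tune_svr(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> LearnerSpec:
    """Small grid search over (C, gamma, epsilon) by inner-CV Pearson R."""
    n = len(y)
    cv = KFold(n_splits=min(3, n), shuffle=True, random_state=spec.random_seed)
    gammas: Sequence[float | str] = SVR_GAMMA_GRID if spec.kernel != "linear" else ("scale",)
    best, best_score = spec, -np.inf
    for C in SVR_C_GRID:
        for gamma in gammas:
            for eps in SVR_EPSILON_GRID:
                scores = []
                for tr, te in cv.split(X):
                    est = SVR(kernel=spec.kernel, C=C, gamma=gamma,
                              epsilon=eps, degree=spec.degree, tol=spec.tol)
                    est.fit(X[tr], y[tr])
                    scores.append(_pearson_score(y[te], est.predict(X[te])))
                score = float(np.mean(scores))
                if score > best_score:
                    best_score = score
                    best = replace(spec, C=C, gamma=gamma, epsilon=eps, tune=False)
    return best


def _tune_knn(spec: LearnerSpec, X: np.ndarray, y: np.ndarray) -> LearnerSpec:
    n = len(y)
    cv = KFold(n_splits=min(3, n), shuffle=True, random_state=spec.random_seed)
    weights = "distance" if spec.weighting == "inverse-distance" else "uniform"
    best, best_score = spec, -np.inf
    for k in KNN_K_GRID:
        scores = []
        for tr, te in cv.split(X):
            kk = min(k, len(tr))
            est = KNeighborsRegressor(n_neighbors=kk, weights=weights)
            est.fit(X[tr], y[tr])
            scores.append(_pearson_score(y[te], est.predict(X[te])))
        score = float(np.mean(scores))
        if score > best_score:
            best_score = score
            best = replace(spec, k=k, tune=False)
    return best


@dataclass
class RegressionModel:
    """A fitted learner bound to an encoder and an optional feature subset."""

    spec: LearnerSpec
    encoder: EncoderSpec
    feature_names: list[str]
    feature_subset: list[str] | None
    estimator: object = field(repr=False)
    train_mean: float = 0.0
    train_y_range: tuple[float, float] = (0.0, 0.0)
    train_length: int | None = None  # required peptide length, if fixed

    def _check_lengths(self, peptides: Sequence[Peptide]) -> None:
        if self.train_length is None:
            return
        bad = [p for p in peptides if len(p) != self.train_length]
        if bad:
            raise ValueError(
                f"model requires peptides of length {self.train_length}; got "
                f"length {len(bad[0])} ({bad[0].sequence})"
            )

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict from already-encoded (and already-subset) feature rows."""
        raw = self.estimator.predict(np.atleast_2d(X))
        return np.exp(raw) if self.spec.log_target else raw

    def predict(self, peptides: Sequence[Peptide]) -> np.ndarray:
        """Predicted half-life in seconds for each peptide."""
        peptides = list(peptides)
        self._check_lengths(peptides)
        fm = encode_dataset(peptides, self.encoder)
        if self.feature_subset is not None:
            fm = fm.restrict(self.feature_subset)
        return self.predict_matrix(fm.values)


def fit_matrix(
    spec: LearnerSpec,
    X: FeatureMatrix,
    y: np.ndarray,
    feature_subset: Sequence[str] | None = None,
) -> RegressionModel:
    """Fit a learner on an encoded feature matrix. See :func:`fit`."""
    y = np.asarray(y, dtype=float)
    if X.n_samples != len(y):
        raise ValueError("rows of X must align with y")
    if len(y) < 2:
        raise ValueError("insufficient training data: need >= 2 rows")
    if np.any(y <= 0):
        raise ValueError("half-lives must be strictly positive")

    values = X.values
    names = list(X.feature_names)
    subset = list(feature_subset) if feature_subset is not None else None
    if subset is not None:
        values = values[:, X.column_indices(subset)]

    target = np.log(y) if spec.log_target else y

    if spec.technique == "svr":
        if spec.tune:
            spec = _tune_svr(spec, values, target)
        est = SVR(kernel=spec.kernel, C=spec.C, gamma=spec.gamma,
                  epsilon=spec.epsilon, degree=spec.degree, tol=spec.tol)
        est.fit(values, target)
    elif spec.technique == "knn":
        if spec.tune:
            spec = _tune_knn(spec, values, target)
        weights = "distance" if spec.weighting == "inverse-distance" else "uniform"
        k_eff = min(spec.k, len(y))  # k >= n degrades to the training mean
        est = KNeighborsRegressor(n_neighbors=k_eff, weights=weights)
        est.fit(values, target)
    else:
        # no subset → table over all features; empty subset → global mean
        est = DecisionTableRegressor(n_bins=spec.n_bins)
        est.fit(values, target)

    return RegressionModel(
        spec=spec,
        encoder=X.spec,
        feature_names=names,
        feature_subset=subset,
        estimator=est,
        train_mean=float(np.mean(y)),
        train_y_range=(float(np.min(y)), float(np.max(y))),
    )


def fit(
    spec: LearnerSpec,
    ds: HalfLifeDataset,
    encoder: EncoderSpec,
    feature_subset: Sequence[str] | None = None,
) -> RegressionModel:
    """Encode a dataset and fit a learner, returning a ready-to-use model.

    The returned model carries its encoder and subset, so :meth:`predict`
    accepts raw peptides. For binary (fixed-length) encoders the training
    length is recorded and enforced at prediction time.
    """
    X = encode_dataset(ds, encoder)
    model = fit_matrix(spec, X, ds.half_lives, feature_subset)
    if encoder.kind == "binary" and encoder.region == "full":
        model.train_length = len(ds.peptides[0])
    return model


def predict(model: RegressionModel, peptides: Sequence[Peptide]) -> np.ndarray:
    """Module-level alias for :meth:`RegressionModel.predict`."""
    return model.predict(peptides)


def save_model(model: RegressionModel, path: Union[str, Path]) -> None:
    """Serialize a fitted model (spec + encoder + subset + fitted state)."""
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path: Union[str, Path]) -> RegressionModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version}")
    return payload["model"]
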