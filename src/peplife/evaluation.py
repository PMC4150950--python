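"""Cross-validated evaluation and stable-vs-unstable group analysis.

Metrics follow the conventions of quantitative structure–activity
regression benchmarks:

* **R** — Pearson correlation between predicted and actual half-life.
* **R²** — coefficient of determination relative to the *training-mean*
  baseline: R² = 1 − Σ(ŷᵢ − xᵢ)² / SD with SD = Σ(xᵢ − ȳ_train)², where
  ȳ_train is the mean half-life of the training peptides. This definition
  is negative whenever the model predicts worse than the training mean.
* **MAE** — mean absolute error in seconds.

Cross-validation is five-fold: records are shuffled with a seed, split
into near-equal folds, each fold predicted by a model trained on the other
four, and metrics computed on the pooled out-of-fold predictions (SD uses
each record's own fold-specific training mean).

The group analysis contrasts the 20 longest-half-life (stable) against the
20 shortest-half-life (unstable) peptides: per-residue mean composition in
each group with a two-sided Welch t-test per residue, plus physicochemical
class means per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ttest_ind

from .features import EncoderSpec, encode_dataset
from .learners import LearnerSpec, RegressionModel, fit_matrix
from .physchem import peptide_properties
from .sequences import AMINO_ACIDS, HalfLifeDataset


@dataclass
class Metrics:
    r: float
    r2: float
    mae: float


def metrics(
    predicted: Sequence[float],
    actual: Sequence[float],
    train_mean: float | Sequence[float],
) -> Metrics:
    """R, R² and MAE of predictions against actual half-lives.

    ``train_mean`` is the mean half-life of the training peptides (a scalar,
    or one value per record when records come from different CV folds); it
    anchors the SD denominator of R². Zero-variance actuals or SD = 0 are
    degenerate and raise ``ValueError``.
    """
    yhat = np.asarray(predicted, dtype=float)
    x = np.asarray(actual, dtype=float)
    if yhat.shape != x.shape or x.size == 0:
        raise ValueError("predicted and actual must have equal non-zero length")
    if np.std(x) == 0:
        raise ValueError("R undefined: actual values have zero variance")
    tm = np.broadcast_to(np.asarray(train_mean, dtype=float), x.shape)
    sd = float(np.sum((x - tm) ** 2))
    if sd == 0:
        raise ValueError("R^2 undefined: SD (deviation from training mean) is zero")
    if np.std(yhat) == 0:
        r = 0.0  # constant predictions carry no linear association
    else:
        r = float(pearsonr(yhat, x)[0])
    r2 = 1.0 - float(np.sum((yhat - x) ** 2)) / sd
    mae = float(np.mean(np.abs(yhat - x)))
    return Metrics(r=r, r2=r2, mae=mae)


@dataclass
class CVReport:
    """Per-record out-of-fold predictions and pooled metrics."""

    fold_assignment: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    actual: np.ndarray = field(repr=False)
    train_means: np.ndarray = field(repr=False)
    r: float = 0.0
    r2: float = 0.0
    mae: float = 0.0
    seed: int = 0
    n_folds: int = 5


def cross_validate(
    ds: HalfLifeDataset,
    encoder: EncoderSpec,
    learner: LearnerSpec,
    seed: int = 0,
    n_folds: int = 5,
    feature_subset: Sequence[str] | None = None,
) -> CVReport:
    """Seeded k-fold cross-validation (default five-fold, pooled metrics)."""
    n = len(ds)
    if n < 2 * n_folds:
        raise ValueError(
            f"too few records for {n_folds}-fold CV: n={n} (need >= {2 * n_folds})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)

    X = encode_dataset(ds, encoder)
    y = ds.half_lives
    fold_assignment = np.empty(n, dtype=int)
    predicted = np.empty(n)
    train_means = np.empty(n)

    for f, test_idx in enumerate(folds):
        fold_assignment[test_idx] = f + 1
        train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
        Xtrain = type(X)(X.feature_names, X.values[train_idx], X.spec)
        model = fit_matrix(learner, Xtrain, y[train_idx], feature_subset)
        Xtest = X.values[test_idx]
        if feature_subset is not None:
            Xtest = Xtest[:, X.column_indices(list(feature_subset))]
        predicted[test_idx] = model.predict_matrix(Xtest)
        train_means[test_idx] = float(np.mean(y[train_idx]))

    m = metrics(predicted, y, train_means)
    return CVReport(
        fold_assignment=fold_assignment,
        predicted=predicted,
        actual=y.copy(),
        train_means=train_means,
        r=m.r,
        r2=m.r2,
        mae=m.mae,
        seed=seed,
        n_folds=n_folds,
    )


@dataclass
class GroupComparison:
    """Stable (top) vs unstable (bottom) half-life extremes of a dataset."""

    stable_indices: np.ndarray = field(repr=False)
    unstable_indices: np.ndarray = field(repr=False)
    composition_means: pd.DataFrame = field(repr=False)  # residues × {stable, unstable}
    p_values: pd.Series = field(repr=False)  # per residue, two-sided Welch t
    class_means: pd.DataFrame = field(repr=False)  # physicochemical panel × groups
    group_size: int = 20


def compare_extremes(ds: HalfLifeDataset, group_size: int = 20) -> GroupComparison:
    """Contrast amino-acid composition of the most vs least stable peptides.

    Groups are the ``group_size`` peptides with the longest and shortest
    half-lives (shrunk to ⌊n/2⌋ when the dataset is smaller than twice the
    requested size, so the groups stay disjoint). Per-residue composition
    differences are tested with a two-sided Welch t-test; residues constant
    in both groups get p = 1.0. Ties in half-life are broken by record
    order, so group membership depends only on the half-life values, not on
    the order records arrived in.
    """
    n = len(ds)
    g = min(group_size, n // 2)
    if g < 2:
        raise ValueError("need at least 4 records for a group comparison")

    order = np.lexsort(([p.sequence for p in ds.peptides], ds.half_lives))
    unstable_idx = order[:g]
    stable_idx = order[-g:]

    comp = encode_dataset(ds, EncoderSpec(kind="aac")).values
    stable_comp = comp[stable_idx]
    unstable_comp = comp[unstable_idx]

    means = pd.DataFrame(
        {
            "stable": stable_comp.mean(axis=0),
            "unstable": unstable_comp.mean(axis=0),
        },
        index=list(AMINO_ACIDS),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = ttest_ind(stable_comp, unstable_comp, equal_var=False).pvalue
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    p_series = pd.Series(pvals, index=list(AMINO_ACIDS), name="p_value")

    rows = {}
    for label, idx in (("stable", stable_idx), ("unstable", unstable_idx)):
        profiles = [peptide_properties(ds.peptides[i]) for i in idx]
        rows[label] = pd.DataFrame(profiles).mean()
    class_means = pd.DataFrame(rows)

    return GroupComparison(
        stable_indices=np.sort(stable_idx),
        unstable_indices=np.sort(unstable_idx),
        composition_means=means,
        p_values=p_series,
        class_means=class_means,
        group_size=g,
    )
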