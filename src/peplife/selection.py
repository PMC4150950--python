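"""Correlation-based feature-subset selection (CFS) with best-first search.

CFS scores a subset S of k features by the merit

    merit(S) = k * r_cf / sqrt(k + k*(k-1) * r_ff)

where ``r_cf`` is the mean absolute Pearson correlation between the
features of S and the target and ``r_ff`` the mean absolute pairwise
correlation within S. The merit rewards features correlated with the
half-life while penalizing redundancy among them. Constant features are
assigned correlation 0 (not NaN) so they can never be selected.

The search is forward best-first from the empty set: a priority queue of
subsets ordered by merit, the best unexpanded subset expanded by all
single-feature additions, terminating after a fixed number of consecutive
non-improving expansions (default 5). Ties between equal-merit subsets are
broken by lexicographic feature-name order, making the search fully
deterministic.

Selection is intended to run on the full training set (the historical
protocol for this method). That leaks target information into any outer
cross-validation run on the same data — cross-validated metrics after
full-set selection are optimistic. Run selection inside each training fold
if unbiased estimates matter.

The published selected feature sets for the 10mer and 16mer half-life
models ship as named built-ins (:data:`BUILTIN_FEATURE_SETS`) so those
model configurations can be reconstructed on user data without re-running
selection.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureMatrix

#: published selected feature sets, keyed by dataset-encoder pair
BUILTIN_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "hl10-aac": ("D", "G", "P", "R"),
    "hl10-dpc": ("EK", "EL", "GD", "GF", "IE", "KP", "PG", "YL"),
    "hl10-tpc": (
        "AAH", "AGR", "AMP", "ARE", "ASV", "DSI", "EEK", "ELY", "ESK",
        "FCI", "FGD", "FSL", "FSS", "FYC", "GDS", "GFG", "GLF", "GSI",
        "GTS", "ILP", "INF", "INK", "IRN", "ITK", "KIL", "KIS", "KLP",
        "LVL", "MVL", "PGF", "PVQ", "SGL", "SIE", "SLR", "SVL", "VFK",
        "VLF", "VYL",
    ),
    "hl16-aac": ("C", "D", "G", "R"),
    "hl16-dpc": ("CG", "GD", "GF"),
    "hl16-tpc": ("AQC", "EAQ", "FGD", "GFG", "QCG"),
}


def _abs_corr_with_target(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of every column with y; constant columns get 0."""
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc ** 2))
    Xc = values - values.mean(axis=0)
    sx = np.sqrt(np.sum(Xc ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.abs(r)


def _abs_corr_matrix(values: np.ndarray) -> np.ndarray:
    """|Pearson r| between all column pairs; pairs with a constant column get 0."""
    Xc = values - values.mean(axis=0)
    sx = np.sqrt(np.sum(Xc ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ Xc) / np.outer(sx, sx)
    r[~np.isfinite(r)] = 0.0
    np.clip(np.abs(r, out=r), 0.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def feature_target_correlation(X: FeatureMatrix, y: Sequence[float]) -> dict[str, float]:
    """Absolute Pearson correlation of every feature with the half-life."""
    y = np.asarray(y, dtype=float)
    if X.n_samples < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    r = _abs_corr_with_target(X.values, y)
    return dict(zip(X.feature_names, r.tolist()))


def _merit_from_corr(
    idx: Sequence[int], r_cf: np.ndarray, r_ff: np.ndarray
) -> float:
    k = len(idx)
    if k == 0:
        return 0.0
    idx = np.asarray(idx, dtype=int)
    mean_cf = float(np.mean(r_cf[idx]))
    if k == 1:
        return mean_cf
    sub = r_ff[np.ix_(idx, idx)]
    mean_ff = float((sub.sum() - k) / (k * (k - 1)))  # off-diagonal mean
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_merit(subset: Sequence[str], X: FeatureMatrix, y: Sequence[float]) -> float:
    """CFS merit of a named feature subset (empty subset has merit 0)."""
    if len(subset) == 0:
        return 0.0
    idx = X.column_indices(list(subset))
    r_cf = _abs_corr_with_target(X.values, np.asarray(y, dtype=float))
    r_ff = _abs_corr_matrix(X.values[:, idx])
    local = list(range(len(idx)))
    return _merit_from_corr(local, r_cf[idx], r_ff)


@dataclass
class SelectionResult:
    """Outcome of a subset search: the chosen features, their merit, the trace."""

    selected: list[str]
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(repr=False, default_factory=list)


def best_first_select(
    X: FeatureMatrix,
    y: Sequence[float],
    stale_limit: int = 5,
) -> SelectionResult:
    """Forward best-first CFS subset search.

    Expands subsets by single-feature additions in merit order and stops
    after ``stale_limit`` consecutive expansions that fail to improve on
    the best merit seen. With all-constant (zero-signal) features the empty
    set is returned with merit 0.
    """
    if len(X.feature_names) < 1:
        raise ValueError("need at least one candidate feature")
    y = np.asarray(y, dtype=float)
    names = list(X.feature_names)
    n_feat = len(names)
    r_cf = _abs_corr_with_target(X.values, y)
    r_ff = _abs_corr_matrix(X.values)

    order = sorted(range(n_feat), key=lambda i: names[i])  # lexicographic tie-break

    def key_of(subset: frozenset) -> tuple[str, ...]:
        return tuple(sorted(names[i] for i in subset))

    start = frozenset()
    best_subset, best_merit = start, 0.0
    discovery: dict[frozenset, tuple[str, ...]] = {start: ()}
    heap: list[tuple[float, tuple[str, ...], frozenset]] = [(0.0, (), start)]
    seen: set[frozenset] = {start}
    trace: list[tuple[tuple[str, ...], float]] = [((), 0.0)]
    stale = 0

    while heap and stale < stale_limit:
        neg_merit, _, subset = heapq.heappop(heap)
        improved = False
        for i in order:
            if i in subset:
                continue
            child = subset | {i}
            if child in seen:
                continue
            seen.add(child)
            discovery[child] = discovery[subset] + (names[i],)
            merit = _merit_from_corr(sorted(child), r_cf, r_ff)
            trace.append((key_of(child), merit))
            heapq.heappush(heap, (-merit, key_of(child), child))
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_subset = child
                improved = True
        stale = 0 if improved else stale + 1

    return SelectionResult(
        selected=list(discovery[best_subset]),
        merit=float(best_merit),
        trace=trace,
    )
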