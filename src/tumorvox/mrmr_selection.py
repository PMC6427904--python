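"""Minimal-redundancy maximal-relevance feature ranking and the dimension sweep.

Features are discretized into three levels at mu +/- sigma, mutual
information is the plug-in estimate in bits, and ranking is the standard
greedy incremental form: the first feature maximizes relevance I(x; c),
each later step adds argmax of [I(x; c) - mean MI(x, selected)].

The dimension sweep trains/evaluates a classifier on the top-f features for
f = 62 - 5n (n = 0..12), ranks every metric cell across f (higher is
better, tied values share the mean rank), and selects the dimension with
the smallest rank sum, breaking ties toward the smaller feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata


def sweep_f_values(n_features: int = 62, step: int = 5, n_max: int = 12) -> list[int]:
    """The swept dimensions f = n_features - step*n for n = 0..n_max."""
    values = [n_features - step * n for n in range(n_max + 1)]
    if values[-1] < 1:
        raise ValueError(f"sweep reaches non-positive dimension: {values}")
    return values


def discretize(column: np.ndarray) -> np.ndarray:
    """Three-level discretization split at mu - sigma and mu + sigma.

    Returns int8 codes 0 (low), 1 (mid), 2 (high).  A zero-variance column
    collapses to a single level with a warning.
    """
    column = np.asarray(column, dtype=np.float64)
    mu = column.mean()
    sigma = column.std()  # population std
    if sigma == 0:
        warnings.warn("zero-variance column discretizes to a single level", stacklevel=2)
        return np.zeros(column.shape, dtype=np.int8)
    codes = np.ones(column.shape, dtype=np.int8)
    codes[column < mu - sigma] = 0
    codes[column > mu + sigma] = 2
    return codes


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two categorical columns."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty columns")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    n_x, n_y = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * n_y + yi, minlength=n_x * n_y).reshape(n_x, n_y)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


@dataclass
class MRMRStep:
    """One greedy selection step."""

    feature: str
    relevance: float  # I(x; c)
    redundancy: float  # mean MI with the previously selected set (0 at step 1)
    score: float  # relevance - redundancy


@dataclass
class MRMRResult:
    order: list[str]
    steps: list[MRMRStep]
    discretization: str = "three-level at mu +/- sigma"

    def top(self, k: int) -> list[str]:
        return self.order[:k]


def mrmr_rank(
    features: Mapping[str, np.ndarray] | "np.ndarray",
    labels: np.ndarray,
    k: int | None = None,
    feature_names: Sequence[str] | None = None,
    pre_discretized: bool = False,
) -> MRMRResult:
    """Greedy mRMR ranking of ``features`` against the class column ``labels``.

    ``features`` is a name -> column mapping (e.g. a DataFrame) or a 2D
    array with ``feature_names``.  Ties are broken by input (registry)
    order.  ``k`` defaults to ranking every feature.
    """
    if hasattr(features, "columns"):  # pandas DataFrame
        feature_names = list(features.columns)
        columns = {n: np.asarray(features[n]) for n in feature_names}
    elif isinstance(features, Mapping):
        feature_names = list(features.keys())
        columns = {n: np.asarray(features[n]) for n in feature_names}
    else:
        arr = np.asarray(features)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(arr.shape[1])]
        columns = {n: arr[:, i] for i, n in enumerate(feature_names)}
    if not feature_names:
        raise ValueError("empty feature table")
    if k is None:
        k = len(feature_names)
    if not 1 <= k <= len(feature_names):
        raise ValueError(f"k must be in 1..{len(feature_names)}, got {k}")
    labels = np.asarray(labels)

    disc = {
        n: (columns[n] if pre_discretized else discretize(columns[n])) for n in feature_names
    }
    relevance = {n: mutual_information(disc[n], labels) for n in feature_names}

    selected: list[str] = []
    steps: list[MRMRStep] = []
    remaining = list(feature_names)
    pair_mi: dict[tuple[str, str], float] = {}
    red_sum = {n: 0.0 for n in feature_names}
    while len(selected) < k:
        best_name, best_score, best_red = None, -np.inf, 0.0
        for n in remaining:
            red = red_sum[n] / len(selected) if selected else 0.0
            score = relevance[n] - red
            if score > best_score:  # strict: earlier (registry) order wins ties
                best_name, best_score, best_red = n, score, red
        assert best_name is not None
        selected.append(best_name)
        remaining.remove(best_name)
        steps.append(
            MRMRStep(
                feature=best_name,
                relevance=relevance[best_name],
                redundancy=best_red,
                score=best_score,
            )
        )
        for n in remaining:  # fold the new member into each candidate's redundancy sum
            key = (best_name, n)
            if key not in pair_mi:
                pair_mi[key] = mutual_information(disc[best_name], disc[n])
            red_sum[n] += pair_mi[key]
    return MRMRResult(order=selected, steps=steps)


@dataclass
class SweepResult:
    """Outcome of the dimension sweep over the f-value list."""

    f_values: list[int]
    metric_tables: dict[int, dict[Hashable, float]]  # f -> cell -> value
    rank_sums: dict[int, float]
    selected_dimension: int
    ranking: list[str] = field(default_factory=list)  # global mRMR order used


def rank_sum_select(metric_tables: Mapping[int, Mapping[Hashable, float]]) -> SweepResult:
    """Rank every metric cell across f (higher better, mean rank on ties),
    sum ranks per f, and pick the smallest sum; ties go to the smaller f.
    """
    f_values = sorted(metric_tables.keys(), reverse=True)
    if not f_values:
        raise ValueError("empty metric tables")
    # Only cells defined (non-None, finite) for every f are comparable.
    cells = set(metric_tables[f_values[0]].keys())
    for f in f_values[1:]:
        cells &= set(metric_tables[f].keys())
    cells = sorted(
        c
        for c in cells
        if all(
            metric_tables[f][c] is not None and np.isfinite(metric_tables[f][c])
            for f in f_values
        )
    )
    if not cells:
        raise ValueError("no metric cell is defined for every f")
    rank_sums = {f: 0.0 for f in f_values}
    for cell in cells:
        values = np.array([metric_tables[f][cell] for f in f_values], dtype=np.float64)
        ranks = rankdata(-values, method="average")
        for f, r in zip(f_values, ranks):
            rank_sums[f] += float(r)
    best = min(f_values, key=lambda f: (rank_sums[f], f))
    return SweepResult(
        f_values=f_values,
        metric_tables={f: dict(metric_tables[f]) for f in f_values},
        rank_sums=rank_sums,
        selected_dimension=best,
    )


def dimension_sweep(
    ranking: Sequence[str],
    f_values: Sequence[int],
    evaluate_fn: Callable[[Sequence[str]], Mapping[Hashable, float]],
) -> SweepResult:
    """Evaluate ``evaluate_fn`` on the top-f prefix of one global mRMR
    ``ranking`` for every f, then apply rank-sum model selection.

    ``evaluate_fn`` maps a feature-name list to a metric-cell table (e.g.
    cross-validated Dice/PPV/sensitivity/specificity per region/cohort);
    the trainer/evaluator is injected so this module stays classifier-free.
    """
    f_values = list(f_values)
    for f in f_values:
        if f > len(ranking):
            raise ValueError(f"f = {f} exceeds the {len(ranking)} ranked features")
        if f < 1:
            raise ValueError(f"f must be >= 1, got {f}")
    tables = {f: dict(evaluate_fn(list(ranking[:f]))) for f in f_values}
    result = rank_sum_select(tables)
    result.ranking = list(ranking)
    return result
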