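"""ReliefF feature weighting, top-d selection, and a Kruskal-Wallis screen.

ReliefF scores each feature by how well it separates a sample from its
nearest neighbours of other classes while keeping it close to neighbours
of its own class.  For each sampled instance ``R`` the ``k`` nearest
*hits* (same class) and, per other class ``C``, the ``k`` nearest
*misses* are found by Manhattan distance in the range-normalised feature
space; each feature's weight is then updated

    W[f] <- W[f] - sum_hits diff(f, R, H) / (m k)
                 + sum_{C != class(R)} P(C) / (1 - P(class(R)))
                   * sum_misses diff(f, R, M) / (m k)

with ``diff`` the absolute difference normalised by the feature's range
(the Kononenko prior-weighted multiclass form).  Weights lie in
``[-1, 1]``; a constant feature scores exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kruskal

__all__ = [
    "ReliefFConfig",
    "SelectionResult",
    "relieff_weights",
    "select_top",
    "kruskal_wallis_screen",
]

#: Paper-matching default for the retained feature-space dimension.
DEFAULT_DIMENSION = 42


@dataclass(frozen=True)
class ReliefFConfig:
    """ReliefF hyperparameters.

    ``m_samples="all"`` iterates deterministically over every instance
    (no sampling noise); an integer draws that many instances without
    replacement under ``seed``.  ``k_neighbors`` must stay below the
    smallest class count.
    """

    k_neighbors: int = 10
    m_samples: int | Literal["all"] = "all"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.m_samples != "all" and int(self.m_samples) < 1:
            raise ValueError("m_samples must be >= 1 or 'all'")


@dataclass
class SelectionResult:
    """Descending-weight ranking and the retained top-``dimension`` subset."""

    ranked_indices: np.ndarray
    dimension: int
    selected_names: list[str]

    @property
    def selected_indices(self) -> np.ndarray:
        return self.ranked_indices[: self.dimension]


def relieff_weights(features: np.ndarray, labels: np.ndarray,
                    config: ReliefFConfig = ReliefFConfig()) -> np.ndarray:
    """Multiclass ReliefF weights, one per feature column.

    Raises for single-class input or when any class has too few members
    for ``k_neighbors`` same-class neighbours.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n, d = X.shape
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("ReliefF needs at least 2 classes")
    counts = np.bincount(y_idx)
    k = config.k_neighbors
    if counts.min() <= k:
        raise ValueError(
            f"k_neighbors={k} too large: smallest class has {counts.min()} members"
        )
    priors = counts / n

    # Range normalisation; constant features get range 1 so their diffs
    # are exactly 0 and their weights stay exactly 0.
    lo = X.min(axis=0)
    rng_ = X.max(axis=0) - lo
    rng_safe = np.where(rng_ > 0, rng_, 1.0)
    Xn = (X - lo) / rng_safe

    if config.m_samples == "all":
        sampled = np.arange(n)
    else:
        m = int(config.m_samples)
        gen = np.random.default_rng(config.seed)
        sampled = gen.choice(n, size=min(m, n), replace=False)
    m_eff = sampled.size

    dist = cdist(Xn, Xn, metric="cityblock")
    np.fill_diagonal(dist, np.inf)  # a sample is never its own neighbour

    W = np.zeros(d)
    class_members = [np.flatnonzero(y_idx == c) for c in range(classes.size)]
    for r in sampled:
        cr = y_idx[r]
        xr = Xn[r]
        for c, members in enumerate(class_members):
            order = members[np.argsort(dist[r, members], kind="stable")[:k]]
            diffs = np.abs(Xn[order] - xr).sum(axis=0)
            if c == cr:
                W -= diffs / (m_eff * k)
            else:
                W += (priors[c] / (1.0 - priors[cr])) * diffs / (m_eff * k)
    return W


def select_top(weights: np.ndarray, d: int,
               names: list[str] | None = None) -> SelectionResult:
    """Indices of the ``d`` largest weights, descending; ties by ascending index."""
    weights = np.asarray(weights, dtype=np.float64)
    if not 1 <= d <= weights.size:
        raise ValueError(f"d={d} out of range for {weights.size} features")
    ranked = np.argsort(-weights, kind="stable")
    selected = ranked[:d]
    sel_names = [names[i] for i in selected] if names is not None else [
        f"f{i}" for i in selected
    ]
    return SelectionResult(ranked_indices=ranked, dimension=d, selected_names=sel_names)


def kruskal_wallis_screen(features: np.ndarray, labels: np.ndarray,
                          alpha: float = 0.05,
                          names: list[str] | None = None) -> pd.DataFrame:
    """Per-feature Kruskal-Wallis rank test across classes.

    Returns a DataFrame with columns ``H``, ``p_value`` and
    ``significant`` (``p < alpha``); H uses the standard tie correction
    and p-values come from the chi-squared approximation with
    ``n_classes - 1`` degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[0] == 1 and np.asarray(labels).size != 1:
        X = X.T
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 classes")
    group_rows = [np.flatnonzero(y == c) for c in classes]
    if any(rows.size < 2 for rows in group_rows):
        raise ValueError("each class needs at least 2 samples")
    rows = []
    for j in range(X.shape[1]):
        groups = [X[g, j] for g in group_rows]
        H, p = kruskal(*groups)
        rows.append({"H": H, "p_value": p, "significant": bool(p < alpha)})
    index = names if names is not None else [f"f{j}" for j in range(X.shape[1])]
    return pd.DataFrame(rows, index=index)
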