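"""Quantile-difference coordinates for two-condition expression data.

Each gene g is represented by the vector of differences between the
empirical quantiles of its expression in condition 1 and condition 2,
evaluated at a small set of probabilities (default quartiles).  A gene
with no expression change sits near the origin of this space; strongly
differentially expressed genes are outliers.  Everything downstream
(permutation null, outlier index, nearest-neighbour calibration) lives
in this coordinate system, under one weighted Euclidean metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "ExpressionPair",
    "MethodConfig",
    "QuantileDiffMatrix",
    "estimate_quantiles",
    "quantile_differences",
    "scale_columns",
    "pairwise_weighted_distances",
]


@dataclass(frozen=True)
class ExpressionPair:
    """Expression matrices (genes x samples) for two conditions.

    Rows of ``cond1`` and ``cond2`` refer to the same genes, in the same
    order.  Values are assumed already normalized/transformed; no
    pre-processing is applied here.
    """

    cond1: np.ndarray
    cond2: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c1 = np.asarray(self.cond1, dtype=float)
        c2 = np.asarray(self.cond2, dtype=float)
        if c1.ndim != 2 or c2.ndim != 2:
            raise ValueError("expression matrices must be 2-D (genes x samples)")
        if c1.shape[0] != c2.shape[0]:
            raise ValueError(
                f"gene counts differ between conditions: {c1.shape[0]} vs {c2.shape[0]}"
            )
        if c1.shape[1] < 3 or c2.shape[1] < 3:
            raise ValueError("each condition needs at least 3 samples for quantile estimation")
        if not (np.isfinite(c1).all() and np.isfinite(c2).all()):
            raise ValueError("expression matrices contain non-finite values")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != c1.shape[0]:
            raise ValueError("label count does not match gene count")
        if len(set(labels)) != len(labels):
            raise ValueError("gene labels must be unique")
        object.__setattr__(self, "cond1", c1)
        object.__setattr__(self, "cond2", c2)
        object.__setattr__(self, "labels", labels)

    @property
    def n_genes(self) -> int:
        return self.cond1.shape[0]

    @classmethod
    def from_matrices(cls, cond1, cond2, labels=None) -> "ExpressionPair":
        cond1 = np.asarray(cond1, dtype=float)
        if labels is None:
            labels = tuple(f"Gene{i + 1}" for i in range(cond1.shape[0]))
        return cls(cond1, np.asarray(cond2, dtype=float), tuple(labels))


@dataclass(frozen=True)
class MethodConfig:
    """Tuning parameters of the method.

    Parameters
    ----------
    probs : tuple of float
        Probabilities at which quantiles are compared; strictly
        increasing, each in (0, 1).
    weights : tuple of float
        Per-quantile weights of the distance; stored normalized to sum 1.
    alpha : float
        Tail level of the permutation null: genes above the (1 - alpha)
        percentile of the null outlier index become potential DEGs.
    n_permutations : int
        Number of sample-label permutations (B).
    n_neighbours : int
        K for the nearest-neighbour false-positive counts.
    n_folds : int
        Number of groups the permutation replicates are split into for
        the neighbourhood calibration.
    scale : bool
        Divide each quantile-difference column by its original-data
        standard deviation before any distance is taken.
    max_clusters : int
        Largest k tried when choosing the cluster count by silhouette.
    replicable : bool
        When True all randomness derives from ``seed``.
    seed : int
        Master seed.
    workers : int or None
        Parallel worker count for the permutation loop; None lets the
        scheduler use all available processors.  Results are identical
        for any worker count.
    """

    probs: tuple[float, ...] = (0.25, 0.5, 0.75)
    weights: tuple[float, ...] = (0.25, 0.5, 0.25)
    alpha: float = 0.05
    n_permutations: int = 100
    n_neighbours: int = 10
    n_folds: int = 10
    scale: bool = True
    max_clusters: int = 10
    replicable: bool = True
    seed: int = 0
    workers: int | None = None

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        if not probs or any(not (0.0 < p < 1.0) for p in probs):
            raise ValueError("probs must be non-empty with every value in (0, 1)")
        if any(b <= a for a, b in zip(probs, probs[1:])):
            raise ValueError("probs must be strictly increasing")
        weights = np.asarray(self.weights, dtype=float)
        if weights.shape != (len(probs),) or (weights <= 0).any():
            raise ValueError("weights must be positive and match probs in length")
        weights = weights / weights.sum()
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (1 <= self.n_folds <= self.n_permutations):
            raise ValueError("n_folds must satisfy 1 <= n_folds <= n_permutations")
        if self.n_neighbours < 1:
            raise ValueError("n_neighbours must be >= 1")
        if self.max_clusters < 2:
            raise ValueError("max_clusters must be >= 2")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "weights", tuple(weights))


@dataclass(frozen=True)
class QuantileDiffMatrix:
    """Cases x probabilities matrix of quantile differences.

    ``origin`` tags each row with where it came from: the original gene
    index, or the permutation replicate it belongs to.  ``scale_factors``
    record the per-column divisors applied (all 1.0 when unscaled).
    """

    values: np.ndarray
    scale_factors: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        factors = np.asarray(self.scale_factors, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if factors.shape != (values.shape[1],):
            raise ValueError("one scale factor per column required")
        if (factors <= 0).any():
            raise ValueError("scale factors must be positive")
        origin = self.origin
        if origin is None:
            origin = np.arange(values.shape[0])
        origin = np.asarray(origin)
        if origin.shape != (values.shape[0],):
            raise ValueError("one origin tag per row required")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "scale_factors", factors)
        object.__setattr__(self, "origin", origin)

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]


def estimate_quantiles(values, probs) -> np.ndarray:
    """Empirical quantiles by linear interpolation of order statistics.

    Uses the classic continuous estimator with plotting position
    h = (m - 1) p + 1: the h-th order statistic, linearly interpolated
    between neighbours when h is fractional.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no observations")
    probs = np.asarray(probs, dtype=float)
    if ((probs <= 0) | (probs >= 1)).any():
        raise ValueError("probabilities must lie in (0, 1)")
    return np.quantile(values, probs, method="linear")


def quantile_differences(pair: ExpressionPair, config: MethodConfig) -> QuantileDiffMatrix:
    """Per-gene condition-1 minus condition-2 quantiles, unscaled."""
    probs = np.asarray(config.probs)
    q1 = np.quantile(pair.cond1, probs, axis=1, method="linear").T
    q2 = np.quantile(pair.cond2, probs, axis=1, method="linear").T
    return QuantileDiffMatrix(
        values=q1 - q2,
        scale_factors=np.ones(len(probs)),
        origin=np.arange(pair.n_genes),
    )


def scale_columns(
    V: QuantileDiffMatrix, reference: QuantileDiffMatrix, enabled: bool = True
) -> QuantileDiffMatrix:
    """Divide each column by the reference column's sample sd.

    The reference is always the ORIGINAL-data quantile-difference matrix,
    so original genes and permuted replicates share one coordinate
    system.  No centering: zero must keep meaning "no difference".
    """
    if reference.values.shape[1] != V.values.shape[1]:
        raise ValueError("reference column count does not match")
    if not enabled:
        return V
    sds = reference.values.std(axis=0, ddof=1)
    if (sds <= 0).any() or not np.isfinite(sds).all():
        raise ValueError("degenerate quantile column (zero standard deviation in reference)")
    return QuantileDiffMatrix(
        values=V.values / sds,
        scale_factors=V.scale_factors * sds,
        origin=V.origin,
    )


def pairwise_weighted_distances(points, weights) -> np.ndarray:
    """Condensed weighted Euclidean distances d(u,v) = sqrt(sum_p w_p (u_p - v_p)^2)."""
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if points.ndim != 2 or weights.shape != (points.shape[1],):
        raise ValueError("weights length must equal the number of columns")
    return pdist(points * np.sqrt(weights))


def weighted_distances_to(point, others, weights) -> np.ndarray:
    """Weighted Euclidean distance from one point to each row of ``others``."""
    diff = np.asarray(others, dtype=float) - np.asarray(point, dtype=float)
    return np.sqrt((diff * diff) @ np.asarray(weights, dtype=float))
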