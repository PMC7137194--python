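"""Permutation null and the OR outlier index.

The null model for "no differential expression" is built by shuffling
the sample-to-condition assignment: for each of B replicates the pooled
s1 + s2 sample columns are permuted (the same permutation for every
gene) and re-split into two pseudo-conditions.  The quantile-difference
vectors of permuted genes emulate non-DE behaviour.

The OR index scores how much of an outlier a case is within its own
case set: the median of its weighted distances to all other cases,
divided by the median over all pairwise distances of the set.  A value
near 1 is typical; large values mark outliers.  Genes whose OR in the
original data exceeds the (1 - alpha) percentile of the pooled null OR
distribution are the *potential* DEGs; null cases above the same
threshold are the retained "known false positives" used downstream to
calibrate neighbourhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.spatial.distance import squareform

from .quantile_space import (
    ExpressionPair,
    MethodConfig,
    QuantileDiffMatrix,
    pairwise_weighted_distances,
    quantile_differences,
    scale_columns,
)

__all__ = [
    "NullCaseSet",
    "permute_replicate",
    "or_scores",
    "build_null_set",
    "flag_potential",
]


@dataclass(frozen=True)
class NullCaseSet:
    """Pooled permuted cases, their OR values and the retained subset.

    ``cases`` holds the scaled quantile-difference vectors of all n * B
    permuted cases; ``replicate_id`` maps each case to its permutation
    replicate (1..B).  ``retained`` indexes the cases whose OR exceeds
    ``threshold``, the empirical (1 - alpha) percentile of ``or_values``.
    """

    cases: np.ndarray
    replicate_id: np.ndarray
    or_values: np.ndarray
    threshold: float
    retained: np.ndarray

    @property
    def n_cases(self) -> int:
        return self.cases.shape[0]

    @property
    def retained_cases(self) -> np.ndarray:
        return self.cases[self.retained]


def permute_replicate(pair: ExpressionPair, rng: np.random.Generator) -> ExpressionPair:
    """One permutation replicate: shuffle pooled sample columns, re-split.

    The same column permutation is applied to every gene, mimicking a
    random reassignment of samples to the two conditions.
    """
    s1 = pair.cond1.shape[1]
    pooled = np.concatenate([pair.cond1, pair.cond2], axis=1)
    perm = rng.permutation(pooled.shape[1])
    shuffled = pooled[:, perm]
    return ExpressionPair(shuffled[:, :s1], shuffled[:, s1:], pair.labels)


def or_scores(points, weights) -> np.ndarray:
    """OR outlier index of each case within the set.

    OR(x_i) = median_{j != i} d(x_i, x_j) / M with M the median of all
    pairwise weighted distances.  Medians of even counts are the mean of
    the two central order statistics.
    """
    points = np.asarray(points, dtype=float)
    m = points.shape[0]
    if m < 3:
        raise ValueError("need at least 3 cases to score outliers")
    condensed = pairwise_weighted_distances(points, weights)
    M = float(np.median(condensed))
    if M == 0.0:
        raise ValueError("degenerate case set (median pairwise distance is zero)")
    D = squareform(condensed)
    # row-wise median excluding the self-distance on the diagonal
    off_diag = D[~np.eye(m, dtype=bool)].reshape(m, m - 1)
    return np.median(off_diag, axis=1) / M


def _replicate_or(pair: ExpressionPair, config: MethodConfig,
                  scale_ref: QuantileDiffMatrix, seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    perm_pair = permute_replicate(pair, rng)
    V = quantile_differences(perm_pair, config)
    V = scale_columns(V, scale_ref, enabled=config.scale)
    return V.values, or_scores(V.values, config.weights)


def build_null_set(
    pair: ExpressionPair, config: MethodConfig, scale_ref: QuantileDiffMatrix
) -> NullCaseSet:
    """Generate B permutation replicates and pool their OR values.

    OR is computed *within* each replicate's n cases; the threshold is
    the empirical (1 - alpha) quantile (linear interpolation) of the
    pooled n * B values.  Replicate b's random stream derives from
    (seed, b), so the result is identical for any worker count and
    execution order.
    """
    B = config.n_permutations
    if config.replicable:
        children = np.random.SeedSequence(config.seed).spawn(B)
    else:
        children = np.random.SeedSequence().spawn(B)
    results = Parallel(n_jobs=config.workers or -1, prefer="processes")(
        delayed(_replicate_or)(pair, config, scale_ref, child) for child in children
    )
    cases = np.concatenate([values for values, _ in results], axis=0)
    or_values = np.concatenate([scores for _, scores in results])
    replicate_id = np.repeat(np.arange(1, B + 1), pair.n_genes)
    threshold = float(np.quantile(or_values, 1.0 - config.alpha, method="linear"))
    retained = np.flatnonzero(or_values > threshold)
    return NullCaseSet(cases, replicate_id, or_values, threshold, retained)


def flag_potential(original_or: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of genes with OR strictly above the null threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    idx = np.flatnonzero(np.asarray(original_or) > threshold)
    if idx.size == 0:
        warnings.warn("no gene exceeds the permutation threshold; no potential DEGs",
                      stacklevel=2)
    return idx
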