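"""Nearest-neighbour false-positive calibration (FP and dFP).

The retained null cases are known false positives: permuted cases whose
OR also cleared the threshold.  To judge whether a potential DEG looks
like them, the B permutation replicates are split into ``n_folds``
groups; within each fold a potential gene is ranked against the other
potential genes plus that fold's retained null cases, and

* FP  = how many of its K nearest neighbours are null cases,
* dFP = the sum of inverse distances to those null neighbours
        (a kernel-density flavoured weighting of the same counts),

averaged over folds.  A genuinely differentially expressed gene sits in
a region empty of null cases (FP near 0); a false positive is embedded
among them (FP near the uniform-mixing expectation K * P / (P + n_pot)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantile_space import weighted_distances_to
from .permutation import NullCaseSet

__all__ = [
    "FoldAssignment",
    "NeighbourhoodScore",
    "assign_folds",
    "fp_dfp",
    "expected_fp",
]

_EPS = 1e-10


@dataclass(frozen=True)
class FoldAssignment:
    """Balanced random partition of permutation replicates into folds."""

    fold_of_replicate: dict[int, int]
    fold_cases: tuple[np.ndarray, ...]  # per fold: retained-case vectors

    @property
    def n_folds(self) -> int:
        return len(self.fold_cases)

    @property
    def fold_counts(self) -> np.ndarray:
        return np.array([c.shape[0] for c in self.fold_cases])


@dataclass(frozen=True)
class NeighbourhoodScore:
    gene_index: int
    fp_per_fold: np.ndarray
    dfp_per_fold: np.ndarray

    @property
    def mean_fp(self) -> float:
        return float(self.fp_per_fold.mean())

    @property
    def mean_dfp(self) -> float:
        return float(self.dfp_per_fold.mean())


def assign_folds(null: NullCaseSet, n_folds: int, rng: np.random.Generator) -> FoldAssignment:
    """Randomly split the B replicates into balanced folds.

    Folds partition replicates (not individual cases) so each fold's
    retained cases come from independent permutations.
    """
    replicates = np.unique(null.replicate_id)
    B = replicates.size
    if n_folds > B:
        raise ValueError(f"n_folds ({n_folds}) exceeds the number of replicates ({B})")
    order = rng.permutation(B)
    fold_of_replicate = {
        int(replicates[pos]): int(i % n_folds) + 1 for i, pos in enumerate(order)
    }
    retained_reps = null.replicate_id[null.retained]
    retained_vecs = null.retained_cases
    fold_labels = np.array([fold_of_replicate[int(b)] for b in retained_reps])
    fold_cases = tuple(
        retained_vecs[fold_labels == f] for f in range(1, n_folds + 1)
    )
    return FoldAssignment(fold_of_replicate, fold_cases)


def fp_dfp(
    potentials: np.ndarray,
    folds: FoldAssignment,
    n_neighbours: int,
    weights,
    gene_indices=None,
) -> list[NeighbourhoodScore]:
    """FP and dFP per potential DEG, per fold.

    For gene g in fold f the candidate set is the other potential genes
    followed by fold f's retained null cases, ranked by weighted
    distance to g; ties break by candidate position in that ordering.
    """
    potentials = np.asarray(potentials, dtype=float)
    n_pot = potentials.shape[0]
    K = n_neighbours
    if gene_indices is None:
        gene_indices = np.arange(n_pot)
    for f, cases in enumerate(folds.fold_cases, start=1):
        if n_pot - 1 + cases.shape[0] < K:
            raise ValueError(f"neighbourhood undersized in fold {f}")
    scores = []
    for i in range(n_pot):
        fp = np.empty(folds.n_folds)
        dfp = np.empty(folds.n_folds)
        others = np.delete(potentials, i, axis=0)
        d_others = weighted_distances_to(potentials[i], others, weights)
        for f, cases in enumerate(folds.fold_cases):
            d_cases = weighted_distances_to(potentials[i], cases, weights)
            d_all = np.concatenate([d_others, d_cases])
            is_null = np.zeros(d_all.size, dtype=bool)
            is_null[d_others.size:] = True
            # stable sort => distance ties resolved by candidate ordinal
            nearest = np.argsort(d_all, kind="stable")[:K]
            null_hits = nearest[is_null[nearest]]
            fp[f] = null_hits.size
            dfp[f] = np.sum(1.0 / np.maximum(d_all[null_hits], _EPS))
        scores.append(NeighbourhoodScore(int(gene_indices[i]), fp, dfp))
    return scores


def expected_fp(n_neighbours: int, folds: FoldAssignment, n_potential: int):
    """Uniform-mixing reference for FP.

    Under complete mixing of potential genes with a fold's retained
    cases, each of the K nearest neighbours is a null case with
    probability P_f / (P_f + n_potential).  Returns (expectation,
    proportion-in-percent), both averaged over folds.
    """
    if n_potential < 1:
        raise ValueError("need at least one potential DEG")
    counts = folds.fold_counts.astype(float)
    with np.errstate(invalid="ignore"):
        props = np.where(counts + n_potential > 0, counts / (counts + n_potential), 0.0)
    proportion = float(props.mean())
    return n_neighbours * proportion, 100.0 * proportion
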