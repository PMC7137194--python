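"""DEG selection rules and PAM clustering of the candidate genes.

Two selection criteria label the potential DEGs:

* strong  — mean FP (and hence mean dFP) exactly 0: no retained null
  case ever enters the gene's neighbourhood;
* relaxed — mean FP below the expected false-positive-neighbour count
  under uniform mixing, the one numeric reference the method defines.

Independently, the candidates are clustered on their z-scored
(OR, FP, dFP) profile with partitioning around medoids (PAM, classic
BUILD + SWAP), the cluster count chosen by maximum mean silhouette.
Clusters are reported in decreasing order of mean OR, so the most
differentially expressed genes land in cluster 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

__all__ = [
    "ClusterSummary",
    "strong_relaxed_flags",
    "pam_cluster",
    "mean_silhouette",
    "choose_k",
    "summarize_clusters",
]


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster accounting, clusters ordered by decreasing mean OR."""

    k: int
    sizes: tuple[int, ...]
    characteristics: pd.DataFrame  # rows: cluster; cols: mean/sd of OR, FP, dFP
    members: tuple[tuple[str, ...], ...]
    silhouette_by_k: dict[int, float]
    assignment: np.ndarray  # cluster ordinal (1-based) per input row


def strong_relaxed_flags(mean_fp: np.ndarray, expectation: float):
    """Strong: mean FP exactly 0.  Relaxed: mean FP strictly below the
    expected false-positive-neighbour reference (strong genes are always
    relaxed, even in the degenerate zero-reference case)."""
    mean_fp = np.asarray(mean_fp, dtype=float)
    if mean_fp.size == 0:
        raise ValueError("no scores to flag")
    strong = mean_fp == 0.0
    relaxed = (mean_fp < expectation) | strong
    return strong, relaxed


def _pam_cost(D: np.ndarray, medoids: np.ndarray) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    m = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        # gain of adding candidate c: sum of reductions over all points
        gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


# tiny instances are solved exactly; above this many medoid subsets the
# BUILD+SWAP local search takes over
_EXACT_SUBSET_LIMIT = 1000


def pam_cluster(points: np.ndarray, k: int):
    """Partitioning around medoids on Euclidean distances.

    Small instances (at most ``_EXACT_SUBSET_LIMIT`` candidate medoid
    subsets) are solved by exact enumeration.  Larger ones use the
    deterministic BUILD initialization followed by greedy SWAP local
    search (best improving medoid <-> non-medoid exchange per pass) until
    no swap lowers the total distance-to-medoid cost.  Both paths are
    fully deterministic.  Returns (medoid indices, assignment of each
    point to a medoid ordinal).
    """
    points = np.asarray(points, dtype=float)
    m = points.shape[0]
    if not (2 <= k < m):
        raise ValueError(f"k must satisfy 2 <= k < {m}")
    D = squareform(pdist(points))
    if comb(m, k) <= _EXACT_SUBSET_LIMIT:
        best = min(
            itertools.combinations(range(m), k),
            key=lambda s: (_pam_cost(D, np.array(s)), s),
        )
        medoids_arr = np.array(best)
        return medoids_arr, np.argmin(D[:, medoids_arr], axis=1)
    medoids = _pam_build(D, k)
    cost = _pam_cost(D, np.array(medoids))
    while True:
        best = (0.0, None)
        medoid_set = set(medoids)
        for mi in range(k):
            trial = list(medoids)
            for c in range(m):
                if c in medoid_set:
                    continue
                trial[mi] = c
                delta = _pam_cost(D, np.array(trial)) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, c))
            trial[mi] = medoids[mi]
        if best[1] is None:
            break
        mi, c = best[1]
        medoids[mi] = c
        cost += best[0]
    medoids_arr = np.array(sorted(medoids))
    assignment = np.argmin(D[:, medoids_arr], axis=1)
    return medoids_arr, assignment


def mean_silhouette(points: np.ndarray, assignment: np.ndarray) -> float:
    """Average silhouette width (b - a) / max(a, b); singletons score 0."""
    assignment = np.asarray(assignment)
    if np.unique(assignment).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = squareform(pdist(np.asarray(points, dtype=float)))
    return float(silhouette_samples(D, assignment, metric="precomputed").mean())


def choose_k(points: np.ndarray, max_clusters: int):
    """Best cluster count by mean silhouette over k = 2..max_clusters.

    Ties go to the smallest k.  Returns (k*, {k: mean silhouette}).
    """
    points = np.asarray(points, dtype=float)
    m = points.shape[0]
    if m <= 3:
        raise ValueError("too few points to choose a cluster count")
    widths: dict[int, float] = {}
    for k in range(2, min(max_clusters, m - 1) + 1):
        _, assignment = pam_cluster(points, k)
        widths[k] = mean_silhouette(points, assignment)
    best = max(widths, key=lambda k: (widths[k], -k))
    return best, widths


def _zscore(table: np.ndarray) -> np.ndarray:
    mu = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (table - mu) / sd


def summarize_clusters(
    scores: pd.DataFrame, k: int | None = None, max_clusters: int = 10
) -> ClusterSummary:
    """Cluster the potential DEGs on z-scored (OR, FP, dFP) and summarize.

    ``scores`` needs columns gene, OR, FP, dFP.  When ``k`` is None the
    cluster count is chosen by silhouette.  Clusters are relabeled in
    decreasing order of mean OR.
    """
    if scores.empty:
        raise ValueError("no potential DEGs to cluster")
    table = _zscore(scores[["OR", "FP", "dFP"]].to_numpy(dtype=float))
    silhouette_by_k: dict[int, float] = {}
    if k is None:
        k, silhouette_by_k = choose_k(table, max_clusters)
    _, raw_assignment = pam_cluster(table, k)
    or_vals = scores["OR"].to_numpy(dtype=float)
    # empty clusters (possible with duplicated points) sort last
    cluster_means = np.array(
        [or_vals[raw_assignment == c].mean() if (raw_assignment == c).any() else -np.inf
         for c in range(k)]
    )
    order = np.argsort(-cluster_means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignment = relabel[raw_assignment]
    sizes, rows, members = [], [], []
    for c in range(1, k + 1):
        mask = assignment == c
        sizes.append(int(mask.sum()))
        sub = scores.loc[mask, ["OR", "FP", "dFP"]]
        rows.append(
            {
                "cluster": c,
                "mean_OR": sub["OR"].mean(),
                "sd_OR": sub["OR"].std(ddof=1) if mask.sum() > 1 else 0.0,
                "mean_FP": sub["FP"].mean(),
                "sd_FP": sub["FP"].std(ddof=1) if mask.sum() > 1 else 0.0,
                "mean_dFP": sub["dFP"].mean(),
                "sd_dFP": sub["dFP"].std(ddof=1) if mask.sum() > 1 else 0.0,
            }
        )
        members.append(tuple(scores.loc[mask, "gene"].astype(str)))
    characteristics = pd.DataFrame(rows).set_index("cluster")
    return ClusterSummary(
        k=k,
        sizes=tuple(sizes),
        characteristics=characteristics,
        members=tuple(members),
        silhouette_by_k=silhouette_by_k,
        assignment=assignment,
    )
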