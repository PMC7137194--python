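"""End-to-end orchestration of the two-step detection procedure.

Step 1 builds the quantile-difference space, generates the permutation
null and flags genes whose OR index exceeds the (1 - alpha) null
percentile (the potential DEGs).  Step 2 scores each potential gene
against fold-partitioned retained null cases (FP, dFP), applies the
strong and relaxed selection rules, and clusters the candidates with
PAM.  Given a seed the whole run is deterministic, for any worker
count.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterSummary, strong_relaxed_flags, summarize_clusters
from .neighborhood import assign_folds, expected_fp, fp_dfp
from .permutation import build_null_set, flag_potential, or_scores
from .quantile_space import (
    ExpressionPair,
    MethodConfig,
    quantile_differences,
    scale_columns,
)

__all__ = ["RunResult", "run_pipeline"]

# beyond ~n^2 * workers * 8 bytes of live distance matrices, warn
_MEMORY_BUDGET_BYTES = 4e9

_TABLE_COLUMNS = ["gene", "OR", "FP", "dFP", "strong", "relaxed", "cluster"]


@dataclass
class RunResult:
    """Everything a run produces.

    ``table`` holds one row per potential DEG: gene, OR, FP, dFP,
    strong, relaxed, cluster.  ``expected_fp`` is the uniform-mixing
    false-positive-neighbour reference used by the relaxed rule and
    ``null_proportion_pct`` the corresponding percentage of retained
    null cases among candidates.
    """

    config: MethodConfig
    table: pd.DataFrame
    clusters: ClusterSummary | None
    expected_fp: float
    null_proportion_pct: float
    threshold: float
    provenance: dict = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def run_pipeline(pair: ExpressionPair, config: MethodConfig | None = None) -> RunResult:
    """Run both steps of the method on an expression pair."""
    if config is None:
        config = MethodConfig()
    t0 = time.perf_counter()
    log: list[str] = [
        f"n_genes={pair.n_genes} s1={pair.cond1.shape[1]} s2={pair.cond2.shape[1]}",
        f"seed={config.seed} B={config.n_permutations} alpha={config.alpha}",
    ]
    est_bytes = (pair.n_genes ** 2) * 8 * (config.workers or 1)
    if est_bytes > _MEMORY_BUDGET_BYTES:
        warnings.warn(
            f"~{est_bytes / 1e9:.1f} GB of pairwise distances may be live at once; "
            "consider fewer workers", stacklevel=2)

    V0 = quantile_differences(pair, config)
    V = scale_columns(V0, V0, enabled=config.scale)
    original_or = or_scores(V.values, config.weights)
    null = build_null_set(pair, config, scale_ref=V0)
    log.append(f"null cases={null.n_cases} retained={null.retained.size} "
               f"threshold={null.threshold:.4f}")
    potential = flag_potential(original_or, null.threshold)
    log.append(f"potential DEGs={potential.size}")

    if potential.size == 0:
        warnings.warn("no potential DEGs found", stacklevel=2)
        return RunResult(
            config=config,
            table=pd.DataFrame(columns=_TABLE_COLUMNS),
            clusters=None,
            expected_fp=float("nan"),
            null_proportion_pct=float("nan"),
            threshold=null.threshold,
            provenance=_provenance(config, t0),
            log=log,
        )

    # fold assignment draws from its own stream, independent of the replicates
    fold_seed = np.random.SeedSequence(config.seed).spawn(config.n_permutations + 1)[-1] \
        if config.replicable else np.random.SeedSequence()
    folds = assign_folds(null, config.n_folds, np.random.default_rng(fold_seed))
    scores = fp_dfp(V.values[potential], folds, config.n_neighbours,
                    config.weights, gene_indices=potential)
    expectation, proportion = expected_fp(config.n_neighbours, folds, potential.size)
    log.append(f"expected FP={expectation:.2f} null proportion={proportion:.2f}%")
    mean_fp = np.array([s.mean_fp for s in scores])
    mean_dfp = np.array([s.mean_dfp for s in scores])
    strong, relaxed = strong_relaxed_flags(mean_fp, expectation)

    table = pd.DataFrame(
        {
            "gene": [pair.labels[i] for i in potential],
            "OR": original_or[potential],
            "FP": mean_fp,
            "dFP": mean_dfp,
            "strong": strong,
            "relaxed": relaxed,
        }
    )
    clusters = None
    if potential.size > 3:
        clusters = summarize_clusters(table, k=None, max_clusters=config.max_clusters)
        table["cluster"] = clusters.assignment
        log.append(f"clusters: k={clusters.k} sizes={clusters.sizes}")
    else:
        table["cluster"] = 1
        log.append("too few potential DEGs for cluster selection; single cluster")
    return RunResult(
        config=config,
        table=table,
        clusters=clusters,
        expected_fp=expectation,
        null_proportion_pct=proportion,
        threshold=null.threshold,
        provenance=_provenance(config, t0),
        log=log,
    )


def _provenance(config: MethodConfig, t0: float) -> dict:
    from . import __version__

    return {
        "seed": config.seed,
        "version": __version__,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
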