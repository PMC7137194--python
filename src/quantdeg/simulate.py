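"""Synthetic two-condition expression studies with known ground truth.

The generator reproduces the standard benchmark design for this method:
n genes, of which a chosen number are differentially expressed.  Non-DE
genes draw expression from N(0, 1) in both conditions.  A DE gene g
draws N(0, 1) in condition 1 and N(mu_g, 1) in condition 2, where
|mu_g| = Delta_g controls how important the gene is (the sign of mu_g is
random).  Default design: 1000 genes, 100 DE split over
Delta in {1.5, 2, 3}, 30 samples per condition.

The study table layout is: column 1 DE flag, column 2 Delta, then the
s1 condition-1 and s2 condition-2 expression columns, with gene row
labels — readable/writable as delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantile_space import ExpressionPair

__all__ = ["SimulatedStudy", "simulate_study", "detection_table", "write_study", "read_study"]


@dataclass(frozen=True)
class SimulatedStudy:
    """A simulated expression pair plus per-gene ground truth."""

    pair: ExpressionPair
    de_flag: np.ndarray  # bool per gene
    delta: np.ndarray    # 0 for non-DE genes
    mu: np.ndarray       # signed shift, |mu| = delta
    seed: int

    @property
    def n_de(self) -> int:
        return int(self.de_flag.sum())


def _split_counts(n_de: int, deltas: tuple[float, ...]) -> list[int]:
    # even split; remainder goes to the larger Delta values first
    order = np.argsort(deltas)[::-1]
    counts = [n_de // len(deltas)] * len(deltas)
    for i in range(n_de % len(deltas)):
        counts[order[i]] += 1
    return counts


def simulate_study(
    n_genes: int = 1000,
    n_de: int = 100,
    deltas: tuple[float, ...] = (1.5, 2.0, 3.0),
    s1: int = 30,
    s2: int = 30,
    seed: int = 0,
    delta_counts: dict[float, int] | None = None,
) -> SimulatedStudy:
    """Generate a study with known DE structure.

    ``delta_counts`` optionally fixes how many DE genes get each Delta
    (must sum to ``n_de``); by default DE genes are split as evenly as
    possible across ``deltas``.  DE genes are placed at random rows.
    """
    if not (0 <= n_de <= n_genes):
        raise ValueError("n_de must lie in [0, n_genes]")
    if s1 < 3 or s2 < 3:
        raise ValueError("need at least 3 samples per condition")
    rng = np.random.default_rng(seed)
    deltas = tuple(float(d) for d in deltas)
    if delta_counts is not None:
        if set(delta_counts) - set(deltas):
            raise ValueError("delta_counts keys must be drawn from deltas")
        counts = [int(delta_counts.get(d, 0)) for d in deltas]
        if sum(counts) != n_de:
            raise ValueError("delta_counts must sum to n_de")
    else:
        counts = _split_counts(n_de, deltas)

    delta = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    per_gene_delta = np.repeat(deltas, counts)
    delta[de_idx] = per_gene_delta
    de_flag = delta > 0
    sign = np.where(rng.random(n_genes) < 0.5, -1.0, 1.0)
    mu = delta * sign

    cond1 = rng.standard_normal((n_genes, s1))
    cond2 = rng.standard_normal((n_genes, s2)) + mu[:, None]
    pair = ExpressionPair.from_matrices(cond1, cond2)
    return SimulatedStudy(pair, de_flag, delta, mu, seed)


def write_study(study: SimulatedStudy, path, sep: str = "\t") -> None:
    """Write the study in the flag/Delta/expressions table layout."""
    s1 = study.pair.cond1.shape[1]
    s2 = study.pair.cond2.shape[1]
    frame = pd.DataFrame(
        np.column_stack([study.de_flag.astype(int), study.delta,
                         study.pair.cond1, study.pair.cond2]),
        index=list(study.pair.labels),
        columns=(["DE", "Delta"]
                 + [f"C1.S{i + 1}" for i in range(s1)]
                 + [f"C2.S{i + 1}" for i in range(s2)]),
    )
    frame.to_csv(path, sep=sep)


def read_study(path, s1: int, sep: str = "\t") -> SimulatedStudy:
    """Read a study table written by :func:`write_study`."""
    frame = pd.read_csv(path, sep=sep, index_col=0)
    body = frame.to_numpy(dtype=float)
    de_flag = body[:, 0].astype(bool)
    delta = body[:, 1]
    cond1 = body[:, 2:2 + s1]
    cond2 = body[:, 2 + s1:]
    pair = ExpressionPair(cond1, cond2, tuple(str(i) for i in frame.index))
    return SimulatedStudy(pair, de_flag, delta, delta.copy(), seed=-1)


def detection_table(
    study: SimulatedStudy, scores: pd.DataFrame, selection: str = "relaxed"
) -> dict:
    """Confusion accounting of a detection result against ground truth.

    ``scores`` is the potential-DEG table (columns gene, strong,
    relaxed, cluster).  Returns overall TP/FP/FN for the chosen
    selection plus a per-(Delta, cluster) breakdown of identified genes
    with their strong/relaxed counts.
    """
    if selection not in ("strong", "relaxed"):
        raise ValueError("selection must be 'strong' or 'relaxed'")
    labels = list(study.pair.labels)
    label_to_idx = {g: i for i, g in enumerate(labels)}
    genes = scores["gene"].astype(str)
    if not set(genes).issubset(label_to_idx):
        raise ValueError("score gene ids do not match the study's gene labels")
    sel_mask = scores[selection].to_numpy(dtype=bool)
    selected_idx = np.array([label_to_idx[g] for g in genes[sel_mask]], dtype=int)
    truth = study.de_flag
    tp = int(truth[selected_idx].sum()) if selected_idx.size else 0
    fp = int(selected_idx.size - tp)
    fn = int(truth.sum() - tp)

    strata = []
    clusters = sorted(scores["cluster"].unique()) if len(scores) else []
    delta_levels = sorted({d for d in study.delta if d > 0}, reverse=True) + [0.0]
    for d in delta_levels:
        row = {"delta": d, "n_true": int((study.delta == d).sum()) if d > 0 else None}
        for c in clusters:
            in_c = scores["cluster"].to_numpy() == c
            idx = np.array([label_to_idx[g] for g in genes[sel_mask & in_c]], dtype=int)
            at_d = idx[(study.delta[idx] == d)] if d > 0 else idx[~truth[idx]]
            n_strong = int(scores.loc[sel_mask & in_c, "strong"].to_numpy()[
                np.isin(np.array([label_to_idx[g] for g in genes[sel_mask & in_c]]), at_d)
            ].sum()) if at_d.size else 0
            row[f"cluster{c}"] = {"identified": int(at_d.size), "strong": n_strong,
                                  "relaxed": int(at_d.size)}
        strata.append(row)
    return {"selection": selection, "TP": tp, "FP": fp, "FN": fn, "strata": strata}
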