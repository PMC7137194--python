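"""Reading expression matrices and writing run results."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_expression_matrix", "write_results", "load_results"]

_SEPS = {"tsv": "\t", "csv": ","}


def read_expression_matrix(path, format: str | None = None) -> pd.DataFrame:
    """Read a genes x samples matrix from delimited text.

    The first column is used as gene labels when it is non-numeric;
    otherwise rows are auto-labelled Gene1..Genen.  Any non-numeric or
    missing cell raises with its location.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in _SEPS:
        raise ValueError("format must be 'tsv' or 'csv'")
    raw = pd.read_csv(path, sep=_SEPS[format], header=0, index_col=None)
    if raw.empty:
        raise ValueError(f"{path}: no data rows")
    first = raw.iloc[:, 0]
    labelled = first.dtype == object
    if labelled:
        labels = first.astype(str).tolist()
        body = raw.iloc[:, 1:]
    else:
        labels = [f"Gene{i + 1}" for i in range(len(raw))]
        body = raw
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at row {labels[r]!r}, "
            f"column {body.columns[c]!r}"
        )
    if len(set(labels)) != len(labels):
        dup = pd.Series(labels)
        name = dup[dup.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene label {name!r}")
    numeric.index = pd.Index(labels, name="gene")
    return numeric


def write_results(result, directory) -> dict[str, Path]:
    """Write a run result: genes TSV, summary JSON and a plain-text log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": directory / "potential_degs.tsv",
        "summary": directory / "summary.json",
        "log": directory / "run.log",
    }
    result.table.to_csv(paths["table"], sep="\t", index=False)
    summary = {
        "config": dataclasses.asdict(result.config),
        "threshold": result.threshold,
        "n_potential": int(len(result.table)),
        "expected_fp": result.expected_fp,
        "null_proportion_pct": result.null_proportion_pct,
        "clusters": {
            "k": result.clusters.k if result.clusters else None,
            "sizes": list(result.clusters.sizes) if result.clusters else [],
            "characteristics": (
                result.clusters.characteristics.reset_index().to_dict(orient="records")
                if result.clusters else []
            ),
            "silhouette_by_k": (
                {str(k): v for k, v in result.clusters.silhouette_by_k.items()}
                if result.clusters else {}
            ),
        },
        "provenance": result.provenance,
    }
    paths["summary"].write_text(json.dumps(summary, indent=2, default=float) + "\n")
    paths["log"].write_text("\n".join(result.log) + "\n")
    return paths


def load_results(directory):
    """Re-read the TSV table and JSON summary written by :func:`write_results`."""
    directory = Path(directory)
    table = pd.read_csv(directory / "potential_degs.tsv", sep="\t")
    summary = json.loads((directory / "summary.json").read_text())
    return table, summary
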