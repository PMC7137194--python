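"""Diagnostic scatter of the potential DEGs.

One marker per candidate gene: OR on the vertical axis, mean FP on the
horizontal axis, marker area inversely proportional to mean dFP (big
symbols = low false-positive density = trustworthy), colour by cluster,
triangles for genes accepted by the relaxed selection.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_scores"]

_EPS = 1e-10
_CYCLE = ["tab:red", "tab:blue", "tab:green", "tab:orange", "tab:purple",
          "tab:brown", "tab:pink", "tab:gray", "tab:olive", "tab:cyan"]


def plot_scores(result, path, max_area: float = 220.0) -> None:
    """Write the OR / FP / dFP scatter of a run result to ``path``."""
    table = result.table
    if table.empty:
        raise ValueError("nothing to plot: no potential DEGs")
    inv = 1.0 / (table["dFP"].to_numpy() + _EPS)
    area = 20.0 + (max_area - 20.0) * inv / inv.max()
    fig, ax = plt.subplots(figsize=(7, 5))
    for c in sorted(table["cluster"].unique()):
        colour = _CYCLE[(int(c) - 1) % len(_CYCLE)]
        for marker, relaxed in (("^", True), ("o", False)):
            mask = (table["cluster"] == c) & (table["relaxed"] == relaxed)
            if not mask.any():
                continue
            ax.scatter(
                table.loc[mask, "FP"], table.loc[mask, "OR"],
                s=area[mask.to_numpy()], marker=marker, alpha=0.7,
                color=colour, edgecolor="black", linewidth=0.3,
                label=f"cluster {c}" + (" (relaxed DEG)" if relaxed else ""),
            )
    ax.set_xlabel("mean FP (false-positive neighbours)")
    ax.set_ylabel("OR (outlier index)")
    ax.set_title("Potential DEGs: OR vs FP, symbol size ~ 1/dFP")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
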