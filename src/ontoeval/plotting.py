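"""Precision-recall and remaining-uncertainty / misinformation curves.

Curves are built from the written evaluation TSV (not in-memory objects),
mirroring the table -> plotting decoupling of the pipeline: every plotted
point appears verbatim as a table row, drawn in threshold order with no
monotonic interpolation.  One figure per namespace per curve kind; the
best-score point (Fmax or Smin) of each method is marked and shown in the
legend.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["Curve", "build_curves", "render"]

_KINDS = {
    "pr": (("rc", "pr"), "recall", "precision", "f", False),
    "rumi": (("ru", "mi"), "remaining uncertainty", "misinformation", "s", True),
}


@dataclass
class Curve:
    """Ordered (x, y) points for one (method, namespace), with best point."""

    filename: str
    label: str
    namespace: str
    x: list[float]
    y: list[float]
    best_x: float
    best_y: float
    best_value: float


def build_curves(
    table: pd.DataFrame,
    best: pd.DataFrame,
    kind: str = "pr",
    team_map: dict[str, tuple[str, str]] | None = None,
) -> list[Curve]:
    """Reshape the evaluation table into one curve per retained method.

    ``best`` is the (already team-deduplicated) best-score table for the
    matching metric; only files present there are plotted.  Missing metric
    columns raise a ``KeyError`` naming the column.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown curve kind {kind!r}; expected one of {sorted(_KINDS)}")
    (xcol, ycol), _, _, metric, _ = _KINDS[kind]
    for col in (xcol, ycol, metric):
        if col not in table.columns:
            raise KeyError(f"evaluation table lacks required column {col!r}")
    tm = team_map or {}
    curves: list[Curve] = []
    for _, brow in best.sort_values(["ns", "filename"]).iterrows():
        sub = table[(table["filename"] == brow["filename"])
                    & (table["ns"] == brow["ns"])].sort_values("tau")
        if sub.empty:
            continue
        label = brow.get("label") or tm.get(brow["filename"],
                                            (None, brow["filename"]))[1]
        curves.append(Curve(
            filename=brow["filename"], label=str(label), namespace=brow["ns"],
            x=sub[xcol].tolist(), y=sub[ycol].tolist(),
            best_x=float(brow[xcol]), best_y=float(brow[ycol]),
            best_value=float(brow[metric]),
        ))
    return curves


def render(curves: list[Curve], kind: str, out_dir: str | Path,
           fmt: str = "png") -> list[Path]:
    """Write one figure per namespace; returns the created file paths."""
    _, xlabel, ylabel, metric, minimize = _KINDS[kind]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    namespaces = sorted({c.namespace for c in curves})
    for ns in namespaces:
        fig, ax = plt.subplots(figsize=(6, 5))
        for c in (c for c in curves if c.namespace == ns):
            tag = f"{metric.upper()}min" if minimize else f"{metric.upper()}max"
            line, = ax.plot(c.x, c.y, label=f"{c.label} ({tag}={c.best_value:.3f})")
            ax.plot([c.best_x], [c.best_y], "o", color=line.get_color())
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.set_title(ns)
        ax.legend(fontsize=8)
        path = out / f"{kind}_{ns}.{fmt}"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
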