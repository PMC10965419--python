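"""End-to-end evaluation runs over a directory of prediction files.

Each prediction file (one per method) is parsed, propagated and swept over
the threshold grid against the shared ontology and ground truth; files are
processed one at a time so only one score matrix is resident.  Outputs are
a long evaluation table (one row per file, namespace and threshold) and
best-score tables for Fmax, Smin and weighted Fmax, optionally deduplicated
to one prediction per team and namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import parse_ground_truth, parse_predictions
from .metrics import (best_scores, default_tau_grid, records_to_frame,
                      sweep_thresholds)
from .ontology import ParseOptions, load_ia, parse_obo
from .propagation import propagate_scores, propagate_truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "EvaluationRun", "run_evaluation", "dedupe_teams",
           "load_team_map"]

EXIT_OK, EXIT_FATAL, EXIT_PARTIAL = 0, 1, 2


@dataclass
class RunConfig:
    """Configuration of one evaluation run (mirrors the CLI flags)."""

    obo_path: str | Path
    pred_dir: str | Path
    gt_path: str | Path
    ia_path: str | Path | None = None
    team_map_path: str | Path | None = None
    out_dir: str | Path = "results"
    n_thresholds: int = 100
    thresholds: list[float] | None = None
    averaging: str = "macro"
    norm: str = "cafa"
    prop_mode: str = "fill"
    exclude_roots: bool = False
    max_terms: int | None = None
    n_blocks: int = 1
    include_part_of: bool = False
    overwrite: bool = False
    log_level: str = "INFO"


@dataclass
class EvaluationRun:
    """Result bundle: the long table, per-metric best tables, exit code."""

    table: pd.DataFrame
    best: dict[str, pd.DataFrame] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return EXIT_PARTIAL if self.skipped else EXIT_OK


def load_team_map(text: str) -> dict[str, tuple[str, str]]:
    """Parse filename TAB team TAB display-name; duplicate filenames are fatal."""
    mapping: dict[str, tuple[str, str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"team map: expected 3 columns, got {line!r}")
        fname, team, display = (p.strip() for p in parts[:3])
        if fname in mapping:
            raise ValueError(f"team map: duplicate filename {fname!r}")
        mapping[fname] = (team, display)
    return mapping


def dedupe_teams(
    best_rows: pd.DataFrame,
    team_map: dict[str, tuple[str, str]] | None,
    metric: str,
    minimize: bool = False,
) -> pd.DataFrame:
    """Keep, per (team, namespace), the file with the best ranking metric.

    Unmapped files form singleton teams (their own filename); display names
    are substituted when a mapping provides one.  ``metric`` names the
    column ranked, maximized unless ``minimize``.
    """
    if best_rows.empty:
        return best_rows
    rows = best_rows.copy()
    tm = team_map or {}
    rows["team"] = [tm.get(f, (f, f))[0] for f in rows["filename"]]
    rows["label"] = [tm.get(f, (f, f))[1] for f in rows["filename"]]
    idx = (rows.groupby(["team", "ns"], sort=True)[metric]
           .idxmin() if minimize else
           rows.groupby(["team", "ns"], sort=True)[metric].idxmax())
    return rows.loc[sorted(idx)].reset_index(drop=True)


def run_evaluation(cfg: RunConfig) -> EvaluationRun:
    """Run the full evaluation described by ``cfg`` and write outputs.

    Raises on fatal input problems (missing paths, unparseable ontology or
    ground truth, no valid prediction files); an unreadable prediction file
    is skipped with an error logged and the run continues.
    """
    logging.basicConfig(level=cfg.log_level,
                        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
    obo_path, gt_path = Path(cfg.obo_path), Path(cfg.gt_path)
    pred_dir, out_dir = Path(cfg.pred_dir), Path(cfg.out_dir)
    for p in (obo_path, gt_path, pred_dir):
        if not p.exists():
            raise FileNotFoundError(p)
    out_dir.mkdir(parents=True, exist_ok=True)
    eval_path = out_dir / "evaluation.tsv"
    if eval_path.exists() and not cfg.overwrite:
        raise FileExistsError(f"{eval_path} exists; pass overwrite to replace")

    graphs = parse_obo(obo_path.read_text(),
                       ParseOptions(include_part_of=cfg.include_part_of))
    gt = parse_ground_truth(gt_path.read_text(), graphs)
    gt = {ns: propagate_truth(m, graphs[ns]) for ns, m in gt.items()}
    weights = None
    if cfg.ia_path is not None:
        ia_text = Path(cfg.ia_path).read_text()
        weights = {ns: load_ia(ia_text, g) for ns, g in graphs.items()}

    if cfg.thresholds is not None:
        taus = np.asarray(sorted(cfg.thresholds), dtype=np.float64)
    else:
        taus = default_tau_grid(cfg.n_thresholds)

    pred_files = sorted(p for p in pred_dir.iterdir() if p.is_file())
    if not pred_files:
        raise FileNotFoundError(f"no prediction files in {pred_dir}")

    frames: list[pd.DataFrame] = []
    best_acc: dict[str, list[dict]] = {"f": [], "s": [], "wf": []}
    skipped: list[str] = []
    for path in pred_files:
        try:
            text = path.read_text()
        except OSError as exc:
            logger.error("skipping unreadable prediction file %s: %s", path, exc)
            skipped.append(path.name)
            continue
        preds = parse_predictions(text, graphs, gt, max_terms=cfg.max_terms)
        for ns in sorted(graphs):
            graph = graphs[ns]
            if gt[ns].n_targets == 0:
                continue
            pred = propagate_scores(preds[ns], graph, mode=cfg.prop_mode)
            records = sweep_thresholds(
                gt[ns], pred, graph,
                weights=None if weights is None else weights[ns],
                taus=taus, averaging=cfg.averaging, norm=cfg.norm,
                exclude_roots=cfg.exclude_roots, n_blocks=cfg.n_blocks,
            )
            frames.append(records_to_frame(records, filename=path.name))
            for key, rec in best_scores(records).items():
                row = {"filename": path.name, "ns": ns, "tau": rec.tau,
                       "cov": rec.coverage, "pr": rec.pr, "rc": rec.rc,
                       "f": rec.f}
                if rec.s is not None:
                    row.update(wpr=rec.wpr, wrc=rec.wrc, wf=rec.wf,
                               ru=rec.ru, mi=rec.mi, s=rec.s)
                best_acc[key].append(row)
        logger.info("evaluated %s", path.name)
    if len(skipped) == len(pred_files):
        raise RuntimeError("no valid prediction files could be processed")

    table = pd.concat(frames, ignore_index=True)
    team_map = None
    if cfg.team_map_path is not None:
        team_map = load_team_map(Path(cfg.team_map_path).read_text())

    best: dict[str, pd.DataFrame] = {}
    for key, metric, minimize in (("f", "f", False), ("s", "s", True),
                                  ("wf", "wf", False)):
        if not best_acc[key]:
            continue
        df = pd.DataFrame(best_acc[key])
        best[key] = dedupe_teams(df, team_map, metric, minimize=minimize)

    float_fmt = "%.6g"
    table.to_csv(eval_path, sep="\t", index=False, float_format=float_fmt)
    for key, df in best.items():
        df.to_csv(out_dir / f"best_{key}.tsv", sep="\t", index=False,
                  float_format=float_fmt)
    logger.info("wrote %d evaluation rows for %d file(s) to %s",
                len(table), len(pred_files) - len(skipped), out_dir)
    return EvaluationRun(table=table, best=best, skipped=skipped)
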