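"""Threshold-swept evaluation metrics for hierarchical multi-label predictions.

For every score threshold tau, each target's predicted term set
``P = {terms scored >= tau}`` is compared with its true (propagated) set
``T``, giving a per-target confusion summary (tp, fp, fn) — plain counts,
or sums of per-term information-accretion (IA) weights when an IA file is
supplied.  From these the module derives:

* precision / recall / F-measure, macro- or micro-averaged, with the CAFA
  normalization (precision over predicted targets, recall over all
  ground-truth targets) or the "full" normalization (both over all targets);
* IA-weighted precision / recall / F-measure;
* remaining uncertainty (ru, IA mass of false negatives) and misinformation
  (mi, IA mass of false positives), averaged over all ground-truth targets,
  and the semantic distance s = sqrt(ru^2 + mi^2).

Fmax is the maximum of F over the threshold grid and Smin the minimum of s;
the default grid is 100 evenly spaced cutoffs in [0, 1).
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationMatrix, ScoreMatrix
from .ontology import OntologyGraph

__all__ = [
    "MetricRecord",
    "ThresholdConfusion",
    "default_tau_grid",
    "confusion_per_target",
    "pr_rc_f",
    "ru_mi_s",
    "aggregate",
    "sweep_thresholds",
    "best_scores",
    "records_to_frame",
]

AVERAGING_MODES = ("macro", "micro")
NORM_MODES = ("cafa", "full")


def default_tau_grid(n: int = 100) -> np.ndarray:
    """``n`` evenly spaced cutoffs in [0, 1): 0, 1/n, ..., (n-1)/n."""
    if n < 1:
        raise ValueError("threshold grid must contain at least one cutoff")
    return np.arange(n, dtype=np.float64) / n


@dataclass(frozen=True)
class MetricRecord:
    """All metrics for one (namespace, threshold) pair.

    Weighted fields (wpr, wrc, wf, ru, mi, s) are None unless IA weights
    were supplied.
    """

    namespace: str
    tau: float
    n_targets: int
    coverage: float
    pr: float
    rc: float
    f: float
    wpr: float | None = None
    wrc: float | None = None
    wf: float | None = None
    ru: float | None = None
    mi: float | None = None
    s: float | None = None


@dataclass
class ThresholdConfusion:
    """Per-target confusion summaries at one threshold.

    tp + fn is constant over thresholds for a fixed target (it equals the
    target's truth size, or truth IA mass in the weighted arrays).
    """

    namespace: str
    tau: float
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    predicted_flag: np.ndarray
    wtp: np.ndarray | None = None
    wfp: np.ndarray | None = None
    wfn: np.ndarray | None = None

    @property
    def n_targets(self) -> int:
        return len(self.tp)


def confusion_per_target(
    truth_row: np.ndarray,
    score_row: np.ndarray,
    tau: float,
    weights: np.ndarray | None = None,
    exclude_roots: bool = False,
    roots: frozenset[int] | set[int] = frozenset(),
    strict: bool = False,
) -> tuple[float, float, float, bool]:
    """Confusion summary (tp, fp, fn, predicted_flag) for one target.

    The predicted set is {terms with score >= tau and score > 0} (strictly
    greater than tau when ``strict``).  With ``exclude_roots`` the root
    terms are removed from both the predicted and the true set before
    counting, so a root-only prediction leaves the target unpredicted.
    With ``weights`` the three outputs are IA-weight sums instead of counts.
    """
    predicted = (score_row > tau) if strict else (score_row >= tau)
    predicted = predicted & (score_row > 0)
    true = truth_row.astype(bool).copy()
    if exclude_roots and roots:
        idx = np.fromiter(roots, dtype=np.intp)
        predicted = predicted.copy()
        predicted[idx] = False
        true[idx] = False
    w = np.ones(len(score_row)) if weights is None else weights
    tp = float(w[predicted & true].sum())
    fp = float(w[predicted & ~true].sum())
    fn = float(w[~predicted & true].sum())
    return tp, fp, fn, bool(predicted.any())


def pr_rc_f(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean, with 0/0 defined as 0."""
    pr = tp / (tp + fp) if tp + fp > 0 else 0.0
    rc = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
    return pr, rc, f


def ru_mi_s(fn_ia: float, fp_ia: float) -> tuple[float, float, float]:
    """Remaining uncertainty, misinformation and semantic distance.

    ru is the IA mass of the false negatives, mi the IA mass of the false
    positives, and s their Euclidean norm.
    """
    return fn_ia, fp_ia, math.hypot(fn_ia, fp_ia)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return out


def aggregate(conf: ThresholdConfusion, averaging: str = "macro", norm: str = "cafa") -> MetricRecord:
    """Collapse per-target confusions at one threshold into a MetricRecord.

    macro: per-target precision/recall are computed first and then averaged
    — precision over the targets with at least one prediction (norm="cafa",
    the CAFA convention) or over all ground-truth targets (norm="full");
    recall always over all ground-truth targets.  micro: the per-target
    (tp, fp, fn) are summed first and the ratios computed once, which makes
    the norm choice irrelevant.  ru and mi are averaged over all
    ground-truth targets.
    """
    if averaging not in AVERAGING_MODES:
        raise ValueError(f"unknown averaging {averaging!r}")
    if norm not in NORM_MODES:
        raise ValueError(f"unknown norm {norm!r}")
    n = conf.n_targets
    if n < 1:
        raise ValueError("aggregate requires at least one ground-truth target")
    flags = conf.predicted_flag
    coverage = float(flags.mean())

    def _avg(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> tuple[float, float, float]:
        if averaging == "micro":
            return pr_rc_f(float(tp.sum()), float(fp.sum()), float(fn.sum()))
        pr_t = _safe_ratio(tp, tp + fp)
        rc_t = _safe_ratio(tp, tp + fn)
        if norm == "cafa":
            pr = float(pr_t[flags].mean()) if flags.any() else 0.0
        else:
            pr = float(pr_t.mean())
        rc = float(rc_t.mean())
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        return pr, rc, f

    pr, rc, f = _avg(conf.tp, conf.fp, conf.fn)
    wpr = wrc = wf = ru = mi = s = None
    if conf.wtp is not None:
        wpr, wrc, wf = _avg(conf.wtp, conf.wfp, conf.wfn)
        ru, mi, s = ru_mi_s(float(conf.wfn.sum()) / n, float(conf.wfp.sum()) / n)
    return MetricRecord(
        namespace=conf.namespace, tau=float(conf.tau), n_targets=n,
        coverage=coverage, pr=pr, rc=rc, f=f,
        wpr=wpr, wrc=wrc, wf=wf, ru=ru, mi=mi, s=s,
    )


def _confusions_block(
    truth: np.ndarray,
    scores: np.ndarray,
    taus: np.ndarray,
    namespace: str,
    weights: np.ndarray | None,
    root_mask: np.ndarray | None,
    strict: bool,
) -> list[ThresholdConfusion]:
    """Vectorized per-target confusions for a block of thresholds."""
    t = truth.copy()
    if root_mask is not None:
        t &= ~root_mask
    tf = t.astype(np.float64)
    out = []
    for tau in taus:
        p = (scores > tau) if strict else (scores >= tau)
        p &= scores > 0
        if root_mask is not None:
            p &= ~root_mask
        pf = p.astype(np.float64)
        inter = pf * tf
        conf = ThresholdConfusion(
            namespace=namespace, tau=float(tau),
            tp=inter.sum(axis=1),
            fp=(pf - inter).sum(axis=1),
            fn=(tf - inter).sum(axis=1),
            predicted_flag=p.any(axis=1),
        )
        if weights is not None:
            conf.wtp = inter @ weights
            conf.wfp = (pf - inter) @ weights
            conf.wfn = (tf - inter) @ weights
        out.append(conf)
    return out


def sweep_thresholds(
    gt: AnnotationMatrix,
    pred: ScoreMatrix,
    graph: OntologyGraph,
    weights: np.ndarray | None = None,
    taus: np.ndarray | None = None,
    averaging: str = "macro",
    norm: str = "cafa",
    exclude_roots: bool = False,
    strict: bool = False,
    n_blocks: int = 1,
) -> list[MetricRecord]:
    """One MetricRecord per threshold for a (propagated) prediction matrix.

    Targets in the ground truth but absent from the prediction matrix count
    as unpredicted at every threshold.  The grid may be split into
    ``n_blocks`` independently evaluated blocks (computed concurrently);
    the result is identical to sequential evaluation.
    """
    taus = default_tau_grid() if taus is None else np.asarray(taus, dtype=np.float64)
    if taus.size == 0:
        raise ValueError("empty threshold grid")

    # Expand the (possibly smaller) score matrix onto the ground-truth rows.
    n, m = gt.truth.shape
    scores = np.zeros((n, m), dtype=np.float64)
    if pred.n_targets:
        pos = {t: i for i, t in enumerate(gt.targets)}
        rows = np.fromiter((pos[t] for t in pred.targets), dtype=np.intp)
        scores[rows] = pred.scores

    root_mask = None
    if exclude_roots and graph.roots:
        root_mask = np.zeros(m, dtype=bool)
        root_mask[np.fromiter(graph.roots, dtype=np.intp)] = True

    blocks = np.array_split(taus, max(1, min(n_blocks, taus.size)))

    def work(block: np.ndarray) -> list[ThresholdConfusion]:
        return _confusions_block(gt.truth, scores, block, gt.namespace,
                                 weights, root_mask, strict)

    if len(blocks) > 1:
        with ThreadPoolExecutor(max_workers=len(blocks)) as pool:
            per_block = list(pool.map(work, blocks))
    else:
        per_block = [work(b) for b in blocks]

    return [aggregate(conf, averaging=averaging, norm=norm)
            for block in per_block for conf in block]


def best_scores(records: list[MetricRecord]) -> dict[str, MetricRecord]:
    """Best rows over the threshold grid for one (prediction, namespace).

    Returns Fmax (max f), and — when IA metrics are present — Smin (min s)
    and weighted Fmax (max wf).  Ties are broken by the lowest threshold;
    records are assumed ordered by tau.
    """
    if not records:
        raise ValueError("best_scores requires at least one record")
    ordered = sorted(records, key=lambda r: r.tau)
    best: dict[str, MetricRecord] = {"f": max(ordered, key=lambda r: r.f)}
    if ordered[0].s is not None:
        best["s"] = min(ordered, key=lambda r: r.s)
        best["wf"] = max(ordered, key=lambda r: r.wf)
    return best


def records_to_frame(records: list[MetricRecord], filename: str | None = None) -> pd.DataFrame:
    """Evaluation table: one row per record, weighted columns only with IA."""
    rows = []
    for r in records:
        row = {
            "ns": r.namespace, "tau": r.tau, "cov": r.coverage,
            "pr": r.pr, "rc": r.rc, "f": r.f, "n": r.n_targets,
        }
        if r.s is not None:
            row.update(wpr=r.wpr, wrc=r.wrc, wf=r.wf, ru=r.ru, mi=r.mi, s=r.s)
        if filename is not None:
            row = {"filename": filename, **row}
        rows.append(row)
    return pd.DataFrame(rows)
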