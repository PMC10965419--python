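"""Ground-truth and prediction parsing into per-namespace matrices.

The ground truth becomes a Boolean n x m matrix (targets x terms) per
namespace; each prediction file becomes a real-valued n' x m matrix of
scores in (0, 1], where a structural zero means "not predicted" and
n' <= n because prediction targets are filtered to those present in the
ground truth.  Columns align exactly with the ontology's dense term index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = ["AnnotationMatrix", "ScoreMatrix", "parse_ground_truth", "parse_predictions"]


@dataclass
class AnnotationMatrix:
    """Boolean targets x terms ground-truth matrix for one namespace."""

    namespace: str
    targets: list[str]
    truth: np.ndarray  # bool, shape (n, m)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class ScoreMatrix:
    """Real-valued targets x terms prediction-score matrix for one namespace.

    ``targets`` is a subset of the ground-truth targets in inherited order;
    scores lie in (0, 1] and 0 encodes absence.
    """

    namespace: str
    targets: list[str]
    scores: np.ndarray  # float64, shape (n', m)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


class GroundTruthError(ValueError):
    """No usable ground-truth rows."""


def parse_ground_truth(
    gt_text: str, graphs: dict[str, OntologyGraph]
) -> dict[str, AnnotationMatrix]:
    """Parse a headerless 2-column TSV ``target TAB term`` into matrices.

    Rows referencing terms absent from every namespace are dropped (count
    logged); duplicate pairs collapse to one; a target appears in a
    namespace's matrix only if it has at least one annotation there.
    Zero usable rows overall is fatal.
    """
    pairs: dict[str, set[tuple[str, int]]] = {ns: set() for ns in graphs}
    dropped = 0
    for line in gt_text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            dropped += 1
            continue
        target, term = parts[0].strip(), parts[1].strip()
        hit = False
        for ns, graph in graphs.items():
            idx = graph.index.get(term)
            if idx is not None:
                pairs[ns].add((target, idx))
                hit = True
                break
        if not hit:
            dropped += 1
    if dropped:
        logger.warning("ground truth: dropped %d rows with unknown terms", dropped)
    if not any(pairs.values()):
        raise GroundTruthError("ground truth contains no rows matching the ontology")

    matrices: dict[str, AnnotationMatrix] = {}
    for ns, graph in graphs.items():
        targets = sorted({t for t, _ in pairs[ns]})
        pos = {t: i for i, t in enumerate(targets)}
        truth = np.zeros((len(targets), graph.n_terms), dtype=bool)
        for t, j in pairs[ns]:
            truth[pos[t], j] = True
        matrices[ns] = AnnotationMatrix(namespace=ns, targets=targets, truth=truth)
        logger.info("ground truth %s: %d targets, %d annotations",
                    ns, len(targets), int(truth.sum()))
    return matrices


def parse_predictions(
    pred_text: str,
    graphs: dict[str, OntologyGraph],
    gt: dict[str, AnnotationMatrix],
    max_terms: int | None = None,
) -> dict[str, ScoreMatrix]:
    """Parse a headerless 3-column TSV ``target TAB term TAB score``.

    Rows with targets absent from the ground truth or terms absent from the
    ontology are dropped (counts logged); duplicate (target, term) pairs keep
    the maximum score; scores above 1 are clamped to 1 with a warning and
    scores <= 0 are dropped.  When ``max_terms`` is set, only the
    ``max_terms`` highest-scoring terms per target per namespace are kept,
    breaking ties at the cut by lower term index.  Lines that do not parse as
    three columns with a numeric score are skipped with a warning (this
    tolerates CAFA-style AUTHOR/MODEL/END headers).  An empty result is not
    an error: the file is scored as an empty prediction.
    """
    gt_pos = {ns: {t: i for i, t in enumerate(m.targets)} for ns, m in gt.items()}
    kept: dict[str, dict[tuple[int, int], float]] = {ns: {} for ns in graphs}
    dropped_target = dropped_term = dropped_bad = clamped = 0
    for line in pred_text.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            dropped_bad += 1
            continue
        target, term = parts[0].strip(), parts[1].strip()
        try:
            score = float(parts[2])
        except ValueError:
            dropped_bad += 1
            continue
        ns = idx = None
        for cand_ns, graph in graphs.items():
            j = graph.index.get(term)
            if j is not None:
                ns, idx = cand_ns, j
                break
        if ns is None:
            dropped_term += 1
            continue
        row = gt_pos[ns].get(target)
        if row is None:
            dropped_target += 1
            continue
        if score > 1.0:
            clamped += 1
            score = 1.0
        if score <= 0.0:
            continue
        key = (row, idx)
        prev = kept[ns].get(key)
        if prev is None or score > prev:
            kept[ns][key] = score
    if dropped_target or dropped_term or dropped_bad or clamped:
        logger.warning(
            "predictions: dropped %d unknown-target, %d unknown-term, "
            "%d malformed rows; clamped %d scores > 1",
            dropped_target, dropped_term, dropped_bad, clamped,
        )

    matrices: dict[str, ScoreMatrix] = {}
    for ns, graph in graphs.items():
        rows_used = sorted({r for r, _ in kept[ns]})
        remap = {r: i for i, r in enumerate(rows_used)}
        scores = np.zeros((len(rows_used), graph.n_terms), dtype=np.float64)
        for (r, j), s in kept[ns].items():
            scores[remap[r], j] = s
        if max_terms is not None:
            _cap_terms(scores, max_terms)
        targets = [gt[ns].targets[r] for r in rows_used]
        matrices[ns] = ScoreMatrix(namespace=ns, targets=targets, scores=scores)
        logger.info("predictions %s: %d targets, %d scored terms",
                    ns, len(targets), int((scores > 0).sum()))
    return matrices


def _cap_terms(scores: np.ndarray, max_terms: int) -> None:
    """Keep only the ``max_terms`` best-scoring terms per row, in place.

    Ordering is by descending score then ascending term index, so the cut is
    deterministic.
    """
    if max_terms <= 0:
        raise ValueError("max_terms must be a positive integer")
    m = scores.shape[1]
    for row in scores:
        nz = np.flatnonzero(row)
        if len(nz) <= max_terms:
            continue
        # lexsort: last key is primary -> sort by -score, ties by index.
        order = nz[np.lexsort((nz, -row[nz]))]
        row[order[max_terms:]] = 0.0
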