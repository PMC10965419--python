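"""Upward propagation of annotations and scores along the ontology DAG.

Both the ground truth and the prediction scores are extended from annotated
terms to all of their ancestors up to the namespace root(s).  Because the
graph is topologically sorted at parse time (children before parents), each
propagation is a single linear pass over the order.

Two score-propagation modes exist:

``fill`` (default, CAFA behaviour)
    A parent's own score is never overwritten.  An *unscored* parent
    receives the maximum over its children's final values, so fills cascade
    to the root; the value cascading through an already-scored parent is
    that parent's own kept score.
``max``
    A parent receives the maximum of its own score and its children's final
    values, which makes the score function monotone non-decreasing from
    leaf to root (every thresholded prediction is a consistent subgraph).
"""

from __future__ import annotations

import numpy as np

from .annotations import AnnotationMatrix, ScoreMatrix
from .ontology import OntologyGraph

__all__ = ["propagate_truth", "propagate_scores", "PROPAGATION_MODES"]

PROPAGATION_MODES = ("fill", "max")


def propagate_truth(gt: AnnotationMatrix, graph: OntologyGraph) -> AnnotationMatrix:
    """Close each target's annotation set under the ancestor relation.

    After propagation a cell (t, term) is true iff *term* is an
    ancestor-or-self of a directly annotated term of *t*.  Idempotent.
    """
    truth = gt.truth.copy()
    for i in graph.topo_order:
        col = truth[:, i]
        for p in graph.parents[i]:
            truth[:, p] |= col
    return AnnotationMatrix(namespace=gt.namespace, targets=gt.targets, truth=truth)


def propagate_scores(pred: ScoreMatrix, graph: OntologyGraph, mode: str = "fill") -> ScoreMatrix:
    """Propagate prediction scores to the root(s) in ``fill`` or ``max`` mode.

    Idempotent in both modes; in ``max`` mode the output satisfies
    score(parent) >= score(child) on every edge.
    """
    if mode not in PROPAGATION_MODES:
        raise ValueError(f"unknown propagation mode {mode!r}; expected one of {PROPAGATION_MODES}")
    scores = pred.scores.copy()
    if mode == "max":
        for i in graph.topo_order:
            col = scores[:, i]
            for p in graph.parents[i]:
                np.maximum(scores[:, p], col, out=scores[:, p])
    else:
        # cand[:, p] accumulates the max final value over p's children; a
        # term's final value is its own score when scored, else its fill.
        cand = np.zeros_like(scores)
        for i in graph.topo_order:
            unscored = scores[:, i] == 0.0
            scores[unscored, i] = cand[unscored, i]
            col = scores[:, i]
            for p in graph.parents[i]:
                np.maximum(cand[:, p], col, out=cand[:, p])
    return ScoreMatrix(namespace=pred.namespace, targets=pred.targets, scores=scores)
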