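"""Synthetic ontologies, ground truths and predictions for testing.

The generator emulates the structural properties the evaluator consumes —
a per-namespace DAG, leaf-biased annotation sets, and predictors whose
score distribution depends on a quality knob — not the topology of any
real ontology.  Everything is deterministic given the seed: identical
spec + seed yields byte-identical files.

``quality`` is the probability that a term of the (propagated) truth is
predicted; true terms score near 1 (pushed down by ``noise``), while false
positives appear at a noise-dependent rate with scores in a low band.  At
``quality=1, noise=0`` the prediction reproduces the propagated truth
exactly with score 1, so a perfect evaluator must report Fmax = 1 and
Smin = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .ontology import OntologyGraph, parse_obo
from .oracle import oracle_evaluate  # re-exported reference evaluator

__all__ = [
    "FixtureSpec",
    "gen_ontology",
    "gen_truth_and_predictions",
    "write_fixture",
    "oracle_evaluate",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark instance."""

    n_terms: int = 50
    n_namespaces: int = 2
    edge_prob: float = 0.15
    n_targets: int = 25
    annotations_per_target: int = 3
    quality: float = 0.8
    noise: float = 0.3
    seed: int = 42

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        return cls(**json.loads(text))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _term_id(k: int) -> str:
    return f"FX:{k:07d}"


def gen_ontology(spec: FixtureSpec) -> str:
    """Emit a valid acyclic OBO document per the spec.

    Terms are split round-robin-free across namespaces; within a namespace
    every non-root term takes one mandatory parent among earlier terms
    (acyclic by construction) plus extra parents with probability
    ``edge_prob`` each.
    """
    if spec.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n_ns = max(1, min(spec.n_namespaces, spec.n_terms))
    sizes = [spec.n_terms // n_ns + (1 if i < spec.n_terms % n_ns else 0)
             for i in range(n_ns)]
    stanzas = ["format-version: 1.2", "ontology: fixture"]
    k = 0
    for ns_i, size in enumerate(sizes):
        ns = f"ns{ns_i + 1}"
        base = k
        for i in range(size):
            tid = _term_id(k)
            lines = [f"[Term]", f"id: {tid}", f"name: term {k}", f"namespace: {ns}"]
            if i > 0:
                mandatory = int(rng.integers(0, i))
                parents = {mandatory}
                extra = np.flatnonzero(rng.random(i) < spec.edge_prob)
                parents.update(int(j) for j in extra)
                for j in sorted(parents):
                    lines.append(f"is_a: {_term_id(base + j)} ! term {base + j}")
            stanzas.append("\n".join(lines))
            k += 1
    return "\n\n".join(stanzas) + "\n"


def _closure(graph: OntologyGraph, idx: int) -> set[int]:
    out = {idx}
    frontier = [idx]
    while frontier:
        t = frontier.pop()
        for p in graph.parents[t]:
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def gen_truth_and_predictions(
    spec: FixtureSpec, graphs: dict[str, OntologyGraph]
) -> tuple[str, str]:
    """Generate (ground-truth TSV, prediction TSV) over the given graphs.

    Truth draws leaf-biased term sets; predictions score the propagated
    truth terms high with probability ``quality`` and sprinkle low-scoring
    false positives at a rate proportional to ``noise``.
    """
    # Separate RNG streams so the truth is invariant to the quality/noise
    # knobs and prediction files at different qualities share one truth.
    rng_truth = np.random.default_rng(spec.seed + 1)
    rng_pred = np.random.default_rng(spec.seed + 2)
    ns_order = sorted(graphs)
    leaves_of = {
        ns: [i for i in range(g.n_terms)
             if not any(i in g.parents[c] for c in range(g.n_terms))]
        for ns, g in graphs.items()
    }

    gt_rows: list[str] = []
    per_target: list[tuple[str, OntologyGraph, set[int]]] = []
    for t in range(spec.n_targets):
        target = f"target_{t:04d}"
        graph = graphs[ns_order[t % len(ns_order)]]
        leaves = leaves_of[graph.namespace]
        pool = [i for i in range(graph.n_terms) if i not in graph.roots] \
            or list(range(graph.n_terms))
        annotated: set[int] = set()
        for _ in range(spec.annotations_per_target):
            if leaves and rng_truth.random() < 0.7:
                annotated.add(int(rng_truth.choice(leaves)))
            else:
                annotated.add(int(rng_truth.choice(pool)))
        for i in sorted(annotated):
            gt_rows.append(f"{target}\t{graph.ids[i]}")
        closed = set().union(*(_closure(graph, i) for i in annotated))
        per_target.append((target, graph, closed))

    pred_rows: list[str] = []
    for target, graph, closed in per_target:
        for i in sorted(closed):
            if rng_pred.random() < spec.quality:
                score = 1.0 if spec.noise == 0 else max(
                    0.01, 1.0 - spec.noise * float(rng_pred.random()))
                pred_rows.append(f"{target}\t{graph.ids[i]}\t{score:.6f}")
        if spec.noise > 0:
            for i in sorted(set(range(graph.n_terms)) - closed):
                if rng_pred.random() < 0.1 * spec.noise:
                    score = 0.01 + 0.49 * float(rng_pred.random())
                    pred_rows.append(f"{target}\t{graph.ids[i]}\t{score:.6f}")
    return "\n".join(gt_rows) + "\n", "\n".join(pred_rows) + "\n"


def write_fixture(
    spec: FixtureSpec, out_dir: str | Path, qualities: list[float] | None = None
) -> Path:
    """Write ontology.obo, gt.tsv and pred/*.tsv under ``out_dir``.

    With ``qualities`` set, one prediction file per quality level is
    written (sharing the ontology and ground truth); otherwise a single
    file at ``spec.quality``.
    """
    out = Path(out_dir)
    (out / "pred").mkdir(parents=True, exist_ok=True)
    obo = gen_ontology(spec)
    (out / "ontology.obo").write_text(obo)
    graphs = parse_obo(obo)
    gt_written = False
    for q in qualities if qualities is not None else [spec.quality]:
        qspec = FixtureSpec(**{**asdict(spec), "quality": q})
        gt_text, pred_text = gen_truth_and_predictions(qspec, graphs)
        if not gt_written:
            (out / "gt.tsv").write_text(gt_text)
            gt_written = True
        (out / "pred" / f"pred_q{q:g}.tsv").write_text(pred_text)
    return out
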