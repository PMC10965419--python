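"""Shared fixtures: tiny hand-built ontologies and random instance generators."""

from __future__ import annotations

import numpy as np
import pytest

from ontoeval import (parse_ground_truth, parse_obo, parse_predictions,
                      propagate_scores, propagate_truth, sweep_thresholds)

DIAMOND_OBO = """format-version: 1.2
ontology: test

[Term]
id: A
name: root

[Term]
id: B
name: left
is_a: A

[Term]
id: C
name: right
is_a: A

[Term]
id: D
name: leaf
is_a: B
is_a: C
"""

CHAIN_OBO = """format-version: 1.2
ontology: test

[Term]
id: A
name: root

[Term]
id: B
name: mid
is_a: A

[Term]
id: D
name: leaf
is_a: B
"""

TWO_NS_OBO = """format-version: 1.2
ontology: test

[Term]
id: A
name: a
namespace: ns1

[Term]
id: B
name: b
namespace: ns1
is_a: A

[Term]
id: X
name: x
namespace: ns2

[Term]
id: Y
name: y
namespace: ns2
is_a: X
"""


@pytest.fixture
def diamond():
    return parse_obo(DIAMOND_OBO)


@pytest.fixture
def chain():
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def two_ns():
    return parse_obo(TWO_NS_OBO)


def obo_from_parents(parents: dict[str, set[str]]) -> str:
    """Build an OBO document (single default namespace) from a parent map."""
    stanzas = ["format-version: 1.2", "ontology: generated"]
    for term in sorted(parents):
        lines = [f"[Term]", f"id: {term}", f"name: {term}"]
        for p in sorted(parents[term]):
            lines.append(f"is_a: {p}")
        stanzas.append("\n".join(lines))
    return "\n\n".join(stanzas) + "\n"


def random_dag(rng: np.random.Generator, n_terms: int) -> dict[str, set[str]]:
    """Random parent map over t000..t{n-1}; edges only to lower indices."""
    names = [f"t{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {names[0]: set()}
    for i in range(1, n_terms):
        k = 1 + int(rng.integers(0, min(3, i)))
        choice = rng.choice(i, size=min(k, i), replace=False)
        parents[names[i]] = {names[int(j)] for j in choice}
    # a second root sometimes, to exercise multi-root handling
    if n_terms > 3 and rng.random() < 0.3:
        parents[names[1]] = set()
    return parents


def random_instance(rng: np.random.Generator, n_terms=20, n_targets=6):
    """Random (parents, truth, preds, ia) sharing exact text-roundtrip floats."""
    parents = random_dag(rng, n_terms)
    terms = sorted(parents)
    non_roots = [t for t in terms if parents[t]] or terms
    truth = {}
    for i in range(n_targets):
        k = 1 + int(rng.integers(0, 3))
        truth[f"p{i:02d}"] = {str(x) for x in rng.choice(non_roots, size=k)}
    preds = {}
    for tgt in truth:
        scored = {}
        for t in terms:
            if rng.random() < 0.4:
                s = float(f"{rng.uniform(0.001, 1.0):.3f}")
                if s > 0:
                    scored[t] = s
        preds[tgt] = scored
    ia = {t: float(f"{rng.uniform(0, 4):.3f}") for t in terms}
    return parents, truth, preds, ia


def engine_evaluate(parents, truth, preds, taus, ia=None, averaging="macro",
                    norm="cafa", prop_mode="fill", exclude_roots=False,
                    strict=False, n_blocks=1, max_terms=None):
    """Run the full matrix engine on raw structures via the public parsers."""
    graphs = parse_obo(obo_from_parents(parents))
    g = graphs["default"]
    gt_text = "".join(f"{t}\t{term}\n" for t in sorted(truth)
                      for term in sorted(truth[t]))
    pred_text = "".join(f"{t}\t{term}\t{s!r}\n" for t in sorted(preds)
                        for term, s in sorted(preds[t].items()))
    gt = parse_ground_truth(gt_text, graphs)
    gt = {ns: propagate_truth(m, graphs[ns]) for ns, m in gt.items()}
    pred = parse_predictions(pred_text, graphs, gt, max_terms=max_terms)["default"]
    pred = propagate_scores(pred, g, mode=prop_mode)
    weights = None
    if ia is not None:
        weights = np.array([ia[t] for t in g.ids])
    return sweep_thresholds(gt["default"], pred, g, weights=weights,
                            taus=np.asarray(taus), averaging=averaging,
                            norm=norm, exclude_roots=exclude_roots,
                            strict=strict, n_blocks=n_blocks)
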