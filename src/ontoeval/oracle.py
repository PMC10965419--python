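"""Brute-force reference evaluator built on explicit sets.

This module re-derives the whole evaluation semantics independently of the
matrix engine: ancestor closures by recursion, score propagation as a
recursive definition over the DAG, confusions as literal set arithmetic,
and averaging with plain Python floats.  It deliberately shares no code
with :mod:`ontoeval.metrics` or :mod:`ontoeval.propagation` and is only
meant for small instances (tens of terms, tens of targets); it is the
comparison standard the fast engine is tested against.

Inputs are primitive structures: ``parents`` maps each term id to the set
of its direct parents, ``truth`` maps target -> set of directly annotated
terms, ``preds`` maps target -> {term: score}.
"""

from __future__ import annotations

import math
from functools import lru_cache

__all__ = ["oracle_evaluate"]


def _ancestors_or_self(term: str, parents: dict[str, set[str]]) -> set[str]:
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def _children_map(parents: dict[str, set[str]]) -> dict[str, set[str]]:
    ch: dict[str, set[str]] = {t: set() for t in parents}
    for t, ps in parents.items():
        for p in ps:
            ch[p].add(t)
    return ch


def _propagated_scores(
    scored: dict[str, float], parents: dict[str, set[str]], mode: str
) -> dict[str, float]:
    """Final per-term score by direct recursion over the DAG.

    fill: final(t) = own score if scored, else max over children's finals.
    max:  final(t) = max(own score, children's finals).
    """
    children = _children_map(parents)

    @lru_cache(maxsize=None)
    def final(t: str) -> float:
        child_best = max((final(c) for c in children[t]), default=0.0)
        own = scored.get(t, 0.0)
        if mode == "max":
            return max(own, child_best)
        return own if own > 0.0 else child_best

    return {t: final(t) for t in parents}


def oracle_evaluate(
    truth: dict[str, set[str]],
    preds: dict[str, dict[str, float]],
    parents: dict[str, set[str]],
    taus,
    ia: dict[str, float] | None = None,
    averaging: str = "macro",
    norm: str = "cafa",
    prop_mode: str = "fill",
    exclude_roots: bool = False,
    strict: bool = False,
) -> list[dict[str, float]]:
    """Evaluate one namespace naively; returns one dict of metrics per tau.

    Each dict carries tau, coverage (cov), pr, rc, f and — when ``ia`` is
    given — wpr, wrc, wf, ru, mi, s.  Targets are the keys of ``truth``;
    predictions for unknown targets are ignored.
    """
    roots = {t for t, ps in parents.items() if not ps}
    drop = roots if exclude_roots else set()
    weight = (lambda s: float(len(s))) if ia is None else (
        lambda s: float(sum(ia.get(t, 0.0) for t in s)))

    closed_truth = {
        tgt: set().union(*(_ancestors_or_self(t, parents) for t in ts)) - drop
        for tgt, ts in truth.items()
    }
    final_scores = {
        tgt: _propagated_scores(
            {t: s for t, s in preds.get(tgt, {}).items() if t in parents},
            parents, prop_mode)
        for tgt in truth
    }

    n = len(truth)
    results = []
    for tau in taus:
        per_target = []
        for tgt in truth:
            fs = final_scores[tgt]
            if strict:
                pred_set = {t for t, s in fs.items() if s > tau and s > 0} - drop
            else:
                pred_set = {t for t, s in fs.items() if s >= tau and s > 0} - drop
            true_set = closed_truth[tgt]
            tp = weight(pred_set & true_set)
            fp = weight(pred_set - true_set)
            fn = weight(true_set - pred_set)
            ctp = len(pred_set & true_set)
            cfp = len(pred_set - true_set)
            cfn = len(true_set - pred_set)
            per_target.append((ctp, cfp, cfn, tp, fp, fn, bool(pred_set)))

        cov = sum(1 for row in per_target if row[6]) / n

        def avg(i_tp, i_fp, i_fn):
            if averaging == "micro":
                tp = sum(r[i_tp] for r in per_target)
                fp = sum(r[i_fp] for r in per_target)
                fn = sum(r[i_fn] for r in per_target)
                pr = tp / (tp + fp) if tp + fp > 0 else 0.0
                rc = tp / (tp + fn) if tp + fn > 0 else 0.0
            else:
                prs, rcs = [], []
                for r in per_target:
                    tp, fp, fn = r[i_tp], r[i_fp], r[i_fn]
                    prs.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
                    rcs.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
                if norm == "cafa":
                    covered = [p for p, r in zip(prs, per_target) if r[6]]
                    pr = sum(covered) / len(covered) if covered else 0.0
                else:
                    pr = sum(prs) / n
                rc = sum(rcs) / n
            f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
            return pr, rc, f

        pr, rc, f = avg(0, 1, 2)
        rec = {"tau": float(tau), "cov": cov, "pr": pr, "rc": rc, "f": f, "n": n}
        if ia is not None:
            wpr, wrc, wf = avg(3, 4, 5)
            ru = sum(r[5] for r in per_target) / n
            mi = sum(r[4] for r in per_target) / n
            rec.update(wpr=wpr, wrc=wrc, wf=wf, ru=ru, mi=mi,
                       s=math.sqrt(ru * ru + mi * mi))
        results.append(rec)
    return results
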