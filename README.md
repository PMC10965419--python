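# ontoeval

Benchmarking tool for hierarchical multi-label prediction over ontologies.
Given an ontology in OBO format, a ground-truth annotation file and one or
more prediction files (one per method), `ontoeval` propagates annotations
and scores up the ontology DAG and sweeps a score-threshold grid to compute
precision–recall curves, the **Fmax** summary, information-accretion-weighted
variants, and remaining-uncertainty/misinformation curves with the **Smin**
semantic distance — the evaluation protocol used for protein function
prediction (Gene Ontology annotation), where predicted term sets must be
judged against the ancestor closure of the truth rather than flat labels.

It is intended for developers of function-prediction methods (or any
DAG-structured multi-label classifier) who need CAFA-style internal
benchmarking on their own datasets.

## The metrics

Let the ontology be a DAG of *m* terms per namespace. For each target *i*
the true set *T<sub>i</sub>* is the ancestor closure of its annotations; at
threshold τ the predicted set is *P<sub>i</sub>(τ) = {t : score(t) ≥ τ}*
after propagating scores to the root(s). With per-target precision
pr<sub>i</sub> = |P<sub>i</sub>∩T<sub>i</sub>|/|P<sub>i</sub>| and recall
rc<sub>i</sub> = |P<sub>i</sub>∩T<sub>i</sub>|/|T<sub>i</sub>|, macro
averaging follows the CAFA convention — precision averaged over the *m(τ)*
targets with at least one prediction, recall over all *n* ground-truth
targets:

    Fmax = max_τ  2·pr(τ)·rc(τ) / (pr(τ) + rc(τ))

Micro averaging sums the per-target confusion masses before forming the
ratios. With per-term information-accretion weights ia(t), set cardinalities
become IA-mass sums, giving weighted precision/recall/Fmax as well as

    ru(τ) = (1/n) Σ_i  ia(T_i \ P_i(τ))     (remaining uncertainty)
    mi(τ) = (1/n) Σ_i  ia(P_i(τ) \ T_i)     (misinformation)
    Smin  = min_τ √(ru(τ)² + mi(τ)²)

Score propagation is `fill` by default (a parent's own score is never
overwritten, as in CAFA) or `max` (parents receive the maximum over their
children, making every thresholded prediction a consistent subgraph).

## Worked example

A four-term diamond ontology (`T:0004 → T:0002/T:0003 → T:0001`), two
annotated proteins, and one prediction file:

```sh
ontoeval ex/ontology.obo ex/pred ex/gt.tsv --ia ex/ia.tsv \
         --out-dir ex/out --thresholds 0.25,0.5,0.75
```

`ex/out/evaluation.tsv` (one row per method, namespace and threshold):

```
filename      ns       tau   cov  pr        rc   f         n  wpr  wrc  wf    ru   mi  s
method_a.tsv  default  0.25  1    0.833333  1    0.909091  2  0.6  1    0.75  0    2   2
method_a.tsv  default  0.5   1    1         1    1         2  1    1    1     0    0   0
method_a.tsv  default  0.75  0.5  1         0.5  0.666667  2  1    0.5  0.666667  0.5  0  0.5
```

At τ = 0.25 every scored term survives, including a false-positive branch,
so precision drops and misinformation is positive (mi = 2 is the IA mass of
the wrong branch). At τ = 0.5 the surviving terms match the propagated
truth exactly — perfect row. At τ = 0.75 one protein loses all its
predictions: coverage falls to 0.5 and recall (averaged over *all* targets)
halves, while precision (averaged over *covered* targets only, the CAFA
normalization) stays 1. `ex/out/best_f.tsv` and `best_s.tsv` report
Fmax = 1 and Smin = 0, both attained at τ = 0.5.

`ontoeval-plot ex/out/evaluation.tsv --best ex/out/best_f.tsv --kind pr`
renders the precision–recall curves with the Fmax point marked;
`--kind rumi` draws the ru–mi curves. `ontoeval-fixtures` generates
synthetic benchmarks (ontology, ground truth, predictions of controllable
quality) for testing.

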