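# Methods

## Data model and pipeline

The evaluator holds three in-memory structures per namespace: the ontology
DAG with a dense 0..m−1 term index, a Boolean n × m ground-truth matrix
(targets × terms), and a real n′ × m score matrix per prediction file
(n′ ≤ n, since predictions are filtered to ground-truth targets). Matrices
are dense NumPy arrays: at the scale this tool targets (tens of thousands
of terms, thousands of targets, one prediction file resident at a time)
dense column operations during propagation are simple and fast; extremely
large target sets would favour a sparse layout, a known limitation.

Each OBO namespace ("aspect"/"sub-ontology") is an independent ontology:
graphs, matrices and all metrics are built and reported per namespace.
Terms without a namespace key share the namespace `default`, so
single-namespace ontologies work unchanged.

Parsing rules: only `is_a` edges form the hierarchy by default; `part_of`
relationships are included behind a flag because common practice varies and
the minimal hierarchy is the unambiguous choice. Obsolete terms are
dropped; `alt_id` values alias their canonical term so older annotation
files still match; cross-namespace edges are dropped with a warning rather
than failing, since public OBO files occasionally contain them. A cyclic
hierarchy or an empty document is fatal.

The DAG is topologically sorted once at parse time (Kahn's algorithm,
children first, ties broken by term index for byte-reproducible output), so
each propagation is a single linear pass over the order.

## Propagation semantics

Truth propagation closes each target's annotation set under the ancestor
relation; it always runs and is idempotent, so pre-propagated input is safe.

Score propagation has two modes:

* **fill** (default, the CAFA behaviour): a parent's own score is never
  overwritten. An unscored parent receives the maximum over its children's
  *final* values, so fills cascade to the root — the root is scored
  whenever any descendant is. The value cascading through an
  already-scored parent is that parent's own kept score (the literal
  "never overwrite" reading); a consequence, accepted and documented, is
  that thresholded prediction sets need not be consistent subgraphs.
* **max**: a parent receives the maximum of its own and its children's
  final scores, making the score function monotone non-decreasing toward
  the root; every thresholded prediction is then a consistent subgraph.

## Metrics and averaging

At each threshold τ of the grid (default: 100 evenly spaced cutoffs in
[0, 1), i.e. 0.00…0.99) the predicted set is {terms with score ≥ τ and
score > 0}. Inclusive comparison (≥) is the default so a grid point equal
to a score keeps that prediction; a strict (>) variant is exposed as a flag
since either convention appears in practice, and the reference oracle
implements both. Per-target confusion summaries (tp, fp, fn) are counts,
or IA-mass sums when an information-accretion file is supplied; tp + fn is
threshold-invariant (the target's truth mass), a conservation property the
tests check.

Macro averaging computes per-target precision/recall first and averages:
precision over targets with ≥ 1 prediction (norm `cafa`) or over all
ground-truth targets (norm `full`, penalising low coverage); recall always
over all ground-truth targets. Micro averaging sums confusions first and
forms the ratios once — dividing the sums by n first would cancel in every
ratio, so summing is mathematically identical. All degenerate ratios use
0/0 → 0, making every record total (an empty prediction file yields all-zero
metrics rather than an error). ru and mi are always averaged over all
ground-truth targets, mirroring the recall normalization.

Root terms can be excluded from both the predicted and the true set before
counting; a root-only prediction then leaves its target uncovered.
Duplicate (target, term) prediction rows keep the maximum score (monotone
and order-independent); the optional per-target term cap keeps the highest
scores, breaking boundary ties by lower term index, and is applied before
propagation — the cap limits the terms *processed*, and the propagated
closure of the kept terms remains evaluable.

The threshold grid may be split into blocks evaluated concurrently
(threads); blocks are independent and concatenated in grid order, so the
result is bit-identical to sequential evaluation — parallelism is a
contract about identity of results, with a default of one block.

## Best-score tables and team handling

Fmax maximises F over the grid, Smin minimises s = √(ru² + mi²), weighted
Fmax maximises the IA-weighted F; ties break to the lowest threshold, and
no interpolation between grid points is performed. With a team map,
each table keeps one file per (team, namespace), ranked by that table's own
metric (f, s, or wf) since no single criterion is canonical; unmapped files
form singleton teams. Plots are rebuilt from the written TSV — not from
in-memory objects — so every plotted point appears verbatim as a table row,
drawn in threshold order without monotonic interpolation.

## Synthetic benchmarks and the reference oracle

The fixture generator emulates only the structural features the evaluator
consumes: a per-namespace random DAG (every non-root term takes ≥ 1 parent
among earlier terms, acyclic by construction), leaf-biased annotation sets,
and predictors parameterised by `quality` (probability a propagated-truth
term is predicted; true terms score near 1, pushed down by `noise`) and a
noise-dependent false-positive rate with scores in (0, 0.5]. Defaults —
50 terms, 2 namespaces, 25 targets, 3 annotations per target, quality 0.8,
noise 0.3 — are sized so runs complete in seconds while leaving room for
imperfect predictions on either side. It does not mimic real GO topology
(term-depth distributions, annotation bias), so passing tests demonstrate
correctness of the evaluation semantics, not calibration against any real
corpus. Truth generation and score generation use separate RNG streams, so
prediction files at different quality levels share one ground truth and
identical spec + seed gives byte-identical files.

The oracle (`ontoeval.oracle`) re-derives the full semantics with explicit
Python sets and recursion — ancestor closures by graph walk, fill/max
propagation as a memoised recursive definition, confusions as literal set
arithmetic — sharing no code with the matrix engine. Equivalence is
asserted to 1e−12 (absolute) across randomized instances and all
2×2×2×2×2 option combinations; instances are kept small (≤ 30 terms,
≤ 10 targets, 11 thresholds) because the oracle is deliberately naive.

## Numerical and degenerate-input choices

Scores are parsed as float64; values > 1 clamp to 1 with a warning, values
≤ 0 are treated as "not predicted". Harmonic means and s are computed from
the aggregated values. Prediction files that cannot be read are skipped
with an error logged (exit code 2 flags a partial run); an unparseable
ontology or ground truth, an empty prediction directory, or an empty
threshold grid is fatal (exit code 1). All tie-breaks (topological order,
term cap, best-score threshold) are deterministic, and no stage uses
randomness, so identical inputs reproduce outputs byte for byte.
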