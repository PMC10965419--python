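"""Ontology parsing and per-namespace DAG construction.

An OBO document is split into one independent directed acyclic graph per
namespace (GO calls these "aspects" or "sub-ontologies").  Each graph carries
a dense 0..m-1 term index, a children-first topological order computed once at
parse time, and the set of root terms (terms with no parents).  Hierarchical
edges point child -> parent.

Only ``is_a`` edges form the hierarchy by default; ``part_of`` relationships
can be included with an option.  Obsolete terms are excluded and alternative
ids resolve to their canonical term.
"""

from __future__ import annotations

import heapq
import io
import logging
from dataclasses import dataclass, field

import numpy as np
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "ParseOptions",
    "OntologyGraph",
    "parse_obo",
    "topological_order",
    "find_roots",
    "load_ia",
]


@dataclass(frozen=True)
class ParseOptions:
    """Which OBO relationship kinds form hierarchical edges.

    ``is_a`` is always included; ``part_of`` only when ``include_part_of``
    is set.  Other relationship types never form edges.
    """

    include_part_of: bool = False

    @property
    def edge_kinds(self) -> tuple[str, ...]:
        return ("is_a", "part_of") if self.include_part_of else ("is_a",)


DEFAULT_NAMESPACE = "default"


@dataclass
class OntologyGraph:
    """One namespace of an ontology as an indexed DAG.

    Attributes
    ----------
    namespace : str
        Namespace tag from the OBO file ("default" when absent).
    ids : list of str
        Canonical term accession per dense index 0..m-1.
    names : list of str
        Human-readable labels, aligned with ``ids``.
    index : dict
        Maps canonical ids *and* alt_ids to the dense index.
    parents : list of list of int
        ``parents[i]`` are the dense indices reachable from term i by one
        hierarchical (child -> parent) edge.
    topo_order : numpy.ndarray
        Permutation of 0..m-1 placing every term before all of its parents
        (children first, roots last).
    roots : frozenset of int
        Dense indices of terms with no parents; never empty.
    """

    namespace: str
    ids: list[str]
    names: list[str]
    index: dict[str, int]
    parents: list[list[int]]
    topo_order: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    roots: frozenset[int] = frozenset()

    @property
    def n_terms(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return sum(len(p) for p in self.parents)

    def __post_init__(self) -> None:
        if len(self.topo_order) != self.n_terms:
            self.topo_order = topological_order(self)
        if not self.roots:
            self.roots = find_roots(self)


class OntologyError(ValueError):
    """Fatal ontology defect: empty document or cyclic hierarchy."""


def parse_obo(obo_text: str, options: ParseOptions | None = None) -> dict[str, OntologyGraph]:
    """Parse an OBO document into one :class:`OntologyGraph` per namespace.

    Obsolete terms are excluded, alt_ids are recorded as aliases of their
    canonical term, and edges whose endpoints fall in different namespaces
    are dropped with a warning.  A cyclic hierarchy or an empty document is
    a fatal :class:`OntologyError`.
    """
    options = options or ParseOptions()
    multigraph = obonet.read_obo(io.StringIO(obo_text))
    if multigraph.number_of_nodes() == 0:
        raise OntologyError("ontology contains no usable terms")

    # Partition terms by namespace, preserving document order.
    by_ns: dict[str, list[str]] = {}
    for term_id, data in multigraph.nodes(data=True):
        ns = data.get("namespace", DEFAULT_NAMESPACE)
        by_ns.setdefault(ns, []).append(term_id)

    graphs: dict[str, OntologyGraph] = {}
    node_ns = {t: multigraph.nodes[t].get("namespace", DEFAULT_NAMESPACE) for t in multigraph}
    for ns, term_ids in by_ns.items():
        index: dict[str, int] = {t: i for i, t in enumerate(term_ids)}
        names = [multigraph.nodes[t].get("name", "") for t in term_ids]
        for t in term_ids:
            for alt in multigraph.nodes[t].get("alt_id", []):
                index.setdefault(alt, index[t])
        parents: list[list[int]] = [[] for _ in term_ids]
        for t in term_ids:
            seen: set[int] = set()
            for _, parent, kind in multigraph.out_edges(t, keys=True):
                if kind not in options.edge_kinds:
                    continue
                if node_ns[parent] != ns:
                    logger.warning(
                        "dropping cross-namespace edge %s -> %s (%s vs %s)",
                        t, parent, ns, node_ns[parent],
                    )
                    continue
                pi = index[parent]
                if pi not in seen:
                    seen.add(pi)
                    parents[index[t]].append(pi)
        graph = OntologyGraph(
            namespace=ns, ids=term_ids, names=names, index=index, parents=parents
        )
        logger.info(
            "namespace %s: %d terms, %d edges, %d root(s)",
            ns, graph.n_terms, graph.n_edges, len(graph.roots),
        )
        graphs[ns] = graph
    return graphs


def topological_order(graph: OntologyGraph) -> np.ndarray:
    """Children-first topological order via Kahn's algorithm.

    Ties are broken by term index, so the order is deterministic for a given
    document.  Raises :class:`OntologyError` naming a cycle member if the
    hierarchy is cyclic.
    """
    m = graph.n_terms
    # In-degree for the children-first order counts child edges: a term is
    # emittable once all of its children have been emitted.
    children: list[list[int]] = [[] for _ in range(m)]
    pending = np.zeros(m, dtype=np.intp)
    for child, ps in enumerate(graph.parents):
        for p in ps:
            children[p].append(child)
            pending[p] += 1
    ready = [i for i in range(m) if pending[i] == 0]
    heapq.heapify(ready)
    order = np.empty(m, dtype=np.intp)
    k = 0
    while ready:
        i = heapq.heappop(ready)
        order[k] = i
        k += 1
        for p in graph.parents[i]:
            pending[p] -= 1
            if pending[p] == 0:
                heapq.heappush(ready, p)
    if k != m:
        stuck = graph.ids[int(np.nonzero(pending)[0][0])]
        raise OntologyError(f"cyclic hierarchy detected (involves {stuck!r})")
    return order


def find_roots(graph: OntologyGraph) -> frozenset[int]:
    """Indices of terms with no outgoing hierarchical edge (the namespace roots)."""
    return frozenset(i for i, ps in enumerate(graph.parents) if not ps)


def load_ia(ia_text: str, graph: OntologyGraph) -> np.ndarray:
    """Load per-term information-accretion weights for one namespace.

    The file is a headerless two-column TSV ``term-id TAB weight``.  Every
    graph term receives a weight: terms missing from the file get 0 (warned),
    file entries for unknown terms are ignored (warned).  A negative or
    non-numeric weight is a fatal error naming the offending line.
    """
    weights = np.zeros(graph.n_terms, dtype=np.float64)
    seen = np.zeros(graph.n_terms, dtype=bool)
    unknown = 0
    for lineno, line in enumerate(ia_text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"IA file line {lineno}: expected 2 tab-separated columns")
        term, raw = parts[0].strip(), parts[1].strip()
        try:
            w = float(raw)
        except ValueError:
            raise ValueError(f"IA file line {lineno}: non-numeric weight {raw!r}") from None
        if not np.isfinite(w) or w < 0:
            raise ValueError(f"IA file line {lineno}: negative or non-finite weight {raw}")
        idx = graph.index.get(term)
        if idx is None:
            unknown += 1
            continue
        weights[idx] = w
        seen[idx] = True
    if unknown:
        logger.warning("IA file: %d entries for terms not in namespace %s ignored",
                       unknown, graph.namespace)
    missing = int((~seen).sum())
    if missing:
        logger.warning("IA file: %d terms of namespace %s missing, weight set to 0",
                       missing, graph.namespace)
    return weights
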