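"""Gene Ontology DAG: parsing, queries, information content and the
hierarchy-aware term-correlation matrix.

The GO organizes the terms of each sub-ontology (BP, MF, CC) in a rooted
DAG whose edges point from a child term to its more general parent. This
module parses OBO files into a light :class:`OntologyGraph`, answers
ancestor/descendant queries, and computes the two quantities the GCN
branch consumes:

* the information content of a selected term ``t``,
  ``IC(t) = 1 - log(1 + |desc(t)|) / log(|T|)``, where ``desc(t)`` is the
  set of selected descendants of ``t`` including ``t`` itself and ``|T|``
  the number of selected terms — deep, specific terms have few descendants
  and hence high IC;
* the correlation weight attached to every direct parent→child pair
  ``(t, s)``, ``A(t, s) = n_s / n_t + IC(s) / sum_{s' in ch(t)} IC(s')``,
  combining the annotation-frequency ratio with the child's share of the
  sibling information content.

``A`` is symmetrized, given self-loops and degree-normalized before it
enters the graph convolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

from .exceptions import CycleError, OntologyError

NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


@dataclass
class OntologyGraph:
    """A rooted DAG of ontology terms with typed child→parent edges.

    Parameters
    ----------
    terms
        Primary term identifiers (``GO:XXXXXXX`` style strings).
    edges
        ``(child, parent, relation)`` triples; both endpoints must be terms.
    namespace
        Term → sub-ontology code (``BP``, ``MF`` or ``CC``).
    alt_ids
        Alternate identifier → primary identifier.
    """

    terms: set
    edges: set
    namespace: dict
    alt_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        self._parents = {t: set() for t in self.terms}
        self._children = {t: set() for t in self.terms}
        for child, parent, _rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise OntologyError(
                    f"edge ({child}, {parent}) references an unknown term"
                )
            self._parents[child].add(parent)
            self._children[parent].add(child)
        for alt, primary in self.alt_ids.items():
            if primary not in self.terms:
                raise OntologyError(f"alt_id {alt} maps to unknown term {primary}")
        self._validate_acyclic()

    def _validate_acyclic(self):
        for ns in set(self.namespace.values()):
            g = nx.DiGraph()
            members = [t for t in self.terms if self.namespace.get(t) == ns]
            g.add_nodes_from(members)
            g.add_edges_from(
                (c, p)
                for c, p, _ in self.edges
                if self.namespace.get(c) == ns and self.namespace.get(p) == ns
            )
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                continue
            raise CycleError([edge[0] for edge in cycle])

    # -- lookups ---------------------------------------------------------
    def resolve(self, term: str) -> str:
        """Map an alternate id to its primary id; primary ids pass through."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise OntologyError(f"unknown term {term!r}")

    def __contains__(self, term) -> bool:
        return term in self.terms or term in self.alt_ids

    def parents(self, term: str) -> set:
        return set(self._parents[self.resolve(term)])

    def children(self, term: str) -> set:
        return set(self._children[self.resolve(term)])

    def ancestors(self, term: str) -> set:
        """Transitive closure over parent edges, excluding the term itself."""
        t = self.resolve(term)
        seen: set = set()
        stack = list(self._parents[t])
        while stack:
            p = stack.pop()
            if p not in seen:
                seen.add(p)
                stack.extend(self._parents[p])
        return seen

    def descendants(self, term: str) -> set:
        """Transitive closure over child edges, excluding the term itself."""
        t = self.resolve(term)
        seen: set = set()
        stack = list(self._children[t])
        while stack:
            c = stack.pop()
            if c not in seen:
                seen.add(c)
                stack.extend(self._children[c])
        return seen

    def roots(self, namespace: str | None = None) -> set:
        out = set()
        for t in self.terms:
            if namespace is not None and self.namespace.get(t) != namespace:
                continue
            if not self._parents[t]:
                out.add(t)
        return out


def parse_obo(path, relations: Iterable[str] = ("is_a",)) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file.

    Obsolete terms are dropped, ``alt_id`` declarations are collected, and
    only edges whose relation appears in ``relations`` are retained
    (``is_a`` by default; add ``part_of`` to follow part-whole links).
    """
    try:
        net = obonet.read_obo(path, ignore_obsolete=True)
    except (OSError, ValueError) as exc:
        raise OntologyError(f"cannot read OBO file {path!r}: {exc}") from exc

    wanted = set(relations)
    terms = set(net.nodes)
    edges = set()
    namespace = {}
    alt_ids = {}
    for t, data in net.nodes(data=True):
        ns = data.get("namespace")
        if ns is not None:
            namespace[t] = NAMESPACE_CODES.get(ns, ns)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = t
    # obonet stores edges child -> parent keyed by relation name
    for child, parent, rel in net.edges(keys=True):
        if rel in wanted:
            edges.add((child, parent, rel))
    return OntologyGraph(terms=terms, edges=edges, namespace=namespace, alt_ids=alt_ids)


@dataclass
class TermIndex:
    """An ordered set of selected terms mapped to matrix columns."""

    terms: list
    namespace: str | None = None

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise OntologyError("TermIndex contains duplicate terms")
        self.position = {t: i for i, t in enumerate(self.terms)}

    def __len__(self):
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term):
        return term in self.position

    def __getitem__(self, i):
        return self.terms[i]

    def index_of(self, term) -> int:
        try:
            return self.position[term]
        except KeyError:
            raise OntologyError(f"term {term!r} is not in the selected set") from None


def ancestors(graph: OntologyGraph, term: str) -> set:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term)


def descendants_within(graph: OntologyGraph, term: str, index: TermIndex) -> set:
    """``desc(t)``: the selected-set descendants of ``t`` plus ``t`` itself."""
    if term not in index:
        raise OntologyError(f"term {term!r} is not in the selected set")
    out = {term}
    out.update(d for d in graph.descendants(term) if d in index)
    return out


def information_content(
    graph: OntologyGraph, index: TermIndex, clamp: bool = False
) -> np.ndarray:
    """Per-term information content over the selected set.

    ``IC(t) = 1 - log(1 + |desc(t)|) / log(|T|)``. The value is independent
    of the log base. It is not clamped by default: a term whose descendant
    set covers the whole selected set comes out slightly negative, which the
    formula permits; pass ``clamp=True`` to floor at zero.
    """
    n = len(index)
    if n < 2:
        raise OntologyError("information content needs at least 2 selected terms")
    log_n = math.log(n)
    ic = np.empty(n, dtype=float)
    for i, t in enumerate(index):
        d = len(descendants_within(graph, t, index))
        ic[i] = 1.0 - math.log(1 + d) / log_n
    if clamp:
        np.maximum(ic, 0.0, out=ic)
    return ic


def correlation_matrix(
    graph: OntologyGraph,
    index: TermIndex,
    counts: Mapping[str, int],
    ic: Sequence[float],
) -> np.ndarray:
    """Hierarchy-aware correlation weights on direct parent→child pairs.

    ``A[t, s] = n_s / n_t + IC(s) / sum_{s' in ch(t)} IC(s')`` where
    ``ch(t)`` are the direct selected children of ``t``; every other entry
    is zero. Row = parent, column = child, both in index order.
    """
    ic = np.asarray(ic, dtype=float)
    n = len(index)
    if ic.shape != (n,):
        raise OntologyError(f"IC vector has shape {ic.shape}, expected ({n},)")
    A = np.zeros((n, n), dtype=float)
    for t in index:
        ti = index.index_of(t)
        ch = sorted(c for c in graph.children(t) if c in index)
        if not ch:
            continue
        n_t = counts.get(t, 0)
        if n_t <= 0:
            raise OntologyError(f"parent term {t} has nonpositive count {n_t}")
        ic_sum = float(sum(ic[index.index_of(c)] for c in ch))
        if ic_sum <= 0:
            raise OntologyError(
                f"children of {t} have nonpositive total information content"
            )
        for s in ch:
            si = index.index_of(s)
            n_s = counts.get(s, 0)
            if n_s <= 0:
                raise OntologyError(f"child term {s} has nonpositive count {n_s}")
            A[ti, si] = n_s / n_t + ic[si] / ic_sum
    return A


def normalize_adjacency(A: np.ndarray, variant: str = "sym") -> np.ndarray:
    """Degree-normalize a correlation matrix for graph convolution.

    The raw matrix is symmetrized and given self-loops,
    ``M = A + Aᵀ + I``, so information flows both up and down the DAG and
    every term retains its own signal. ``variant="sym"`` returns the
    symmetric renormalization ``D̃^{-1/2} M D̃^{-1/2}`` used by the model;
    ``variant="row"`` returns the row-stochastic ``D̃^{-1} M`` (rows sum to
    one; exposed for testing).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise OntologyError(f"adjacency must be square, got shape {A.shape}")
    M = A + A.T + np.eye(A.shape[0])
    deg = M.sum(axis=1)
    if variant == "sym":
        d = 1.0 / np.sqrt(deg)
        return d[:, None] * M * d[None, :]
    if variant == "row":
        return M / deg[:, None]
    raise ValueError(f"unknown normalization variant {variant!r}")
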