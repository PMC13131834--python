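"""Gene Ontology DAG handling: OBO parsing, ancestry, and true-path propagation.

The Gene Ontology is three disjoint rooted DAGs (aspects): molecular_function,
biological_process and cellular_component.  Edges point child -> parent and carry
one of the two relations used for annotation propagation, ``is_a`` and
``part_of``; other relations (the ``regulates`` family, ``occurs_in``, ...) are
not part of the true-path rule as applied here and are dropped at parse time.

An annotation to a term implies annotation to every ancestor of that term
(the true-path rule); :func:`propagate_terms` is the closure under this rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

ASPECTS = ("molecular_function", "biological_process", "cellular_component")

#: canonical GO root term ids, used as a cross-check when present
CANONICAL_ROOTS = {
    "molecular_function": "GO:0003674",
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
}

PROPAGATION_RELATIONS = frozenset({"is_a", "part_of"})

_TERM_ID_RE = re.compile(r"^[A-Za-z_]+:\d+$")


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, bad namespaces...)."""


@dataclass(frozen=True)
class Term:
    """One ontology term."""

    id: str
    name: str
    aspect: str
    obsolete: bool = False
    replaced_by: str | None = None


@dataclass
class OntologyGraph:
    """The active (non-obsolete) ontology DAG plus a side index of obsolete terms.

    ``graph`` is a :class:`networkx.DiGraph` whose edges run child -> parent and
    carry a ``relation`` attribute in {is_a, part_of}.  Obsolete terms never
    appear in ``graph``; they live in ``obsolete`` with their ``replaced_by``
    pointer (which is recorded but never auto-applied).
    """

    terms: dict[str, Term]
    graph: nx.DiGraph
    roots: dict[str, str]
    obsolete: dict[str, Term] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def aspect_of(self, term_id: str) -> str:
        return self.terms[term_id].aspect

    def is_root(self, term_id: str) -> bool:
        return term_id in self.roots.values()


def _validate_acyclic(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise OntologyError(
            f"ontology edge set contains a cycle through {cycle[0][0]!r}"
        )


def _find_roots(terms: Mapping[str, Term], graph: nx.DiGraph) -> dict[str, str]:
    roots: dict[str, str] = {}
    for aspect in ASPECTS:
        candidates = [
            t.id
            for t in terms.values()
            if t.aspect == aspect and graph.out_degree(t.id) == 0
        ]
        if not candidates:
            continue
        if len(candidates) > 1:
            raise OntologyError(
                f"aspect {aspect!r} has multiple parentless terms: {sorted(candidates)}"
            )
        root = candidates[0]
        canonical = CANONICAL_ROOTS[aspect]
        if canonical in terms and root != canonical:
            raise OntologyError(
                f"aspect {aspect!r}: parentless term {root!r} is not the "
                f"canonical root {canonical!r} present in this ontology"
            )
        roots[aspect] = root
    return roots


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO 1.2 document into an :class:`OntologyGraph`.

    Keeps all non-obsolete terms and their is_a/part_of edges.  Obsolete terms
    are retained in a side index together with any ``replaced_by`` pointer but
    are excluded from the active graph.  All other relationship types are
    dropped.

    Raises
    ------
    OntologyError
        If the edge set is cyclic or a term carries an unknown namespace.
    OSError / FileNotFoundError
        If the file cannot be read.
    """
    raw = obonet.read_obo(path, ignore_obsolete=False)

    terms: dict[str, Term] = {}
    obsolete: dict[str, Term] = {}
    for node, data in raw.nodes(data=True):
        if not _TERM_ID_RE.match(node):
            raise OntologyError(f"malformed term id {node!r} (expected PREFIX:digits)")
        namespace = data.get("namespace")
        if namespace not in ASPECTS:
            raise OntologyError(
                f"term {node!r} has unknown namespace {namespace!r}; "
                f"expected one of {ASPECTS}"
            )
        if str(data.get("is_obsolete", "")).lower() == "true":
            repl = data.get("replaced_by") or [None]
            obsolete[node] = Term(
                id=node,
                name=data.get("name", ""),
                aspect=namespace,
                obsolete=True,
                replaced_by=repl[0],
            )
        else:
            terms[node] = Term(id=node, name=data.get("name", ""), aspect=namespace)

    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for child, parent, relation in raw.edges(keys=True):
        if relation not in PROPAGATION_RELATIONS:
            continue
        if child in obsolete or parent in obsolete:
            continue
        if terms[child].aspect != terms[parent].aspect:
            raise OntologyError(
                f"edge {child} -> {parent} crosses aspects "
                f"({terms[child].aspect} -> {terms[parent].aspect})"
            )
        graph.add_edge(child, parent, relation=relation)

    _validate_acyclic(graph)
    roots = _find_roots(terms, graph)
    return OntologyGraph(terms=terms, graph=graph, roots=roots, obsolete=obsolete)


def ancestors(graph: OntologyGraph, term: str) -> set[str]:
    """All terms reachable from *term* via is_a/part_of edges, excluding *term*.

    Raises :class:`KeyError` for a term that is not active in the graph.
    """
    if term not in graph.terms:
        raise KeyError(f"unknown or obsolete term id: {term!r}")
    cached = graph._ancestor_cache.get(term)
    if cached is None:
        # edges run child -> parent, so ancestry = forward reachability
        cached = frozenset(nx.descendants(graph.graph, term))
        graph._ancestor_cache[term] = cached
    return set(cached)


def propagate_terms(graph: OntologyGraph, terms: Iterable[str]) -> set[str]:
    """Close a term set under the true-path rule (terms plus all ancestors).

    Idempotent and monotone.  Raises :class:`KeyError` listing every unknown or
    obsolete term id if any element is not active.
    """
    terms = set(terms)
    unknown = sorted(t for t in terms if t not in graph.terms)
    if unknown:
        raise KeyError(f"unknown or obsolete term ids: {unknown}")
    out = set(terms)
    for t in terms:
        out |= ancestors(graph, t)
    return out


def aspect_subgraph(graph: OntologyGraph, aspect: str) -> OntologyGraph:
    """The induced subgraph of one aspect; its single root is the aspect root."""
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}; expected one of {ASPECTS}")
    terms = {tid: t for tid, t in graph.terms.items() if t.aspect == aspect}
    sub = graph.graph.subgraph(terms).copy()
    roots = {aspect: graph.roots[aspect]} if aspect in graph.roots else {}
    obsolete = {tid: t for tid, t in graph.obsolete.items() if t.aspect == aspect}
    return OntologyGraph(terms=terms, graph=sub, roots=roots, obsolete=obsolete)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize an :class:`OntologyGraph` back to OBO 1.2.

    Active terms keep their is_a/part_of tags; obsolete terms are written with
    ``is_obsolete: true`` and their ``replaced_by`` pointer.  Terms and edges
    are emitted in sorted order so output bytes are deterministic.
    """
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    all_terms = sorted(list(graph.terms.values()) + list(graph.obsolete.values()),
                       key=lambda t: t.id)
    for term in all_terms:
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        lines.append(f"namespace: {term.aspect}")
        if term.obsolete:
            lines.append("is_obsolete: true")
            if term.replaced_by:
                lines.append(f"replaced_by: {term.replaced_by}")
        else:
            for _, parent, data in sorted(
                graph.graph.out_edges(term.id, data=True), key=lambda e: e[1]
            ):
                if data["relation"] == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: part_of {parent}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
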