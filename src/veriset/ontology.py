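"""OBO ontology ingestion and hop-bounded ancestor queries.

Terms form a parent-directed DAG over five relation types — is_a,
part_of, regulates, negatively_regulates, positively_regulates — all
traversed uniformly: one hop is one edge of any listed type, and mixed
relation types may occur along a single path.  Ancestors are reached via
the child->parent direction encoded in OBO (is_a / relationship targets
are parents).
"""

from __future__ import annotations

from collections import deque
from pathlib import Path

import networkx as nx
import obonet

RELATION_TYPES = frozenset(
    {"is_a", "part_of", "regulates", "negatively_regulates", "positively_regulates"}
)


class OboParseError(ValueError):
    """The OBO file could not be parsed or is not a DAG."""


class UnknownTermError(KeyError):
    """A queried term id is not in the ontology."""


class OntologyGraph:
    """Typed parent-directed DAG of ontology terms.

    Wraps a :class:`networkx.MultiDiGraph` with edges child -> parent
    keyed by relation type, restricted to the five supported relations.
    Obsolete terms are excluded at load.
    """

    def __init__(self, graph: nx.MultiDiGraph):
        self.graph = graph
        self.names: dict[str, str] = {
            n: data.get("name", n) for n, data in graph.nodes(data=True)
        }
        self._name_index: dict[str, str] = {}
        for term_id, name in self.names.items():
            self._name_index.setdefault(name.casefold(), term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def name_of(self, term_id: str) -> str:
        return self.names[term_id]

    def resolve_name(self, name: str) -> str | None:
        """Exact case-insensitive name -> term id, or None."""
        return self._name_index.get(name.casefold())

    def parents(self, term_id: str) -> list[str]:
        return sorted(set(self.graph.successors(term_id)))


def _build(graph: nx.MultiDiGraph) -> OntologyGraph:
    typed = nx.MultiDiGraph()
    typed.add_nodes_from(graph.nodes(data=True))
    for child, parent, key in graph.edges(keys=True):
        if key in RELATION_TYPES:
            if parent not in typed:
                typed.add_node(parent)
            typed.add_edge(child, parent, key=key)
    if not nx.is_directed_acyclic_graph(nx.DiGraph(typed)):
        raise OboParseError("ontology contains a cycle over the five relations")
    return OntologyGraph(typed)


def load_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into a typed ancestor graph.

    Only the five supported relation types are kept; obsolete terms are
    dropped; a cycle over those relations is a parse error.
    """
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # malformed stanza, bad header, ...
        raise OboParseError(f"failed to parse OBO file {path}: {exc}") from exc
    return _build(graph)


def from_networkx(graph: nx.MultiDiGraph) -> OntologyGraph:
    """Build directly from a child->parent multigraph (used by fixtures)."""
    return _build(graph)


def ancestors_within_hops(
    ontology: OntologyGraph, term_id: str, k: int
) -> dict[str, int]:
    """All ancestors within ``k`` hops, with minimal hop distances.

    BFS over child->parent edges of all five relation types; the term
    itself is excluded; ``k=0`` yields the empty set.
    """
    if term_id not in ontology:
        raise UnknownTermError(f"term {term_id!r} not in ontology")
    if k < 0:
        raise ValueError("hop bound must be >= 0")
    dist: dict[str, int] = {}
    queue: deque[tuple[str, int]] = deque([(term_id, 0)])
    seen = {term_id}
    while queue:
        node, d = queue.popleft()
        if d == k:
            continue
        for parent in ontology.graph.successors(node):
            if parent not in seen:
                seen.add(parent)
                dist[parent] = d + 1
                queue.append((parent, d + 1))
    return dist
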