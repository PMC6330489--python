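"""Gene Ontology term graph: OBO parsing and closure queries.

The ontology is a directed acyclic graph over GO terms.  Each term may
have several parents (via typed relationships such as ``is_a`` and
``part_of``) and several children; terms deeper in the graph are more
specific.  This module parses an OBO 1.2/1.4 flat file into an
:class:`OntologyDAG` and answers parent/child/ancestor/descendant
queries under a configurable set of relationship types.

Only ``[Term]`` stanzas are interpreted; ``[Typedef]`` stanzas are
skipped.  ``intersection_of`` and ``disjoint_from`` clauses are ignored:
they are not part of the parent semantics the shared-term analysis
relies on.  Obsolete terms are dropped from the graph but kept in a
side index so annotations pointing at them can be reported as skipped
rather than silently lost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from os import PathLike
from typing import AbstractSet, Iterable, Mapping

import networkx as nx
import obonet

from .errors import (
    OboParseError,
    ObsoleteTermError,
    OntologyValidationError,
    UnknownTermError,
)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: Relationship types understood by the parser.
KNOWN_RELATIONS = frozenset(
    {"is_a", "part_of", "regulates", "positively_regulates", "negatively_regulates"}
)

#: Default parent relations.  The regulates family is excluded by default
#: (parent maps built from is_a + part_of are the conventional GO parent
#: semantics) but can be selected explicitly.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class GOTerm:
    """One ontology term.

    Parameters
    ----------
    term_id
        GO accession, ``GO:`` followed by seven digits.
    name
        Human-readable term name.
    namespace
        One of ``biological_process``, ``molecular_function``,
        ``cellular_component``.
    parents
        Typed parent links as ``(relation, parent_term_id)`` pairs.
        Empty for namespace roots and for obsolete terms.
    alt_ids
        Secondary accessions that resolve to this term.
    obsolete
        Whether the term is deprecated; obsolete terms keep no parents.
    """

    term_id: str
    name: str
    namespace: str
    parents: tuple[tuple[str, str], ...] = ()
    alt_ids: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass
class OntologyDAG:
    """The acyclic GO term graph restricted to a set of relation types.

    Attributes
    ----------
    terms
        Primary id -> :class:`GOTerm` for every non-obsolete term.
    alt_index
        Secondary accession -> primary id (non-obsolete targets only).
    relations_in_use
        The relation types whose edges are present in the graph.
    obsolete_terms
        Primary id -> :class:`GOTerm` for obsolete terms (not in the graph).
    """

    terms: dict[str, GOTerm]
    alt_index: dict[str, str]
    relations_in_use: frozenset[str]
    obsolete_terms: dict[str, GOTerm] = field(default_factory=dict)
    _graph: nx.DiGraph = field(default_factory=nx.DiGraph, repr=False)

    def __post_init__(self) -> None:
        if self._graph.number_of_nodes() == 0 and self.terms:
            self._graph = _build_graph(self.terms)

    # -- lookups -----------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_index

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Return the primary id for a primary or secondary accession.

        Raises
        ------
        ObsoleteTermError
            If the id names an obsolete term.
        UnknownTermError
            If the id is not in the ontology at all.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_index:
            return self.alt_index[term_id]
        if term_id in self.obsolete_terms:
            raise ObsoleteTermError(term_id)
        raise UnknownTermError(term_id)

    # -- structure queries -------------------------------------------------

    def parents(self, term_id: str) -> set[str]:
        """Direct parents of a term under ``relations_in_use``."""
        return set(self._graph.successors(self.resolve(term_id)))

    def children(self, term_id: str) -> set[str]:
        """Direct children of a term under ``relations_in_use``."""
        return set(self._graph.predecessors(self.resolve(term_id)))

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive parents of a term, excluding the term itself.

        Empty for a namespace root.
        """
        # edges run child -> parent, so graph-descendants are GO-ancestors
        return nx.descendants(self._graph, self.resolve(term_id))

    def descendants(self, term_id: str) -> set[str]:
        """Transitive children of a term, excluding the term itself."""
        return nx.ancestors(self._graph, self.resolve(term_id))

    def roots(self) -> set[str]:
        """Terms with no parents under ``relations_in_use``."""
        return {t for t in self.terms if self._graph.out_degree(t) == 0}

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace


def _build_graph(terms: Mapping[str, GOTerm]) -> nx.DiGraph:
    graph: nx.DiGraph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for term in terms.values():
        for relation, parent_id in term.parents:
            graph.add_edge(term.term_id, parent_id, relation=relation)
    return graph


def _prevalidate(path: str | PathLike) -> None:
    """Cheap line-level scan so malformed stanza lines fail with a line number."""
    in_term = False
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError(
                        f"line {lineno}: malformed stanza header {line!r}"
                    )
                in_term = line == "[Term]"
                continue
            if in_term and ":" not in line:
                raise OboParseError(
                    f"line {lineno}: malformed tag-value line {line!r} in [Term] stanza"
                )


def parse_obo(
    path: str | PathLike,
    relations: AbstractSet[str] | Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyDAG:
    """Parse an OBO flat file into an :class:`OntologyDAG`.

    Parameters
    ----------
    path
        OBO 1.2/1.4 file (go-basic style).
    relations
        Relationship types to turn into parent edges; a subset of
        :data:`KNOWN_RELATIONS`.  ``is_a`` clauses and ``relationship:``
        clauses whose type is selected become edges; everything else is
        dropped.

    Raises
    ------
    OboParseError
        On malformed stanzas (with line number) or dangling parent
        references.
    OntologyValidationError
        If the selected relations induce a directed cycle; the message
        lists one cycle.
    """
    relations = frozenset(relations)
    unknown = relations - KNOWN_RELATIONS
    if unknown:
        raise ValueError(f"unsupported relation types: {sorted(unknown)}")

    _prevalidate(path)
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise OboParseError(f"failed to parse OBO file {path}: {exc}") from exc

    terms: dict[str, GOTerm] = {}
    obsolete: dict[str, GOTerm] = {}
    alt_index: dict[str, str] = {}

    for node, data in multigraph.nodes(data=True):
        if "name" not in data:
            # obonet materialises referenced-but-undefined targets as bare nodes
            raise OboParseError(f"term {node} is referenced but has no [Term] stanza")
        if not GO_ID_PATTERN.match(node):
            raise OboParseError(f"term id {node!r} does not match GO:<7 digits>")
        is_obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        alt_ids = tuple(data.get("alt_id", ()))
        parent_links: list[tuple[str, str]] = []
        if not is_obsolete:
            for _, parent, relation in multigraph.out_edges(node, keys=True):
                if relation in relations:
                    parent_links.append((relation, parent))
        term = GOTerm(
            term_id=node,
            name=data["name"],
            namespace=data.get("namespace", "biological_process"),
            parents=tuple(sorted(parent_links)),
            alt_ids=alt_ids,
            obsolete=is_obsolete,
        )
        if is_obsolete:
            obsolete[node] = term
        else:
            terms[node] = term
            for alt in alt_ids:
                alt_index[alt] = node

    for term in terms.values():
        for _, parent in term.parents:
            if parent not in terms:
                where = "obsolete" if parent in obsolete else "missing"
                raise OboParseError(
                    f"term {term.term_id} has {where} parent {parent}"
                )

    graph = _build_graph(terms)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        path_str = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyValidationError(f"cycle under relations {sorted(relations)}: {path_str}")

    return OntologyDAG(
        terms=terms,
        alt_index=alt_index,
        relations_in_use=relations,
        obsolete_terms=obsolete,
        _graph=graph,
    )


def resolve(dag: OntologyDAG, term_id: str) -> str:
    """Functional alias for :meth:`OntologyDAG.resolve`."""
    return dag.resolve(term_id)


def ancestors(dag: OntologyDAG, term_id: str) -> set[str]:
    """Functional alias for :meth:`OntologyDAG.ancestors`."""
    return dag.ancestors(term_id)


def descendants(dag: OntologyDAG, term_id: str) -> set[str]:
    """Functional alias for :meth:`OntologyDAG.descendants`."""
    return dag.descendants(term_id)
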