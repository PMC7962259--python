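"""Chemical ontology subsumption graphs.

An ontology (ChEBI being the motivating instance) is read from an OBO
flat file into a directed acyclic graph whose edges run from child term
to parent term and carry only the hierarchical ``is_a`` relation.  Terms
may be annotated with a SMILES string describing a fully defined
molecular structure; terms that are leaves of the hierarchy *and* carry
such a structure are the *leaf members* — the classification instances —
while every other term is a *class* that groups members.

The graph supports the queries needed downstream: ancestor closure,
condensation of a class set to an antichain (no retained class subsumes
another), and shortest-path distance between two terms, which is the
basis of the ontology-aware evaluation metric.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyError",
    "OboParseError",
    "UnknownTermError",
    "OntologyGraph",
    "load_ontology",
    "write_obo",
]


class OntologyError(Exception):
    """Base class for ontology-related failures."""


class OboParseError(OntologyError):
    """The OBO file could not be parsed."""


class UnknownTermError(OntologyError, KeyError):
    """A term identifier is not present in the graph."""


#: Pattern matching the ChEBI-style SMILES structure annotation, e.g.
#: ``http://purl.obolibrary.org/obo/chebi/smiles "CCO" xsd:string``
_SMILES_PROPERTY = re.compile(r'(?:^|/)smiles\s+"(?P<smiles>[^"]+)"')


@dataclass
class OntologyGraph:
    """A subsumption DAG over ontology terms.

    Parameters
    ----------
    graph
        Directed graph with one node per term and one edge per ``is_a``
        assertion, oriented child -> parent.  Node attributes: ``name``
        (display label) and optionally ``smiles``.
    root
        Identifier of the designated root term, if the ontology was
        restricted to a single branch at load time.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    root: str | None = None

    # -- basic accessors -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term_id: str) -> str | None:
        self._require(term_id)
        return self.graph.nodes[term_id].get("name")

    def smiles(self, term_id: str) -> str | None:
        """SMILES structure annotation of a term, or None."""
        self._require(term_id)
        return self.graph.nodes[term_id].get("smiles")

    def parents(self, term_id: str) -> set[str]:
        """Direct ``is_a`` parents of a term."""
        self._require(term_id)
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        """Direct ``is_a`` children of a term."""
        self._require(term_id)
        return set(self.graph.predecessors(term_id))

    def _require(self, term_id: str) -> None:
        if term_id not in self.graph:
            raise UnknownTermError(f"unknown term identifier: {term_id!r}")

    # -- spec operations -------------------------------------------------

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` by child -> parent edges.

        Excludes the term itself.
        """
        self._require(term_id)
        # edges point child -> parent, so graph-descendants are
        # ontology-ancestors
        return nx.descendants(self.graph, term_id)

    def descendants(self, term_id: str) -> set[str]:
        """All terms subsumed by ``term_id`` (excluding itself)."""
        self._require(term_id)
        return nx.ancestors(self.graph, term_id)

    def leaf_members(self) -> set[str]:
        """Terms with no children and a SMILES structure annotation.

        These are the classification instances: fully defined molecular
        entities sitting at the leaves of the hierarchy.
        """
        return {
            n
            for n, data in self.graph.nodes(data=True)
            if self.graph.in_degree(n) == 0 and data.get("smiles")
        }

    def condense(self, classes: set[str]) -> set[str]:
        """Drop every class that subsumes another class in the set.

        The result is an antichain under subsumption: no retained class
        is an ancestor of any other.  Idempotent.  Used both to strip
        redundant high-level predictions (e.g. a specific class plus
        'molecular entity') before counting parents and before the
        path-length comparison.
        """
        classes = set(classes)
        for c in classes:
            self._require(c)
        redundant: set[str] = set()
        for c in classes:
            # c is redundant if it is an ancestor of some other class
            redundant.update(self.ancestors(c) & classes)
        return classes - redundant

    def path_length(self, predicted: str, asserted: str) -> int | None:
        """Number of subsumption edges between two terms.

        0 when the terms coincide (an exact match); otherwise the length
        of the shortest path between them in the subsumption graph
        treated as undirected, so that sibling or descendant predictions
        still receive a finite distance.  Returns None when the two
        terms are disconnected.
        """
        self._require(predicted)
        self._require(asserted)
        if predicted == asserted:
            return 0
        try:
            return nx.shortest_path_length(
                self.graph.to_undirected(as_view=True), predicted, asserted
            )
        except nx.NetworkXNoPath:
            return None

    # -- export ----------------------------------------------------------

    def to_edge_tsv(self, path: str | Path) -> None:
        """Write the ``is_a`` edge list as TSV (child_id, parent_id)."""
        with open(path, "w") as fh:
            fh.write("child_id\tparent_id\n")
            for child, parent in sorted(self.graph.edges):
                fh.write(f"{child}\t{parent}\n")


def _extract_smiles(term_id: str, data: dict) -> str | None:
    values = [
        m.group("smiles")
        for pv in data.get("property_value", ())
        if (m := _SMILES_PROPERTY.search(pv))
    ]
    if not values:
        return None
    if len(values) > 1:
        logger.warning(
            "term %s carries %d SMILES annotations; using the first",
            term_id,
            len(values),
        )
    return values[0]


def load_ontology(path: str | Path, root: str | None = None) -> OntologyGraph:
    """Parse an OBO file into a subsumption DAG.

    Only non-obsolete terms and ``is_a`` edges are retained; every other
    relationship type (``has_part``, ...) is dropped.  A term's SMILES is
    read from its ChEBI-style ``property_value`` structure annotation
    when present.  When ``root`` is given, the graph is restricted to
    that term and its descendants (the paper's 'molecular entity'
    branch restriction).

    Raises
    ------
    OboParseError
        If the file is unreadable or malformed (the underlying message
        names the offending stanza where obonet can identify it).
    UnknownTermError
        If ``root`` does not occur in the file.
    OntologyError
        If the retained ``is_a`` graph contains a cycle.
    """
    path = Path(path)
    if not path.exists():
        raise OboParseError(f"no such OBO file: {path}")
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises bare ValueError on bad stanzas
        raise OboParseError(f"failed to parse {path}: {exc}") from exc

    g = nx.DiGraph()
    for term_id, data in multigraph.nodes(data=True):
        attrs: dict = {"name": data.get("name")}
        smiles = _extract_smiles(term_id, data)
        if smiles:
            attrs["smiles"] = smiles
        g.add_node(term_id, **attrs)
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyError(f"is_a hierarchy contains a cycle: {cycle}")

    if root is not None:
        if root not in g:
            raise UnknownTermError(f"root term {root!r} not found in {path}")
        keep = nx.ancestors(g, root) | {root}  # graph-ancestors = branch below
        g = g.subgraph(keep).copy()

    return OntologyGraph(graph=g, root=root)


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    """Serialise a graph back to OBO 1.2, round-trippable by load_ontology."""
    lines = ["format-version: 1.2", "ontology: chemont-export", ""]
    for term_id in sorted(ontology.graph.nodes):
        data = ontology.graph.nodes[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        if data.get("name"):
            lines.append(f"name: {data['name']}")
        for parent in sorted(ontology.graph.successors(term_id)):
            lines.append(f"is_a: {parent}")
        if data.get("smiles"):
            lines.append(
                "property_value: http://purl.obolibrary.org/obo/chebi/smiles "
                f'"{data["smiles"]}" xsd:string'
            )
        lines.append("")
    Path(path).write_text("\n".join(lines))
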