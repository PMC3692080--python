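"""Ontology DAG handling: OBO IO, true-path annotation propagation, DOT export.

A term's gene set under the true-path rule contains every gene directly
annotated to the term or to any of its descendants, so "every term becomes
a gene set".  Propagation follows is_a and part_of edges only, and never
crosses namespaces (GO namespace roots are disjoint).  Enriched terms plus
their ancestor closure can be exported as a Graphviz DOT hierarchy chart
with significance-binned node colors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import obonet

from .geneset_io import Category, GeneSet, GeneSetCollection

__all__ = [
    "OntologyGraph",
    "AnnotationTable",
    "read_obo",
    "write_obo",
    "read_annotations",
    "propagate_annotations",
    "enriched_subgraph",
    "render_dot",
    "DEFAULT_BINS",
]

#: relations that carry the true-path rule
PROPAGATING_RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyGraph:
    """A DAG of terms with child->parent is_a/part_of edges.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point from child
    to parent; node attributes are ``name`` and ``namespace``.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology graph contains a cycle through {cycle[0][0]!r}")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def roots(self) -> frozenset[str]:
        """Terms with no parent."""
        return frozenset(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "")

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` along child->parent edges."""
        return frozenset(nx.descendants(self.graph, term))

    def descendants(self, term: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self.graph, term))

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self.graph


@dataclass
class AnnotationTable:
    """Deduplicated direct (gene, term) annotation pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = frozenset(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def read_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2 subset file.

    Obsolete terms are excluded.  Both ``is_a`` and ``relationship: part_of``
    become child->parent edges; other relationship types are dropped with a
    warning.  Raises on cycles and on edges pointing at undefined terms.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node),
                   namespace=data.get("namespace", ""))
    dropped: set[str] = set()
    for child, parent, rel in multi.edges(keys=True):
        if rel not in PROPAGATING_RELATIONS:
            dropped.add(rel)
            continue
        if parent not in multi.nodes or "name" not in multi.nodes[parent]:
            raise ValueError(f"term {child!r} references undefined parent {parent!r}")
        g.add_edge(child, parent, relation=rel)
    if dropped:
        warnings.warn(
            f"ignored non-propagating relationship types: {sorted(dropped)}",
            UserWarning, stacklevel=2)
    return OntologyGraph(graph=g)


def write_obo(onto: OntologyGraph, path: str | Path) -> None:
    """Write the graph back out as minimal OBO 1.2 [Term] stanzas."""
    g = onto.graph
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: synthetic\n")
        for term in sorted(g.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {onto.name(term)}\n")
            ns = onto.namespace(term)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for _, parent, data in sorted(g.out_edges(term, data=True)):
                if data.get("relation", "is_a") == "is_a":
                    fh.write(f"is_a: {parent} ! {onto.name(parent)}\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! {onto.name(parent)}\n")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a two-column (gene, term) TSV; a header starting with 'gene' is skipped."""
    pairs: set[tuple[str, str]] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and cols[0].lower().startswith("gene"):
                continue
            pairs.add((cols[0].strip(), cols[1].strip()))
    return AnnotationTable(pairs=frozenset(pairs))


def propagate_annotations(
    onto: OntologyGraph,
    direct: AnnotationTable,
    on_unknown_term: str = "warn",
) -> GeneSetCollection:
    """Materialize the true-path rule: one GO-category gene set per term.

    A term's members are the genes directly annotated to it or to any
    descendant.  Terms with no genes after propagation get no set.
    Annotations to terms absent from the graph are skipped with a warning
    (``on_unknown_term='warn'``, default) or raise (``'error'``).
    """
    if on_unknown_term not in ("warn", "error"):
        raise ValueError("on_unknown_term must be 'warn' or 'error'")
    genes_at: dict[str, set[str]] = {t: set() for t in onto.graph.nodes}
    unknown = 0
    for gene, term in direct.pairs:
        if term not in genes_at:
            if on_unknown_term == "error":
                raise ValueError(f"annotation to unknown term {term!r}")
            unknown += 1
            continue
        genes_at[term].add(gene)
    if unknown:
        warnings.warn(f"skipped {unknown} annotations to unknown terms",
                      UserWarning, stacklevel=2)
    # children precede parents in topological order of child->parent edges,
    # so a single pass accumulates each term's descendant union
    for term in nx.topological_sort(onto.graph):
        members = genes_at[term]
        for _, parent in onto.graph.out_edges(term):
            genes_at[parent] |= members
    sets = [
        GeneSet(name=term, description=onto.name(term),
                members=frozenset(members), category=Category.GO)
        for term in sorted(genes_at)
        if (members := genes_at[term])
    ]
    return GeneSetCollection(sets=sets)


def enriched_subgraph(
    onto: OntologyGraph,
    significant: Sequence[tuple[str, float]],
) -> nx.DiGraph:
    """Induce the subgraph of significant terms plus all their ancestors.

    Each node carries ``p_adjusted`` (float for significant terms, ``None``
    for ancestor-only context nodes) and the term ``name``.  An empty
    significant list yields an empty graph.
    """
    for term, _ in significant:
        if term not in onto:
            raise KeyError(f"term {term!r} not in ontology graph")
    keep: set[str] = set()
    for term, _ in significant:
        keep.add(term)
        keep |= onto.ancestors(term)
    sub = onto.graph.subgraph(keep).copy()
    p_by_term = dict(significant)
    for node in sub.nodes:
        sub.nodes[node]["p_adjusted"] = p_by_term.get(node)
    return sub


#: default significance bins: upper p edges mapped dark-to-light
DEFAULT_BINS: tuple[tuple[float, str], ...] = (
    (1e-10, "#b30000"),
    (1e-5, "#e34a33"),
    (0.01, "#fc8d59"),
    (0.05, "#fdcc8a"),
)


def _fill_color(p: Optional[float], bins: Sequence[tuple[float, str]]) -> Optional[str]:
    if p is None:
        return None
    for edge, color in bins:
        if p < edge:
            return color
    return bins[-1][1]


def render_dot(
    subgraph: nx.DiGraph,
    bins: Sequence[tuple[float, str]] = DEFAULT_BINS,
) -> str:
    """Emit a deterministic Graphviz DOT digraph of the enriched hierarchy.

    Node fill color encodes the adjusted-p bin; ancestor-only nodes are
    left uncolored.  Labels carry term name, term ID, and adjusted p when
    present.  Edges point parent->child so the chart reads roots-down.
    """
    lines = ["digraph enrichment_hierarchy {",
             '  rankdir="BT";',
             '  node [shape=box, style="rounded,filled", fillcolor="white"];']
    for node in sorted(subgraph.nodes):
        data = subgraph.nodes[node]
        p = data.get("p_adjusted")
        label_parts = [data.get("name", node), node]
        if p is not None:
            label_parts.append(f"p_adj={p:.3g}")
        label = "\\n".join(s.replace('"', r"\"") for s in label_parts)
        color = _fill_color(p, bins)
        attrs = [f'label="{label}"']
        if color is not None:
            attrs.append(f'fillcolor="{color}"')
        lines.append(f'  "{node}" [{", ".join(attrs)}];')
    for child, parent in sorted(subgraph.edges):
        rel = subgraph.edges[child, parent].get("relation", "is_a")
        style = "" if rel == "is_a" else ' [style=dashed]'
        lines.append(f'  "{child}" -> "{parent}"{style};')
    lines.append("}")
    return "\n".join(lines) + "\n"
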