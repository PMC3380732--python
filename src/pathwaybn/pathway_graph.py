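"""Pathway-structure preprocessing and regulator extension.

A pathway is held as a :class:`networkx.DiGraph` whose nodes carry
``kind`` (``pathway_gene``, ``tf`` or ``mirna``) and ``feature`` (the
expression feature measuring the node: the gene itself for pathway nodes,
the encoding gene for a TF, the family id for a microRNA).  Edges carry an
``interaction`` label, although downstream inference only uses direction.

Preprocessing turns a curated pathway (KGML or an edge-list dialect) into a
DAG over measured genes: non-whitelisted interaction types are dropped at
parse time, cycle-closing edges are discarded, and unmeasured nodes are
bypassed by reconnecting their parents to their children.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import networkx as nx
from lxml import etree

from .ranking import ImportanceRanking, select_top
from .catalog import RegulatorCatalog

log = logging.getLogger(__name__)

__all__ = [
    "INTERACTION_WHITELIST",
    "parse_kgml",
    "read_edge_list",
    "make_acyclic",
    "restrict_to_measured",
    "extend_with_regulators",
]

#: interaction subtypes retained from a pathway map: gene-expression
#: relations (expression, repression, indirect effect) and protein-protein
#: interactions (activation, inhibition, indirect effect).
INTERACTION_WHITELIST = frozenset(
    {"expression", "repression", "activation", "inhibition", "indirect effect"}
)


def _new_graph() -> nx.DiGraph:
    return nx.DiGraph()


def _add_gene_node(g: nx.DiGraph, gene_id: str) -> None:
    g.add_node(gene_id, kind="pathway_gene", feature=gene_id)


def parse_kgml(source) -> nx.DiGraph:
    """Parse a KGML (KEGG Markup Language) pathway file into a directed graph.

    Multi-gene entries are expanded to one node per constituent gene id, all
    sharing the entry's edges; group entries are flattened to their member
    entries.  Only relations with a whitelisted subtype become edges;
    relations referencing unknown entries are skipped with a log message.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed KGML: {exc}") from exc
    root = tree.getroot()

    entry_genes: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "gene":
            entry_genes[eid] = entry.get("name", "").split()
        elif etype == "group":
            groups[eid] = [c.get("id") for c in entry.findall("component")]

    def resolve(eid: str) -> list[str]:
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in groups:
            out: list[str] = []
            for member in groups[eid]:
                out.extend(resolve(member))
            return out
        return []

    g = _new_graph()
    for genes in entry_genes.values():
        for gid in genes:
            _add_gene_node(g, gid)

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        sources, targets = resolve(e1), resolve(e2)
        if not sources or not targets:
            log.info("relation %s->%s references a non-gene entry; skipped", e1, e2)
            continue
        subtypes = [s.get("name", "").replace("_", " ") for s in rel.findall("subtype")]
        kept = [s for s in subtypes if s in INTERACTION_WHITELIST]
        if not kept:
            continue
        for u in sources:
            for v in targets:
                g.add_edge(u, v, interaction=kept[0])
    return g


def read_edge_list(path) -> nx.DiGraph:
    """Read the TSV edge-list dialect: source_gene, target_gene, interaction."""
    g = _new_graph()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("source"):
            fh.seek(0)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            interaction = parts[2] if len(parts) > 2 else "activation"
            _add_gene_node(g, parts[0])
            _add_gene_node(g, parts[1])
            g.add_edge(parts[0], parts[1], interaction=interaction)
    return g


def make_acyclic(g: nx.DiGraph) -> nx.DiGraph:
    """Discard edges that would close a directed cycle.

    Edges are considered in lexicographic (source, target) order and an edge
    is kept iff it does not create a cycle with the edges kept so far;
    self-loops are always discarded.  Idempotent, and the identity on DAGs.
    """
    out = _new_graph()
    out.add_nodes_from(g.nodes(data=True))
    for u, v, data in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])):
        if u == v:
            log.info("self-loop %s->%s discarded", u, v)
            continue
        if out.has_node(v) and nx.has_path(out, v, u):
            log.info("cycle-closing edge %s->%s discarded", u, v)
            continue
        out.add_edge(u, v, **data)
    return out


def restrict_to_measured(g: nx.DiGraph, measured: Iterable[str]) -> nx.DiGraph:
    """Remove nodes without expression data, bypassing them with new edges.

    For every removed node, each of its parents is connected to each of its
    children (edge labelled ``indirect``); applied until no unmeasured node
    remains.  Self-loops arising from a bypass are discarded and existing
    edges are not overwritten.  A DAG input yields a DAG output.
    """
    measured = set(measured)
    out = g.copy()
    for node in sorted(n for n in g.nodes if n not in measured):
        parents = list(out.predecessors(node))
        children = list(out.successors(node))
        out.remove_node(node)
        for p in parents:
            for c in children:
                if p == c or out.has_edge(p, c):
                    continue
                out.add_edge(p, c, interaction="indirect")
    if out.number_of_nodes() == 0:
        log.warning("no pathway node has expression data; empty graph returned")
    return out


def extend_with_regulators(
    g: nx.DiGraph,
    rankings: Mapping[str, Mapping[str, ImportanceRanking]],
    catalog: RegulatorCatalog,
    top_tf: int = 5,
    top_mirna: int = 3,
) -> nx.DiGraph:
    """Attach top-ranked TF and microRNA regulator nodes to the pathway DAG.

    For each pathway gene, edges are added from its up-to-``top_tf`` TFs and
    up-to-``top_mirna`` microRNAs whose permutation-importance score is
    strictly positive.  A regulator targeting several genes becomes a single
    node with multiple outgoing edges; a TF whose encoding gene (or a miRNA
    whose family id) is already a pathway node contributes nothing.
    Regulator nodes have in-degree 0, so acyclicity is preserved.
    """
    out = g.copy()
    pathway_nodes = set(g.nodes)
    for gene in sorted(pathway_nodes):
        gene_ranks = rankings.get(gene, {})
        for kind, cap in (("tf", top_tf), ("mirna", top_mirna)):
            ranking = gene_ranks.get(kind)
            if ranking is None:
                continue
            for reg in select_top(ranking, cap):
                feature = catalog.tf_encoding.get(reg, reg) if kind == "tf" else reg
                if feature in pathway_nodes or reg in pathway_nodes:
                    continue
                if not out.has_node(reg):
                    out.add_node(reg, kind=kind, feature=feature)
                out.add_edge(reg, gene, interaction="regulation")
    assert nx.is_directed_acyclic_graph(out)
    return out
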