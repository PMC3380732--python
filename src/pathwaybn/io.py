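"""Plain-text readers and writers for the pipeline's file formats.

All formats are TSV (or JSON for networks and calls):

* expression: first column ``feature_id``, second ``kind`` (mRNA/miRNA),
  remaining columns one per sample;
* sample metadata: ``sample_id``, ``phenotype``, ``dataset_name``;
* detection calls: ``feature_id`` then one column per sample, values P/M/A;
* discrete panels: like expression but integer states 1..5;
* regulator catalog: ``target_gene``, ``regulator_id``, ``regulator_kind``,
  ``encoding_gene``;
* pathway edge list: ``source``, ``target``, ``interaction``;
* rankings: ``gene_id``, ``regulator_id``, ``regulator_kind``, ``score``,
  ``rank``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .catalog import RegulatorCatalog
from .containers import DiscretePanel, ExpressionMatrix
from .pipeline import RegulatorCall
from .ranking import ImportanceRanking


def read_samples(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return meta.set_index("sample_id")


def read_expression(expr_path, samples_path, calls_path=None, name=None) -> ExpressionMatrix:
    frame = pd.read_csv(expr_path, sep="\t", index_col="feature_id")
    kind = frame.pop("kind")
    meta = read_samples(samples_path)
    pheno = meta.loc[frame.columns, "phenotype"]
    calls = None
    if calls_path is not None:
        calls = pd.read_csv(calls_path, sep="\t", index_col="feature_id")
    if name is None:
        name = meta.loc[frame.columns[0], "dataset_name"] if "dataset_name" in meta else Path(expr_path).stem
    return ExpressionMatrix(frame.astype(float), pheno, kind, present_calls=calls, name=str(name))


def write_panel(panel: DiscretePanel, path) -> None:
    frame = panel.states.copy()
    frame.insert(0, "kind", panel.feature_kind)
    frame.to_csv(path, sep="\t", index_label="feature_id")


def read_panel(path, samples_path, name=None) -> DiscretePanel:
    frame = pd.read_csv(path, sep="\t", index_col="feature_id")
    kind = frame.pop("kind")
    meta = read_samples(samples_path)
    pheno = meta.loc[frame.columns, "phenotype"]
    if name is None:
        name = meta.loc[frame.columns[0], "dataset_name"] if "dataset_name" in meta else Path(path).stem
    return DiscretePanel(frame.astype(int), pheno, kind, name=str(name))


def read_catalog(path) -> RegulatorCatalog:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    tf_targets: dict[str, list[str]] = {}
    mirna_targets: dict[str, list[str]] = {}
    tf_encoding: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        if row.regulator_kind == "tf":
            tf_targets.setdefault(row.target_gene, []).append(row.regulator_id)
            tf_encoding[row.regulator_id] = row.encoding_gene
        else:
            mirna_targets.setdefault(row.target_gene, []).append(row.regulator_id)
    return RegulatorCatalog(tf_targets=tf_targets, tf_encoding=tf_encoding,
                            mirna_targets=mirna_targets)


def write_graph(g: nx.DiGraph, prefix) -> tuple[Path, Path]:
    prefix = Path(prefix)
    edges = prefix.with_suffix(".edges.tsv")
    nodes = prefix.with_suffix(".nodes.tsv")
    with open(edges, "w") as fh:
        fh.write("source\ttarget\tinteraction\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('interaction', '')}\n")
    with open(nodes, "w") as fh:
        fh.write("node_id\tkind\tfeature\n")
        for n in sorted(g.nodes):
            attrs = g.nodes[n]
            fh.write(f"{n}\t{attrs.get('kind', 'pathway_gene')}\t{attrs.get('feature', n)}\n")
    return edges, nodes


def read_graph(prefix) -> nx.DiGraph:
    prefix = Path(prefix)
    g = nx.DiGraph()
    nodes = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", dtype=str)
    for row in nodes.itertuples(index=False):
        g.add_node(row.node_id, kind=row.kind, feature=row.feature)
    edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t", dtype=str)
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, interaction=row.interaction or "")
    return g


def write_rankings(rankings: dict[str, dict[str, ImportanceRanking]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tregulator_id\tregulator_kind\tscore\trank\n")
        for gene in sorted(rankings):
            for kind in sorted(rankings[gene]):
                for rank, (reg, score) in enumerate(rankings[gene][kind].entries, start=1):
                    fh.write(f"{gene}\t{reg}\t{kind}\t{score:.6g}\t{rank}\n")


def read_rankings(path) -> dict[str, dict[str, ImportanceRanking]]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, ImportanceRanking]] = {}
    for (gene, kind), grp in frame.groupby(["gene_id", "regulator_kind"], sort=True):
        entries = [(str(r.regulator_id), float(r.score)) for r in grp.itertuples(index=False)]
        out.setdefault(str(gene), {})[str(kind)] = ImportanceRanking(str(gene), entries)
    return out


def read_evidence(path) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    return {str(r[0]): int(r[1]) for r in frame.itertuples(index=False)}


def write_marginals(marginals: dict, path, scenario: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tp1\tp2\tp3\tp4\tp5\tscenario\n")
        for node in sorted(marginals):
            probs = "\t".join(f"{p:.6f}" for p in marginals[node])
            fh.write(f"{node}\t{probs}\t{scenario}\n")


def write_calls(calls: list[RegulatorCall], path) -> None:
    Path(path).write_text(
        json.dumps([dataclasses.asdict(c) for c in calls], indent=1)
    )


def read_calls(path) -> list[RegulatorCall]:
    return [RegulatorCall(**rec) for rec in json.loads(Path(path).read_text())]
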