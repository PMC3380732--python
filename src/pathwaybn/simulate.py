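"""Seeded synthetic study generator.

Emulates the statistical shape of a multi-cohort two-phenotype expression
study: several mRNA-only datasets plus two concurrent mRNA+microRNA
datasets, a small curated pathway, candidate TF/microRNA catalogs, and one
or more *planted* regulators whose activity differs between phenotypes.

The generative model is linear-Gaussian on the continuous (log) scale,
before discretization: regulator activities are Gaussian with a phenotype
shift for planted regulators, target genes are baseline plus weighted
regulator activities (negative weights for microRNAs) plus propagated
parent-gene signal plus noise.  It is a test-bed for the pipeline, not a
model of microarray physics: probe effects, batch structure and
normalization artifacts are deliberately absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .bayes_net import CPT, DiscreteBayesNet, PanelPool, build_bayes_net
from .catalog import RegulatorCatalog
from .containers import MIRNA, MRNA, ExpressionMatrix
from .discretize import discretize
from .pathway_graph import make_acyclic
from .pipeline import lower_median

__all__ = [
    "PlantedRegulator",
    "SimulationConfig",
    "GroundTruth",
    "simulate_pathway",
    "simulate_catalog",
    "simulate_expression",
    "emit_fixture",
    "simulate_modal_panel",
    "toy_chain_network",
    "random_bayes_net",
]

GROUP_A = "groupA"
GROUP_B = "groupB"

#: weight of a planted regulator on its target gene (sign per regulator)
PLANTED_WEIGHT = 1.0
#: weight of non-planted catalog candidates: sequence-based candidate lists
#: are dominated by predictions with no condition-specific activity, so
#: non-planted candidates are decoys
BACKGROUND_WEIGHT = 0.0
#: propagation weight of a pathway parent's centred signal onto its child
EDGE_WEIGHT = 0.5


@dataclass
class PlantedRegulator:
    """A regulator whose activity differs between phenotypes.

    Pathway-level regulators typically drive several genes of a pathway,
    so ``target_genes`` is a tuple; each listed gene receives the full
    planted weight.
    """

    regulator_id: str
    kind: str  # "tf" | "mirna"
    target_genes: tuple[str, ...]
    effect_size: float = 2.0
    sign: int = 1
    elevated_phenotype: str = GROUP_A

    def __post_init__(self) -> None:
        if isinstance(self.target_genes, str):
            self.target_genes = (self.target_genes,)
        self.target_genes = tuple(self.target_genes)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe the desk-scale reference study: six mRNA-only
    datasets and two concurrent datasets with 40 samples per phenotype
    each, observation noise 0.5, one planted TF of effect size 2.0.
    """

    seed: int = 0
    n_pathway_genes: int = 5
    edge_density: float = 0.2
    inject_cycles: bool = False
    n_tf_pool: int = 12
    n_mirna_pool: int = 6
    tf_targets_per_gene: int = 4
    mirna_targets_per_gene: int = 2
    n_mrna_datasets: int = 6
    samples_per_dataset_per_phenotype: int = 40
    noise_sd: float = 0.5
    n_background_genes: int = 200
    planted_regulators: list[PlantedRegulator] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.planted_regulators:
            # a pathway-level master regulator drives several genes of the
            # pathway, not a single target
            self.planted_regulators = [
                PlantedRegulator("TF03", "tf", tuple(self.gene_ids()[:3]))
            ]
        for p in self.planted_regulators:
            if not np.isfinite(p.effect_size):
                raise ValueError("planted effect sizes must be finite")
            if p.kind == "mirna" and p.sign != -1:
                # microRNAs repress their targets
                raise ValueError("planted microRNA regulators must have sign -1")

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_pathway_genes)]

    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:02d}" for i in range(self.n_tf_pool)]

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:02d}" for i in range(self.n_mirna_pool)]

    @staticmethod
    def tf_encoding_gene(tf_id: str) -> str:
        return f"{tf_id}g"


@dataclass
class GroundTruth:
    de_genes: list[str]
    planted: list[PlantedRegulator]
    weights: dict[str, float]  # "gene|regulator" -> generative weight


def simulate_pathway(cfg: SimulationConfig) -> nx.DiGraph:
    """Random directed pathway at the requested edge density.

    Without cycle injection the edges point from lower to higher gene index
    (a DAG); with it, arbitrary ordered pairs are drawn and a back edge is
    added if needed so at least one directed cycle exists.
    """
    if cfg.n_pathway_genes < 2:
        raise ValueError("need at least 2 pathway genes")
    genes = cfg.gene_ids()
    n = len(genes)
    n_edges = int(round(cfg.edge_density * n * (n - 1)))
    if cfg.inject_cycles:
        candidates = [(i, j) for i in range(n) for j in range(n) if i != j]
    else:
        candidates = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if n_edges > len(candidates):
        raise ValueError(f"density implies {n_edges} edges, only {len(candidates)} possible")
    rng = np.random.default_rng(cfg.seed)
    chosen = [candidates[i] for i in rng.choice(len(candidates), size=n_edges, replace=False)]
    g = nx.DiGraph()
    for gid in genes:
        g.add_node(gid, kind="pathway_gene", feature=gid)
    for i, j in chosen:
        g.add_edge(genes[i], genes[j], interaction="activation")
    if cfg.inject_cycles and nx.is_directed_acyclic_graph(g):
        if chosen:
            i, j = chosen[0]
            g.add_edge(genes[j], genes[i], interaction="activation")
        else:
            g.add_edge(genes[1], genes[0], interaction="activation")
            g.add_edge(genes[0], genes[1], interaction="activation")
    return g


def simulate_catalog(cfg: SimulationConfig, pathway: nx.DiGraph) -> RegulatorCatalog:
    """Seeded random candidate lists, with planted regulators guaranteed to
    appear among their target's candidates."""
    rng = np.random.default_rng(cfg.seed + 1)
    tfs, mirs = cfg.tf_ids(), cfg.mirna_ids()
    if cfg.tf_targets_per_gene > len(tfs) or cfg.mirna_targets_per_gene > len(mirs):
        raise ValueError("regulator pools smaller than targets_per_gene")
    tf_targets, mirna_targets = {}, {}
    for gene in sorted(pathway.nodes):
        tf_targets[gene] = [
            tfs[i] for i in rng.choice(len(tfs), size=cfg.tf_targets_per_gene, replace=False)
        ]
        mirna_targets[gene] = [
            mirs[i] for i in rng.choice(len(mirs), size=cfg.mirna_targets_per_gene, replace=False)
        ]
    for p in cfg.planted_regulators:
        table = tf_targets if p.kind == "tf" else mirna_targets
        for gene in p.target_genes:
            lst = table.setdefault(gene, [])
            if p.regulator_id not in lst:
                if lst:
                    lst[-1] = p.regulator_id
                else:
                    lst.append(p.regulator_id)
    return RegulatorCatalog(
        tf_targets=tf_targets,
        tf_encoding={tf: cfg.tf_encoding_gene(tf) for tf in tfs},
        mirna_targets=mirna_targets,
    )


def _regulator_weights(cfg: SimulationConfig, catalog: RegulatorCatalog) -> dict[tuple[str, str], float]:
    weights: dict[tuple[str, str], float] = {}
    for gene, regs in catalog.tf_targets.items():
        for reg in regs:
            weights[(gene, reg)] = BACKGROUND_WEIGHT
    for gene, regs in catalog.mirna_targets.items():
        for reg in regs:
            weights[(gene, reg)] = -BACKGROUND_WEIGHT
    for p in cfg.planted_regulators:
        for gene in p.target_genes:
            weights[(gene, p.regulator_id)] = p.sign * PLANTED_WEIGHT
    return weights


def simulate_expression(
    cfg: SimulationConfig, pathway: nx.DiGraph, catalog: RegulatorCatalog
) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """Generate the multi-dataset panels and the generative ground truth.

    Emits ``cfg.n_mrna_datasets`` mRNA-only panels (pathway genes,
    background genes, TF-encoding genes) plus two concurrent panels that
    additionally measure the microRNA families, each with independent noise.
    """
    master = np.random.SeedSequence(cfg.seed + 2)
    rng0 = np.random.default_rng(master.spawn(1)[0])
    genes = cfg.gene_ids()
    tfs, mirs = cfg.tf_ids(), cfg.mirna_ids()
    background = [f"BG{i + 1:03d}" for i in range(cfg.n_background_genes)]
    regulators = tfs + mirs
    base_activity = {r: float(rng0.normal(0, 1)) for r in regulators}
    # background features span a wide log-intensity range (as on real
    # arrays); pathway genes sit in the mid-dynamic-range where a phenotype
    # shift remains visible after discretization
    baseline = {g: float(rng0.normal(0, 1.5)) for g in genes}
    baseline.update({g: float(rng0.normal(0, 3.0)) for g in background})
    weights = _regulator_weights(cfg, catalog)
    planted = {p.regulator_id: p for p in cfg.planted_regulators}
    dag = pathway if nx.is_directed_acyclic_graph(pathway) else make_acyclic(pathway)
    topo = [g for g in nx.topological_sort(dag) if g in genes]
    topo += [g for g in genes if g not in topo]

    dataset_names = [f"mrna{i + 1}" for i in range(cfg.n_mrna_datasets)] + [
        "concurrent1",
        "concurrent2",
    ]
    streams = master.spawn(len(dataset_names))
    panels: list[ExpressionMatrix] = []
    n_per = cfg.samples_per_dataset_per_phenotype
    for name, stream in zip(dataset_names, streams):
        rng = np.random.default_rng(stream)
        sample_ids = [f"{name}_s{i + 1:03d}" for i in range(2 * n_per)]
        pheno = pd.Series(
            [GROUP_A] * n_per + [GROUP_B] * n_per, index=sample_ids, name="phenotype"
        )
        elevated = {
            r: np.array([
                1.0 if planted[r].elevated_phenotype == ph else 0.0 for ph in pheno
            ]) if r in planted else 0.0
            for r in regulators
        }
        # activity noise is paired across the two phenotype blocks (common
        # random numbers), so a zero planted effect leaves the group means
        # exactly equal
        activity = {
            r: base_activity[r]
            + (planted[r].effect_size * elevated[r] if r in planted else 0.0)
            + np.tile(rng.normal(0, 1, size=n_per), 2)
            for r in regulators
        }
        rows: dict[str, np.ndarray] = {}
        signal: dict[str, np.ndarray] = {}
        for gene in topo:
            x = baseline[gene] + rng.normal(0, cfg.noise_sd, size=2 * n_per)
            for kind, table in (("tf", catalog.tf_targets), ("mirna", catalog.mirna_targets)):
                for reg in table.get(gene, []):
                    x = x + weights[(gene, reg)] * activity[reg]
            for parent in dag.predecessors(gene):
                x = x + EDGE_WEIGHT * signal[parent]
            rows[gene] = x
            signal[gene] = x - baseline[gene]
        for bg in background:
            rows[bg] = baseline[bg] + rng.normal(0, 1.0, size=2 * n_per)
        for tf in tfs:
            rows[cfg.tf_encoding_gene(tf)] = activity[tf] + rng.normal(
                0, cfg.noise_sd, size=2 * n_per
            )
        concurrent = name.startswith("concurrent")
        if concurrent:
            for mir in mirs:
                rows[mir] = activity[mir] + rng.normal(0, cfg.noise_sd, size=2 * n_per)
        feature_ids = list(rows)
        kind = pd.Series(
            [MIRNA if f in mirs else MRNA for f in feature_ids],
            index=feature_ids, name="kind",
        )
        values = pd.DataFrame(
            np.vstack([rows[f] for f in feature_ids]), index=feature_ids, columns=sample_ids
        )
        panels.append(ExpressionMatrix(values, pheno, kind, name=name))

    # empirical DE truth: pathway genes whose phenotype means, pooled over
    # all datasets, differ by more than one noise_sd
    de_genes = []
    for gene in genes:
        a = np.concatenate([
            p.values.loc[gene, p.samples_of(GROUP_A)].to_numpy() for p in panels
        ])
        b = np.concatenate([
            p.values.loc[gene, p.samples_of(GROUP_B)].to_numpy() for p in panels
        ])
        if abs(a.mean() - b.mean()) > cfg.noise_sd:
            de_genes.append(gene)
    truth = GroundTruth(
        de_genes=de_genes,
        planted=list(cfg.planted_regulators),
        weights={f"{g}|{r}": w for (g, r), w in sorted(weights.items())},
    )
    return panels, truth


def emit_fixture(cfg: SimulationConfig, out_dir) -> list[Path]:
    """Write the whole synthetic study as plain-text files.

    One ``<dataset>.expr.tsv`` per panel (feature_id, kind, samples...) plus
    four metadata files: samples.tsv, pathway.tsv, catalog.tsv and
    ground_truth.json (which carries the DE-gene list).  Byte-identical for
    identical configs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pathway = simulate_pathway(cfg)
    catalog = simulate_catalog(cfg, pathway)
    panels, truth = simulate_expression(cfg, pathway, catalog)
    written: list[Path] = []

    sample_rows = []
    for p in panels:
        frame = p.values.copy()
        frame.insert(0, "kind", p.feature_kind)
        path = out / f"{p.name}.expr.tsv"
        frame.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6f")
        written.append(path)
        for sid in p.sample_ids:
            sample_rows.append((sid, p.phenotype[sid], p.name))

    path = out / "samples.tsv"
    pd.DataFrame(sample_rows, columns=["sample_id", "phenotype", "dataset_name"]).to_csv(
        path, sep="\t", index=False
    )
    written.append(path)

    path = out / "pathway.tsv"
    with open(path, "w") as fh:
        fh.write("source\ttarget\tinteraction\n")
        for u, v, data in sorted(pathway.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('interaction', 'activation')}\n")
    written.append(path)

    path = out / "catalog.tsv"
    with open(path, "w") as fh:
        fh.write("target_gene\tregulator_id\tregulator_kind\tencoding_gene\n")
        for gene in sorted(catalog.tf_targets):
            for tf in catalog.tf_targets[gene]:
                fh.write(f"{gene}\t{tf}\ttf\t{catalog.tf_encoding[tf]}\n")
        for gene in sorted(catalog.mirna_targets):
            for mir in catalog.mirna_targets[gene]:
                fh.write(f"{gene}\t{mir}\tmirna\t{mir}\n")
    written.append(path)

    path = out / "ground_truth.json"
    payload = {
        "de_genes": truth.de_genes,
        "planted": [asdict(p) for p in truth.planted],
        "weights": truth.weights,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# auxiliary generators used for calibration and benchmarking


def simulate_modal_panel(
    n_features: int = 200,
    n_per_group: int = 30,
    n_de: int = 20,
    mode_centers: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0),
    mode_weights: tuple[float, ...] = (0.35, 0.10, 0.25, 0.10, 0.20),
    mode_sd: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Panel with five well-separated per-array expression modes.

    Each feature occupies one mode (unequal occupancies, so quantile bins do
    not align with the modes); differentially expressed features shift by
    one mode between the two phenotypes.  Returns the panel and its DE ids.
    """
    rng = np.random.default_rng(seed)
    k = len(mode_centers)
    features = [f"F{i + 1:03d}" for i in range(n_features)]
    modes = rng.choice(k, size=n_features, p=np.asarray(mode_weights) / sum(mode_weights))
    de = sorted(rng.choice(n_features, size=n_de, replace=False).tolist())
    de_set = set(de)
    centers = np.asarray(mode_centers)
    sample_ids = [f"s{i + 1:03d}" for i in range(2 * n_per_group)]
    pheno = pd.Series(
        [GROUP_A] * n_per_group + [GROUP_B] * n_per_group, index=sample_ids
    )
    values = np.empty((n_features, 2 * n_per_group))
    for i in range(n_features):
        m = np.full(2 * n_per_group, modes[i])
        if i in de_set:
            shift = 1 if modes[i] < k - 1 else -1
            m[n_per_group:] = modes[i] + shift
        values[i] = centers[m] + rng.normal(0, mode_sd, size=2 * n_per_group)
    kind = pd.Series(MRNA, index=features)
    panel = ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=sample_ids), pheno, kind,
        name="modal",
    )
    return panel, [features[i] for i in de]


def toy_chain_network(
    seed: int = 0, n_arrays: int = 100, method: str = "quantile"
) -> tuple[DiscreteBayesNet, dict[str, int]]:
    """16-node calibration toy: 3 chained pathway genes + 13 root regulators.

    Mirrors the structure used to calibrate the Gibbs sampling rate: three
    pathway nodes in a chain, each additionally targeted by its own TFs and
    one microRNA (5 + 4 + 4 regulators).  CPTs are estimated by smoothed
    counting on a discretized panel simulated from a linear-Gaussian model;
    the middle pathway gene is clamped to its median state as evidence.
    """
    regulator_map = {
        "g1": ["t01", "t02", "t03", "t04", "m01"],
        "g2": ["t05", "t06", "t07", "m02"],
        "g3": ["t08", "t09", "t10", "m03"],
    }
    rng = np.random.default_rng(seed)
    activities = {
        r: rng.normal(0, 1, size=n_arrays)
        for regs in regulator_map.values()
        for r in regs
    }
    rows = dict(activities)
    prev = None
    for gene, regs in regulator_map.items():
        x = rng.normal(0, 0.5, size=n_arrays)
        for r in regs:
            w = -0.8 if r.startswith("m") else 0.8
            x = x + w * activities[r]
        if prev is not None:
            x = x + 0.6 * rows[prev]
        rows[gene] = x
        prev = gene
    features = sorted(rows)
    sample_ids = [f"a{i + 1:03d}" for i in range(n_arrays)]
    pheno = pd.Series(
        [GROUP_A] * (n_arrays // 2) + [GROUP_B] * (n_arrays - n_arrays // 2),
        index=sample_ids,
    )
    kind = pd.Series(
        [MIRNA if f.startswith("m0") else MRNA for f in features], index=features
    )
    expr = ExpressionMatrix(
        pd.DataFrame(np.vstack([rows[f] for f in features]), index=features,
                     columns=sample_ids),
        pheno, kind, name="toy",
    )
    panel = discretize(expr, method=method)

    g = nx.DiGraph()
    for gene, regs in regulator_map.items():
        g.add_node(gene, kind="pathway_gene", feature=gene)
        for r in regs:
            g.add_node(r, kind="mirna" if r.startswith("m") else "tf", feature=r)
            g.add_edge(r, gene)
    g.add_edge("g1", "g2")
    g.add_edge("g2", "g3")
    bn = build_bayes_net(g, PanelPool(mrna=[panel], concurrent=panel))
    evidence = {"g2": lower_median(panel.states.loc["g2"])}
    return bn, evidence


def random_bayes_net(n_nodes: int, seed: int = 0, max_parents: int = 3) -> DiscreteBayesNet:
    """Random DAG with Dirichlet CPTs, for benchmarking the exact engine."""
    rng = np.random.default_rng(seed)
    names = [f"n{i:02d}" for i in range(n_nodes)]
    g = nx.DiGraph()
    cpts: dict[str, CPT] = {}
    for i, name in enumerate(names):
        g.add_node(name, kind="pathway_gene", feature=name)
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parents = sorted(
            names[j] for j in rng.choice(i, size=k, replace=False)
        ) if k else []
        for p in parents:
            g.add_edge(p, name)
        shape = (5,) * (len(parents) + 1)
        table = rng.dirichlet(np.ones(5), size=shape[:-1]).reshape(shape)
        cpts[name] = CPT(node=name, parents=tuple(parents), table=table)
    return DiscreteBayesNet(graph=g, cpts=cpts)
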