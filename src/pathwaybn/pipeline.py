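"""Two-scenario inference and regulator calling.

Evidence is built per phenotype: each differentially expressed gene that is
a pathway node is clamped to the (lower) median of its discrete states over
that phenotype's samples.  The same Bayesian network is then queried under
the two evidence sets ("scenario #1" vs "scenario #2") and TF/microRNA
nodes whose posterior marginals contrast strongly between scenarios are
called as putative pathway regulators:

* ``threshold_cross`` — some state has probability above ``p_hi`` in one
  scenario and below it in the other;
* ``fold_change`` — some state shows at least a ``fold``-fold probability
  change, the larger probability exceeding ``p_min``.

Building the network twice, once per concurrent mRNA+microRNA dataset, and
intersecting the called regulators gives a two-variant cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bayes_net import (
    DiscreteBayesNet,
    GibbsConfig,
    PanelPool,
    build_bayes_net,
    exact_marginals,
    gibbs_marginals,
)
from .catalog import RegulatorCatalog
from .containers import MIRNA, DiscretePanel, ExpressionMatrix
from .discretize import discretize
from .pathway_graph import extend_with_regulators, make_acyclic, restrict_to_measured
from .ranking import build_training_table, rank_by_permutation_importance

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioEvidence",
    "RegulatorCall",
    "PipelineResult",
    "lower_median",
    "build_evidence",
    "run_scenarios",
    "call_regulators",
    "cross_validate_calls",
    "rank_all_genes",
    "run_end_to_end",
]


@dataclass
class ScenarioEvidence:
    """Evidence map (node → state 1..5) derived from one phenotype."""

    phenotype: str
    evidence: dict[str, int] = field(default_factory=dict)


@dataclass
class RegulatorCall:
    """One called regulator with the criterion that triggered it."""

    node_id: str
    kind: str
    criterion: str  # "threshold_cross" | "fold_change"
    state: int
    p_scenario1: float
    p_scenario2: float
    dataset_variant: str = ""


def lower_median(states) -> int:
    """Order statistic at position ceil(n/2) of the sorted states.

    For odd n this is the ordinary median; for even n the lower of the two
    middle values, which is always a valid state in 1..5.
    """
    s = np.sort(np.asarray(states, dtype=int))
    if s.size == 0:
        raise ValueError("cannot take the median of zero states")
    return int(s[(s.size - 1) // 2])


def build_evidence(
    panels: DiscretePanel | list[DiscretePanel],
    de_genes: list[str],
    pathway_nodes: set[str],
    phenotype: str,
) -> ScenarioEvidence:
    """Clamp each DE gene that is a pathway node to its phenotype median.

    The median is taken over all the gene's discrete values in the
    phenotype's samples, pooled across every panel that measures the gene.
    DE genes absent from all panels are skipped (logged); DE genes that are
    not pathway nodes (e.g. genes only present as TF regulators) are
    excluded.
    """
    if isinstance(panels, DiscretePanel):
        panels = [panels]
    if not any(p.samples_of(phenotype) for p in panels):
        raise ValueError(f"phenotype {phenotype!r} has no samples in the pool")
    ev: dict[str, int] = {}
    for gene in de_genes:
        if gene not in pathway_nodes:
            continue
        states = [
            p.states.loc[gene, p.samples_of(phenotype)].to_numpy()
            for p in panels
            if gene in p.states.index
        ]
        if not states:
            log.info("DE gene %s absent from every panel; skipped", gene)
            continue
        ev[gene] = lower_median(np.concatenate(states))
    return ScenarioEvidence(phenotype=phenotype, evidence=ev)


def run_scenarios(
    bn: DiscreteBayesNet,
    ev1: ScenarioEvidence,
    ev2: ScenarioEvidence,
    engine: str = "gibbs",
    cfg: GibbsConfig | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Posterior marginals of the same network under the two evidence sets.

    With the Gibbs engine the two runs use independent child seeds derived
    from ``cfg.seed``.
    """
    if engine == "exact":
        return exact_marginals(bn, ev1.evidence), exact_marginals(bn, ev2.evidence)
    if engine != "gibbs":
        raise ValueError(f"unknown engine {engine!r}")
    cfg = cfg or GibbsConfig()
    s1, s2 = (int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(2) >> 1)
    cfg1 = GibbsConfig(Q=cfg.Q, burn_in_frac=cfg.burn_in_frac, seed=s1)
    cfg2 = GibbsConfig(Q=cfg.Q, burn_in_frac=cfg.burn_in_frac, seed=s2)
    return gibbs_marginals(bn, ev1.evidence, cfg1), gibbs_marginals(bn, ev2.evidence, cfg2)


def call_regulators(
    m1: dict[str, np.ndarray],
    m2: dict[str, np.ndarray],
    network: nx.DiGraph,
    p_hi: float = 0.8,
    fold: float = 2.0,
    p_min: float = 0.5,
    kinds: tuple[str, ...] = ("tf", "mirna"),
    dataset_variant: str = "",
) -> list[RegulatorCall]:
    """Call regulator nodes whose marginals contrast between scenarios.

    Both criteria are two-sided (symmetric under swapping scenarios); one
    call per (node, criterion) records the state with the largest absolute
    probability difference among the states that fired.  By default only
    TF/miRNA nodes are examined (``kinds`` is configurable).
    """
    calls: list[RegulatorCall] = []
    for node in sorted(network.nodes):
        kind = network.nodes[node].get("kind", "pathway_gene")
        if kind not in kinds or node not in m1 or node not in m2:
            continue
        p1, p2 = m1[node], m2[node]
        fired: dict[str, list[int]] = {"threshold_cross": [], "fold_change": []}
        for s in range(5):
            a, b = float(p1[s]), float(p2[s])
            if (a > p_hi and b < p_hi) or (b > p_hi and a < p_hi):
                fired["threshold_cross"].append(s)
            hi, lo = max(a, b), min(a, b)
            fold_ok = (hi > p_min) if lo < 1e-6 else (hi / lo >= fold and hi > p_min)
            if fold_ok:
                fired["fold_change"].append(s)
        for criterion, states in fired.items():
            if not states:
                continue
            best = max(states, key=lambda s: abs(float(p1[s]) - float(p2[s])))
            calls.append(
                RegulatorCall(
                    node_id=node,
                    kind=kind,
                    criterion=criterion,
                    state=best + 1,
                    p_scenario1=float(p1[best]),
                    p_scenario2=float(p2[best]),
                    dataset_variant=dataset_variant,
                )
            )
    return calls


def cross_validate_calls(
    calls_a: list[RegulatorCall], calls_b: list[RegulatorCall]
) -> list[str]:
    """Node ids called (by any criterion) in both dataset-variant networks."""
    return sorted({c.node_id for c in calls_a} & {c.node_id for c in calls_b})


# ---------------------------------------------------------------------------
# end-to-end driver


def rank_all_genes(
    genes,
    catalog: RegulatorCatalog,
    mrna_panels: list[DiscretePanel],
    concurrent_panels: list[DiscretePanel],
    n_trees_tf: int = 2000,
    n_trees_mirna: int = 500,
    seed: int = 0,
):
    """Per-gene TF and miRNA importance rankings.

    TF tables pool the mRNA-only datasets; miRNA tables pool the concurrent
    mRNA+miRNA datasets (the only arrays measuring both kinds).  Per-gene
    seeds are derived from ``seed``.
    """
    rankings: dict[str, dict] = {}
    ss = np.random.SeedSequence(seed)
    genes = sorted(genes)
    child_seeds = (ss.generate_state(2 * len(genes)) >> 1).tolist()
    for i, gene in enumerate(genes):
        per_kind = {}
        for j, (kind, panels, n_trees) in enumerate(
            (
                ("tf", mrna_panels, n_trees_tf),
                ("mirna", concurrent_panels, n_trees_mirna),
            )
        ):
            cands = [
                (reg, catalog.feature_of(reg, kind))
                for reg in catalog.candidates(gene, kind)
            ]
            if not cands:
                continue
            table = build_training_table(gene, panels, cands)
            per_kind[kind] = rank_by_permutation_importance(
                table, n_trees=n_trees, seed=int(child_seeds[2 * i + j])
            )
        rankings[gene] = per_kind
    return rankings


@dataclass
class PipelineResult:
    network: nx.DiGraph
    rankings: dict
    calls: dict[str, list[RegulatorCall]]
    marginals: dict[str, tuple]
    intersection: list[str]


def run_end_to_end(
    datasets: list[ExpressionMatrix],
    pathway: nx.DiGraph,
    catalog: RegulatorCatalog,
    de_genes: list[str],
    method: str = "pam",
    top_tf: int = 5,
    top_mirna: int = 3,
    n_trees_tf: int = 400,
    n_trees_mirna: int = 200,
    engine: str = "exact",
    gibbs_cfg: GibbsConfig | None = None,
    seed: int = 0,
    p_hi: float = 0.8,
    fold: float = 2.0,
    p_min: float = 0.5,
) -> PipelineResult:
    """Full analysis: discretize → rank → extend → build BNs → call.

    ``datasets`` mixes mRNA-only panels with (at least one) concurrent
    mRNA+miRNA panels; one Bayesian network per concurrent variant is built
    and the called regulators are intersected across variants.
    """
    panels = [discretize(d, method=method) for d in datasets]
    mrna_panels = [p for p in panels if not p.mirna_features()]
    concurrent = [p for p in panels if p.mirna_features()]
    if not mrna_panels or not concurrent:
        raise ValueError("need at least one mRNA-only and one concurrent dataset")

    measured = set.intersection(
        *(set(p.feature_kind.index[p.feature_kind != MIRNA]) for p in panels)
    )
    g = restrict_to_measured(make_acyclic(pathway), measured)
    rankings = rank_all_genes(
        g.nodes, catalog, mrna_panels, concurrent,
        n_trees_tf=n_trees_tf, n_trees_mirna=n_trees_mirna, seed=seed,
    )
    network = extend_with_regulators(g, rankings, catalog, top_tf=top_tf, top_mirna=top_mirna)

    phenos = sorted(set().union(*(set(p.phenotype.unique()) for p in panels)))
    if len(phenos) != 2:
        raise ValueError(f"expected two phenotypes, found {phenos}")

    pathway_nodes = {n for n in network.nodes
                     if network.nodes[n].get("kind") == "pathway_gene"}
    calls: dict[str, list[RegulatorCall]] = {}
    marginals: dict[str, tuple] = {}
    ev1 = build_evidence(panels, de_genes, pathway_nodes, phenos[0])
    ev2 = build_evidence(panels, de_genes, pathway_nodes, phenos[1])
    for variant in concurrent:
        pool = PanelPool(mrna=mrna_panels, concurrent=variant)
        bn = build_bayes_net(network, pool)
        m1, m2 = run_scenarios(bn, ev1, ev2, engine=engine, cfg=gibbs_cfg)
        marginals[variant.name] = (m1, m2)
        calls[variant.name] = call_regulators(
            m1, m2, network, p_hi=p_hi, fold=fold, p_min=p_min,
            dataset_variant=variant.name,
        )
    names = sorted(calls)
    intersection = (
        cross_validate_calls(calls[names[0]], calls[names[1]])
        if len(names) >= 2
        else sorted({c.node_id for c in calls[names[0]]})
    )
    return PipelineResult(
        network=network, rankings=rankings, calls=calls,
        marginals=marginals, intersection=intersection,
    )
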