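"""Discrete five-state Bayesian networks on extended pathway graphs.

The network skeleton is the extended pathway DAG.  Each node has a
conditional probability table (CPT) estimated by counting discretized
observation vectors into a table initialized with ones (add-one smoothing),
so every conditional distribution is strictly positive.  Which microarrays
supply the counts follows the dataset-selection rule: if a node or any of
its parents is a microRNA, the concurrent mRNA+microRNA dataset is used
(only those arrays measure both kinds); otherwise the pooled mRNA-only
datasets are used.

Two inference engines compute posterior marginals P(X_i | e):

* :func:`exact_marginals` — variable elimination with a min-fill ordering,
  feasible for the toy-scale networks used for calibration;
* :func:`gibbs_marginals` — a single-chain Gibbs sampler that resamples
  every unobserved node from its full conditional each sweep and estimates
  marginals from post-burn-in state frequencies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import DiscretePanel

log = logging.getLogger(__name__)

N_STATES = 5

#: intermediate factors in variable elimination are refused beyond this size
_MAX_FACTOR_CELLS = N_STATES**13

__all__ = [
    "CPT",
    "DiscreteBayesNet",
    "GibbsConfig",
    "PanelPool",
    "n_parent_configurations",
    "count_table",
    "estimate_prior",
    "estimate_cpt",
    "build_bayes_net",
    "joint_probability",
    "exact_marginals",
    "gibbs_marginals",
    "approximation_error",
    "bn_to_json",
    "bn_from_json",
]


def n_parent_configurations(n_parents: int, n_states: int = N_STATES) -> int:
    """Number of joint parent-state configurations of a CPT (exact integer).

    Grows as n_states**n_parents; a node with 100 five-state parents already
    has 5**100 configurations, which is why the number of regulator parents
    per gene must be capped upstream.
    """
    return n_states**n_parents


@dataclass
class CPT:
    """Conditional probability table P(node | parents).

    ``table`` has shape (5,)*p + (5,), axes ordered as (parents..., node)
    with parents sorted lexicographically; every parent-configuration slice
    along the last axis sums to 1 and is strictly positive.
    """

    node: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        expected = (N_STATES,) * (len(self.parents) + 1)
        if self.table.shape != expected:
            raise ValueError(f"CPT shape {self.table.shape} != {expected}")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("CPT slices must sum to 1")
        if not (self.table > 0).all():
            raise ValueError("CPT entries must be strictly positive (smoothed)")


@dataclass
class GibbsConfig:
    """Gibbs sampler configuration.

    ``Q`` is the sampling rate per node: the chain draws Q × n_nodes network
    samples in total (one sample = the network state after one sweep over
    all unobserved nodes).  The first ``burn_in_frac`` of samples are
    discarded before counting state frequencies.
    """

    Q: int = 250
    burn_in_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")


@dataclass
class PanelPool:
    """Discretized datasets available for CPT estimation.

    ``mrna`` holds the mRNA-only panels (pooled for nodes with no microRNA
    in scope); ``concurrent`` is one concurrent mRNA+microRNA panel (used
    whenever a microRNA is in scope).
    """

    mrna: list[DiscretePanel]
    concurrent: DiscretePanel

    def select(self, any_mirna: bool) -> tuple[list[DiscretePanel], str]:
        if any_mirna:
            return [self.concurrent], "concurrent_pool"
        return list(self.mrna), "mrna_pool"


@dataclass
class DiscreteBayesNet:
    """DAG plus per-node CPTs (roots carry a prior 5-vector as a 1-D CPT)."""

    graph: nx.DiGraph
    cpts: dict[str, CPT]
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("network must be acyclic")
        for node in self.graph.nodes:
            cpt = self.cpts.get(node)
            if cpt is None:
                raise ValueError(f"node {node!r} has no CPT")
            if tuple(sorted(self.graph.predecessors(node))) != cpt.parents:
                raise ValueError(f"CPT parents of {node!r} do not match the graph")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def _observation_matrix(features: list[str], panels: list[DiscretePanel]) -> np.ndarray:
    """Stack observation vectors (rows) for ``features`` over all arrays of
    the panels that measure every feature; panels missing a feature are
    skipped with a log message."""
    blocks = []
    for panel in panels:
        missing = [f for f in features if f not in panel.states.index]
        if missing:
            log.info("panel %s lacks %s; its arrays are skipped", panel.name, missing)
            continue
        blocks.append(panel.states.loc[features].to_numpy().T)
    if not blocks:
        return np.empty((0, len(features)), dtype=int)
    return np.vstack(blocks)


def count_table(observations: np.ndarray, n_vars: int) -> np.ndarray:
    """All-ones-initialized count table over (vars...) accumulated from
    observation vectors with entries in 1..5.

    The total mass is 5**n_vars + number of observations.
    """
    counts = np.ones((N_STATES,) * n_vars)
    if observations.size:
        idx = tuple(observations[:, i] - 1 for i in range(n_vars))
        np.add.at(counts, idx, 1.0)
    return counts


def estimate_prior(node: str, panels: list[DiscretePanel]) -> np.ndarray:
    """Add-one smoothed state frequencies: (count_s + 1) / (M + 5)."""
    obs = _observation_matrix([node], panels)
    if not any(node in p.states.index for p in panels):
        raise KeyError(f"node {node!r} absent from the selected pool")
    counts = count_table(obs, 1)
    return counts / counts.sum()


def estimate_cpt(node: str, parents: list[str], panels: list[DiscretePanel]) -> CPT:
    """Estimate P(node | parents) by smoothed counting over the pool.

    Observation vectors are (parent states..., node state) per array; each
    parent-configuration slice of the all-ones-initialized count table is
    normalized independently into a conditional distribution.
    """
    parents = sorted(parents)
    scope = parents + [node]
    for var in scope:
        if not any(var in p.states.index for p in panels):
            pool_names = [p.name for p in panels]
            raise KeyError(f"variable {var!r} not measured in pool {pool_names}")
    obs = _observation_matrix(scope, panels)
    counts = count_table(obs, len(scope))
    table = counts / counts.sum(axis=-1, keepdims=True)
    return CPT(node=node, parents=tuple(parents), table=table)


def build_bayes_net(network: nx.DiGraph, pool: PanelPool) -> DiscreteBayesNet:
    """Estimate every CPT of the extended-pathway network from the pool.

    A node's observations come from the concurrent panel iff the node or one
    of its parents is a microRNA; otherwise from the pooled mRNA datasets.
    Node ids are kept as-is (regulator ids for TF/miRNA nodes); observations
    are looked up through the ``feature`` node attribute (identity when
    absent), e.g. a TF node reads the expression of its encoding gene.
    """
    def feature(n: str) -> str:
        return network.nodes[n].get("feature", n)

    def is_mirna(n: str) -> bool:
        return network.nodes[n].get("kind") == "mirna"

    cpts: dict[str, CPT] = {}
    source: dict[str, str] = {}
    for node in network.nodes:
        parents = tuple(sorted(network.predecessors(node)))
        any_mirna = is_mirna(node) or any(is_mirna(p) for p in parents)
        panels, tag = pool.select(any_mirna)
        scope = [feature(p) for p in parents] + [feature(node)]
        for var in scope:
            if not any(var in p.states.index for p in panels):
                raise KeyError(f"variable {var!r} not measured in the {tag}")
        obs = _observation_matrix(scope, panels)
        counts = count_table(obs, len(scope))
        table = counts / counts.sum(axis=-1, keepdims=True)
        cpts[node] = CPT(node=node, parents=parents, table=table)
        source[node] = tag
    return DiscreteBayesNet(graph=network.copy(), cpts=cpts, source=source)


def joint_probability(bn: DiscreteBayesNet, assignment: dict[str, int]) -> float:
    """P(full assignment) = ∏_i P(X_i | parents(X_i)); states are 1..5."""
    missing = [n for n in bn.graph.nodes if n not in assignment]
    if missing:
        raise ValueError(f"assignment misses nodes: {missing[:5]}")
    p = 1.0
    for node in bn.graph.nodes:
        cpt = bn.cpts[node]
        idx = tuple(assignment[par] - 1 for par in cpt.parents) + (assignment[node] - 1,)
        p *= float(cpt.table[idx])
    return p


# ---------------------------------------------------------------------------
# variable elimination

Factor = tuple[tuple[str, ...], np.ndarray]


def _reduce_factor(varnames: tuple[str, ...], arr: np.ndarray, evidence: dict[str, int]) -> Factor:
    keep = []
    index: list = []
    for v in varnames:
        if v in evidence:
            index.append(evidence[v] - 1)
        else:
            keep.append(v)
            index.append(slice(None))
    return tuple(keep), arr[tuple(index)]


def _align(varnames: tuple[str, ...], arr: np.ndarray, out_vars: list[str]) -> np.ndarray:
    missing = [v for v in out_vars if v not in varnames]
    arr = arr.reshape(arr.shape + (1,) * len(missing))
    current = list(varnames) + missing
    return arr.transpose([current.index(v) for v in out_vars])


def _multiply(f1: Factor, f2: Factor) -> Factor:
    out_vars = list(dict.fromkeys(f1[0] + f2[0]))
    if N_STATES ** len(out_vars) > _MAX_FACTOR_CELLS:
        raise RuntimeError("variable-elimination factor too large; use the Gibbs engine")
    return tuple(out_vars), _align(f1[0], f1[1], out_vars) * _align(f2[0], f2[1], out_vars)


def _sum_out(factor: Factor, var: str) -> Factor:
    varnames, arr = factor
    axis = varnames.index(var)
    return tuple(v for v in varnames if v != var), arr.sum(axis=axis)


def _elimination_order(factors: list[Factor], keep: set[str]) -> list[str]:
    """Greedy min-fill ordering over the factor interaction graph."""
    neighbors: dict[str, set[str]] = {}
    for varnames, _ in factors:
        for v in varnames:
            neighbors.setdefault(v, set()).update(varnames)
    for v in neighbors:
        neighbors[v].discard(v)
    order = []
    active = {v for v in neighbors if v not in keep}
    while active:
        def fill(v: str) -> tuple[int, str]:
            nb = [u for u in neighbors[v] if u in active or u in keep]
            cost = sum(
                1
                for i, a in enumerate(nb)
                for b in nb[i + 1:]
                if b not in neighbors[a]
            )
            return cost, v
        cost, v = min(fill(u) for u in active)
        order.append(v)
        nb = {u for u in neighbors[v] if u != v}
        for a in nb:
            neighbors[a].update(nb - {a})
            neighbors[a].discard(v)
        active.discard(v)
    return order


def _marginal_of(factors: list[Factor], query: str) -> np.ndarray:
    order = _elimination_order(factors, keep={query})
    pool = list(factors)
    for var in order:
        touching = [f for f in pool if var in f[0]]
        if not touching:
            continue
        pool = [f for f in pool if var not in f[0]]
        prod = touching[0]
        for f in touching[1:]:
            prod = _multiply(prod, f)
        pool.append(_sum_out(prod, var))
    result: Factor = ((), np.ones(()))
    for f in pool:
        result = _multiply(result, f)
    vec = result[1]
    if result[0] != (query,):
        vec = _align(result[0], vec, [query])
    total = float(vec.sum())
    if total <= 0:
        raise ValueError("impossible evidence: zero total probability")
    return vec / total


def _point_mass(state: int) -> np.ndarray:
    v = np.zeros(N_STATES)
    v[state - 1] = 1.0
    return v


def exact_marginals(bn: DiscreteBayesNet, evidence: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Exact posterior marginals P(X_i | e) by variable elimination.

    Evidence nodes are reported as point masses.  Intended for networks of
    toy scale (tens of nodes, bounded treewidth); an intermediate factor
    exceeding 5**13 cells raises.
    """
    evidence = dict(evidence or {})
    unknown = [n for n in evidence if n not in bn.graph.nodes]
    if unknown:
        raise KeyError(f"evidence on unknown nodes: {unknown}")
    base = [
        _reduce_factor(cpt.parents + (node,), cpt.table, evidence)
        for node, cpt in bn.cpts.items()
    ]
    out: dict[str, np.ndarray] = {}
    for node in bn.nodes:
        if node in evidence:
            out[node] = _point_mass(evidence[node])
        else:
            out[node] = _marginal_of(base, node)
    return out


# ---------------------------------------------------------------------------
# Gibbs sampling


def gibbs_marginals(
    bn: DiscreteBayesNet,
    evidence: dict[str, int] | None = None,
    cfg: GibbsConfig | None = None,
    n_samples: int | None = None,
) -> dict[str, np.ndarray]:
    """Approximate posterior marginals with a single-chain Gibbs sampler.

    Draws ``n_samples`` network samples (default ``cfg.Q × n_nodes``); each
    sample is produced by resampling every unobserved node, in sorted order,
    from its full conditional — proportional to its own CPT entry times the
    CPT entries of its children at the current Markov-blanket state.  Since
    all CPTs are smoothed, full conditionals are strictly positive.
    Marginals are post-burn-in state frequencies; evidence nodes come back
    as exact point masses.  Deterministic for a fixed seed.
    """
    cfg = cfg or GibbsConfig()
    evidence = dict(evidence or {})
    nodes = bn.nodes
    index = {n: i for i, n in enumerate(nodes)}
    free = [n for n in nodes if n not in evidence]
    total = n_samples if n_samples is not None else cfg.Q * len(nodes)
    burn = int(cfg.burn_in_frac * total)
    rng = np.random.default_rng(cfg.seed)

    # per-node plans: own CPT + the CPTs it appears in as a parent
    own = {}
    child_terms: dict[str, list[tuple[np.ndarray, np.ndarray, int, int]]] = {n: [] for n in free}
    for node in nodes:
        cpt = bn.cpts[node]
        own[node] = (cpt.table, np.array([index[p] for p in cpt.parents], dtype=int))
        for pos, par in enumerate(cpt.parents):
            if par in child_terms:
                child_terms[par].append(
                    (cpt.table, np.array([index[p] for p in cpt.parents], dtype=int), pos, index[node])
                )

    # ancestral initialization consistent with the evidence
    state = np.zeros(len(nodes), dtype=int)
    for node in nx.topological_sort(bn.graph):
        i = index[node]
        if node in evidence:
            state[i] = evidence[node] - 1
            continue
        table, pidx = own[node]
        probs = table[tuple(state[pidx])]
        state[i] = rng.choice(N_STATES, p=probs)

    counts = np.zeros((len(nodes), N_STATES))
    free_idx = [(index[n], own[n][0], own[n][1], child_terms[n]) for n in free]
    for t in range(total):
        for i, table, pidx, children in free_idx:
            probs = table[tuple(state[pidx])].copy()
            for ctab, cpidx, pos, cidx in children:
                sel = tuple(
                    slice(None) if j == pos else state[p] for j, p in enumerate(cpidx)
                )
                probs *= ctab[sel + (state[cidx],)]
            cum = np.cumsum(probs)
            state[i] = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        if t >= burn:
            counts[np.arange(len(nodes)), state] += 1.0

    kept = max(total - burn, 1)
    out: dict[str, np.ndarray] = {}
    for node in nodes:
        if node in evidence:
            out[node] = _point_mass(evidence[node])
        else:
            out[node] = counts[index[node]] / kept
    return out


def approximation_error(
    exact: dict[str, np.ndarray], approx: dict[str, np.ndarray]
) -> float:
    """Max over nodes and states of |exact − approx| marginal probability."""
    if set(exact) != set(approx):
        raise ValueError("marginal tables cover different node sets")
    return max(float(np.abs(exact[n] - approx[n]).max()) for n in exact)


# ---------------------------------------------------------------------------
# serialization


def bn_to_json(bn: DiscreteBayesNet) -> str:
    """Serialize a network to JSON: nodes with parent lists, row-major CPTs
    over (parents..., node), kinds and data-source tags."""
    payload = {
        "n_states": N_STATES,
        "nodes": [
            {
                "id": node,
                "kind": bn.graph.nodes[node].get("kind", "pathway_gene"),
                "parents": list(bn.cpts[node].parents),
                "cpt": bn.cpts[node].table.ravel(order="C").tolist(),
                "source": bn.source.get(node, "mrna_pool"),
            }
            for node in bn.nodes
        ],
    }
    return json.dumps(payload, indent=1)


def bn_from_json(text: str) -> DiscreteBayesNet:
    payload = json.loads(text)
    g = nx.DiGraph()
    cpts: dict[str, CPT] = {}
    source: dict[str, str] = {}
    for rec in payload["nodes"]:
        g.add_node(rec["id"], kind=rec.get("kind", "pathway_gene"), feature=rec["id"])
    for rec in payload["nodes"]:
        parents = tuple(rec["parents"])
        for p in parents:
            g.add_edge(p, rec["id"])
        shape = (N_STATES,) * (len(parents) + 1)
        table = np.asarray(rec["cpt"], dtype=float).reshape(shape, order="C")
        cpts[rec["id"]] = CPT(node=rec["id"], parents=parents, table=table)
        source[rec["id"]] = rec.get("source", "mrna_pool")
    return DiscreteBayesNet(graph=g, cpts=cpts, source=source)
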