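"""Bayesian network: CPT counting, joint, exact inference vs enumeration,
Gibbs convergence, and serialization round-trips."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathwaybn import (
    CPT,
    DiscreteBayesNet,
    DiscretePanel,
    GibbsConfig,
    approximation_error,
    bn_from_json,
    bn_to_json,
    count_table,
    estimate_cpt,
    estimate_prior,
    exact_marginals,
    gibbs_marginals,
    joint_probability,
    n_parent_configurations,
    random_bayes_net,
    toy_chain_network,
)


def make_panel(states, features, name="p"):
    states = np.asarray(states, dtype=int)
    samples = [f"s{j}" for j in range(states.shape[1])]
    pheno = pd.Series(["groupA"] * len(samples), index=samples)
    kind = pd.Series(["mRNA"] * len(features), index=features)
    return DiscretePanel(pd.DataFrame(states, index=features, columns=samples),
                         pheno, kind, name=name)


# -- enumeration oracle (independent of the variable-elimination engine) ----


def joint_tensor(bn):
    """Full joint over all nodes as a dense tensor, axes in sorted order."""
    nodes = bn.nodes
    axis = {n: i for i, n in enumerate(nodes)}
    t = np.ones((5,) * len(nodes))
    for node in nodes:
        cpt = bn.cpts[node]
        scope = cpt.parents + (node,)
        arr = cpt.table
        # expand to global axes
        shape = [1] * len(nodes)
        order = sorted(scope, key=lambda v: axis[v])
        perm = [scope.index(v) for v in order]
        arr = arr.transpose(perm)
        for v in order:
            shape[axis[v]] = 5
        t = t * arr.reshape(shape)
    return t, axis


def enumeration_marginals(bn, evidence):
    t, axis = joint_tensor(bn)
    idx = [slice(None)] * len(axis)
    for node, state in evidence.items():
        idx[axis[node]] = state - 1
        t = t  # slicing below
    t = t[tuple(idx)]
    free = [n for n in bn.nodes if n not in evidence]
    total = t.sum()
    out = {}
    for i, node in enumerate(free):
        other = tuple(j for j in range(len(free)) if j != i)
        out[node] = t.sum(axis=other) / total
    for node, state in evidence.items():
        v = np.zeros(5)
        v[state - 1] = 1.0
        out[node] = v
    return out


class TestCounting:
    def test_parent_configuration_count_closed_form(self):
        assert n_parent_configurations(100) == 5**100
        assert n_parent_configurations(0) == 1

    def test_count_table_mass_conservation(self):
        rng = np.random.default_rng(0)
        obs = rng.integers(1, 6, size=(37, 3))
        counts = count_table(obs, 3)
        assert counts.sum() == pytest.approx(5**3 + 37)
        assert (counts >= 1).all()

    def test_prior_add_one_smoothing(self):
        panel = make_panel(np.full((1, 10), 3), ["g"])
        prior = estimate_prior("g", [panel])
        assert np.allclose(prior, np.array([1, 1, 11, 1, 1]) / 15)

    def test_prior_equal_counts_is_uniform(self):
        panel = make_panel([[1, 2, 3, 4, 5]], ["g"])
        assert np.allclose(estimate_prior("g", [panel]), 0.2)

    def test_single_observation_cpt_slice(self):
        panel = make_panel([[2], [4]], ["p", "g"])
        cpt = estimate_cpt("g", ["p"], [panel])
        assert np.allclose(cpt.table[1], np.array([1, 1, 1, 2, 1]) / 6)
        for row in (0, 2, 3, 4):
            assert np.allclose(cpt.table[row], 0.2)

    def test_zero_observations_gives_uniform_slices(self):
        panel = make_panel(np.empty((2, 0), dtype=int), ["p", "g"])
        cpt = estimate_cpt("g", ["p"], [panel])
        assert np.allclose(cpt.table, 0.2)

    def test_missing_variable_raises(self):
        panel = make_panel([[1, 2]], ["g"])
        with pytest.raises(KeyError):
            estimate_cpt("g", ["nope"], [panel])


class TestJointProbability:
    def test_single_node_net_is_prior(self):
        bn = random_bayes_net(1, seed=0)
        p = joint_probability(bn, {"n00": 2})
        assert p == pytest.approx(float(bn.cpts["n00"].table[1]))

    @pytest.mark.parametrize("n_nodes,seed", [(2, 1), (4, 2), (6, 3)])
    def test_sums_to_one(self, n_nodes, seed):
        bn = random_bayes_net(n_nodes, seed=seed)
        total = sum(
            joint_probability(bn, dict(zip(bn.nodes, states)))
            for states in itertools.product(range(1, 6), repeat=n_nodes)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_two_node_chain_against_hand_table(self):
        prior = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        cond = np.tile(np.array([0.5, 0.2, 0.1, 0.1, 0.1]), (5, 1))
        cond[2] = [0.05, 0.05, 0.7, 0.1, 0.1]
        bn = DiscreteBayesNet(
            graph=nx.DiGraph([("a", "b")]),
            cpts={
                "a": CPT("a", (), prior),
                "b": CPT("b", ("a",), cond),
            },
        )
        assert joint_probability(bn, {"a": 3, "b": 3}) == pytest.approx(0.3 * 0.7)

    def test_partial_assignment_raises(self):
        bn = random_bayes_net(3, seed=4)
        with pytest.raises(ValueError):
            joint_probability(bn, {"n00": 1})


class TestExactMarginals:
    def test_root_prior_without_evidence(self):
        bn = random_bayes_net(5, seed=5)
        roots = [n for n in bn.nodes if not bn.cpts[n].parents]
        marg = exact_marginals(bn)
        for r in roots:
            assert np.allclose(marg[r], bn.cpts[r].table, atol=1e-12)

    def test_full_evidence_gives_point_masses(self):
        bn = random_bayes_net(4, seed=6)
        ev = {n: 2 for n in bn.nodes}
        marg = exact_marginals(bn, ev)
        for n in bn.nodes:
            assert marg[n][1] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        bn = random_bayes_net(n, seed=seed)
        ev = {bn.nodes[0]: int(rng.integers(1, 6))}
        marg = exact_marginals(bn, ev)
        oracle = enumeration_marginals(bn, ev)
        for node in bn.nodes:
            assert np.abs(marg[node] - oracle[node]).max() < 1e-12


class TestGibbs:
    def test_full_evidence_point_masses_any_seed(self):
        bn = random_bayes_net(3, seed=7)
        ev = {n: 4 for n in bn.nodes}
        marg = gibbs_marginals(bn, ev, GibbsConfig(seed=99), n_samples=50)
        for n in bn.nodes:
            assert marg[n][3] == 1.0

    def test_single_node_converges_to_prior(self):
        bn = random_bayes_net(1, seed=8)
        marg = gibbs_marginals(bn, {}, GibbsConfig(seed=1), n_samples=10_000)
        assert np.abs(marg["n00"] - bn.cpts["n00"].table).max() < 0.02

    def test_sixteen_node_toy_within_tolerance(self):
        bn, ev = toy_chain_network(seed=0)
        exact = exact_marginals(bn, ev)
        approx = gibbs_marginals(bn, ev, GibbsConfig(seed=0), n_samples=4000)
        assert approximation_error(exact, approx) <= 0.05

    def test_seed_determinism(self):
        bn, ev = toy_chain_network(seed=2)
        a = gibbs_marginals(bn, ev, GibbsConfig(seed=5), n_samples=500)
        b = gibbs_marginals(bn, ev, GibbsConfig(seed=5), n_samples=500)
        for n in a:
            assert np.array_equal(a[n], b[n])

    def test_default_sample_budget_is_q_times_nodes(self):
        # Q=2 on a 3-node net: marginals from integer frequencies over
        # (1 - burn_in) * 6 kept samples
        bn = random_bayes_net(3, seed=9)
        marg = gibbs_marginals(bn, {}, GibbsConfig(Q=2, burn_in_frac=0.0, seed=0))
        for n in bn.nodes:
            assert np.allclose(marg[n] * 6, np.round(marg[n] * 6))


class TestApproximationError:
    def test_identical_tables_zero(self):
        bn = random_bayes_net(3, seed=10)
        m = exact_marginals(bn)
        assert approximation_error(m, m) == 0.0

    def test_direct_value(self):
        a = {"x": np.array([1.0, 0, 0, 0, 0])}
        b = {"x": np.array([0.9, 0.1, 0, 0, 0])}
        assert approximation_error(a, b) == pytest.approx(0.1)

    def test_matches_elementwise_max_oracle(self):
        rng = np.random.default_rng(11)
        a = {f"n{i}": rng.dirichlet(np.ones(5)) for i in range(4)}
        b = {f"n{i}": rng.dirichlet(np.ones(5)) for i in range(4)}
        expected = max(
            abs(a[n][s] - b[n][s]) for n in a for s in range(5)
        )
        assert approximation_error(a, b) == pytest.approx(expected)

    def test_mismatched_nodes_raise(self):
        with pytest.raises(ValueError):
            approximation_error({"x": np.ones(5) / 5}, {"y": np.ones(5) / 5})


class TestSerialization:
    def test_json_round_trip(self):
        bn, ev = toy_chain_network(seed=1)
        clone = bn_from_json(bn_to_json(bn))
        assert clone.nodes == bn.nodes
        for n in bn.nodes:
            assert clone.cpts[n].parents == bn.cpts[n].parents
            assert np.allclose(clone.cpts[n].table, bn.cpts[n].table)
            assert clone.source[n] == bn.source[n]
        # inference agrees after the round trip
        assert approximation_error(
            exact_marginals(bn, ev), exact_marginals(clone, ev)
        ) < 1e-12


def test_gibbs_error_decreases_with_samples():
    """Median max-error over seeds shrinks as the chain runs longer."""
    sizes = (1000, 8000, 40000)
    medians = []
    for n_samples in sizes:
        errs = []
        for seed in range(3):
            bn, ev = toy_chain_network(seed=seed)
            exact = exact_marginals(bn, ev)
            approx = gibbs_marginals(bn, ev, GibbsConfig(seed=seed + 50),
                                     n_samples=n_samples)
            errs.append(approximation_error(exact, approx))
        medians.append(float(np.median(errs)))
    assert medians[0] >= medians[1] >= medians[2]
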