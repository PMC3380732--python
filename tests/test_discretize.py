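"""Discretization: threshold rules, tie handling, PAM clustering, filters,
and the UPGMA phenotype contrast."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pathwaybn import (
    apply_absent_override,
    discretize_pam,
    discretize_quantile,
    discretize_sigma_mu,
    filter_features,
    phenotype_contrast,
)
from pathwaybn.discretize import _kmedoids_1d

from conftest import make_expr


def sigma_mu_oracle(values):
    """Direct evaluation of the five threshold intervals (sample sd)."""
    mu = np.mean(values)
    sd = np.std(values, ddof=1)
    if sd == 0:
        return [3] * len(values)
    out = []
    for v in values:
        if v <= mu - 2 * sd:
            out.append(1)
        elif v <= mu - sd:
            out.append(2)
        elif v < mu + sd:
            out.append(3)
        elif v < mu + 2 * sd:
            out.append(4)
        else:
            out.append(5)
    return out


class TestSigmaMu:
    def test_two_sigma_above_mean_is_very_high(self):
        # eight values at the mean plus one high outlier: sd ~0.83, so 12.5
        # sits more than 2 sigma above the mean
        vals = [10.0] * 8 + [12.5]
        expr = make_expr(np.array(vals)[:, None], phenotype=["groupA"])
        panel = discretize_sigma_mu(expr)
        mu = np.mean(vals)
        sd = np.std(vals, ddof=1)
        assert vals[-1] >= mu + 2 * sd
        assert panel.states.iloc[-1, 0] == 5
        # value at the mean stays medium
        assert panel.states.iloc[0, 0] == 3

    def test_matches_threshold_oracle(self):
        vals = [4, 6, 8, 10, 12, 14, 16]
        expr = make_expr(np.array(vals, dtype=float)[:, None], phenotype=["groupA"])
        panel = discretize_sigma_mu(expr)
        assert list(panel.states.iloc[:, 0]) == sigma_mu_oracle(vals)

    def test_constant_array_degenerates_to_medium(self):
        expr = make_expr(np.full((6, 1), 7.0), phenotype=["groupA"])
        panel = discretize_sigma_mu(expr)
        assert (panel.states.to_numpy() == 3).all()

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_always_agrees_with_oracle(self, vals):
        expr = make_expr(np.asarray(vals)[:, None], phenotype=["groupA"])
        panel = discretize_sigma_mu(expr)
        assert list(panel.states.iloc[:, 0]) == sigma_mu_oracle(vals)


class TestQuantile:
    def test_permutation_of_1_to_100_gives_equal_bins(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(1, 101)).astype(float)
        expr = make_expr(vals[:, None], phenotype=["groupA"])
        panel = discretize_quantile(expr)
        counts = np.bincount(panel.states.iloc[:, 0], minlength=6)[1:]
        assert list(counts) == [20] * 5

    def test_extremes(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=50)
        expr = make_expr(vals[:, None], phenotype=["groupA"])
        panel = discretize_quantile(expr)
        states = panel.states.iloc[:, 0].to_numpy()
        assert states[np.argmin(vals)] == 1
        assert states[np.argmax(vals)] == 5

    def test_constant_array_maps_to_state_one(self):
        expr = make_expr(np.full((8, 1), 3.3), phenotype=["groupA"])
        panel = discretize_quantile(expr)
        assert (panel.states.to_numpy() == 1).all()


class TestPam:
    def test_separated_point_masses_recover_cluster_index(self):
        vals = np.repeat([0.0, 10.0, 20.0, 30.0, 40.0], 8)
        rng = np.random.default_rng(2)
        vals = rng.permutation(vals)
        expr = make_expr(vals[:, None], phenotype=["groupA"])
        panel = discretize_pam(expr)
        expected = 1 + (vals // 10).astype(int)
        assert list(panel.states.iloc[:, 0]) == list(expected)

    def test_monotone_in_expression(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=60)
        expr = make_expr(vals[:, None], phenotype=["groupA"])
        states = discretize_pam(expr).states.iloc[:, 0].to_numpy()
        order = np.argsort(vals)
        assert (np.diff(states[order]) >= 0).all()

    def test_matches_exhaustive_kmedoids_oracle(self):
        # 5-component Gaussian mixture, well separated, 50 points
        rng = np.random.default_rng(4)
        centers = [0.0, 5.0, 10.0, 15.0, 20.0]
        vals = np.concatenate([rng.normal(c, 0.4, size=10) for c in centers])
        vals = rng.permutation(vals)
        best_cost, best_medoids = None, None
        for medoids in itertools.combinations(sorted(vals), 5):
            m = np.asarray(medoids)
            cost = np.abs(vals[:, None] - m[None, :]).min(axis=1).sum()
            if best_cost is None or cost < best_cost - 1e-12:
                best_cost, best_medoids = cost, m
        oracle = 1 + np.argmin(np.abs(vals[:, None] - best_medoids[None, :]), axis=1)
        assert list(_kmedoids_1d(vals, 5)) == list(oracle)

    def test_few_distinct_values_fall_back_to_quantile(self):
        vals = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        expr = make_expr(vals[:, None], phenotype=["groupA"])
        panel = discretize_pam(expr)
        expected = discretize_quantile(expr)
        assert panel.states.equals(expected.states)


class TestAbsentOverride:
    def test_override_and_identity(self):
        vals = np.array([[10.0, 1.0], [8.0, 9.0]])
        calls = [["A", "P"], ["P", "M"]]
        expr = make_expr(vals, phenotype=["groupA", "groupB"], calls=calls)
        panel = discretize_quantile(expr)
        out = apply_absent_override(panel, expr.present_calls)
        assert out.states.iloc[0, 0] == 1  # called Absent
        assert out.states.iloc[1, 0] == panel.states.iloc[1, 0]

    def test_all_absent_saturates_to_ones(self):
        vals = np.arange(12, dtype=float).reshape(6, 2)
        calls = [["A", "A"]] * 6
        expr = make_expr(vals, phenotype=["groupA", "groupB"], calls=calls)
        out = apply_absent_override(discretize_quantile(expr), expr.present_calls)
        assert (out.states.to_numpy() == 1).all()

    def test_missing_calls_is_identity(self):
        vals = np.arange(10, dtype=float)[:, None]
        expr = make_expr(vals, phenotype=["groupA"])
        panel = discretize_quantile(expr)
        assert apply_absent_override(panel, None) is panel


class TestFilterFeatures:
    def test_constant_feature_discarded(self):
        vals = np.vstack([np.full(20, 5.0), np.linspace(1, 20, 20)])
        expr = make_expr(vals)
        kept = filter_features(expr)
        assert "f1" not in kept

    def test_present_and_variable_feature_kept(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 7, size=20)  # CV well above 0.5
        expr = make_expr(x[None, :], calls=[["P"] * 20])
        assert filter_features(expr) == ["f1"]

    def test_presence_fraction_boundary_is_strict(self):
        # 17/20 = 0.85 exactly: not *more than* 85%, so discarded
        x = np.random.default_rng(6).normal(10, 7, size=20)
        calls = [["P"] * 17 + ["A"] * 3]
        expr = make_expr(x[None, :], calls=calls)
        assert filter_features(expr) == []


class TestPhenotypeContrast:
    def test_identical_states_give_zero(self):
        states = np.full((1, 6), 4)
        expr = make_expr(states.astype(float))
        panel = discretize_quantile(expr)  # all constant -> state 1 everywhere
        score = phenotype_contrast(panel, ["f1"])
        assert score.per_gene["f1"] == 0.0

    def test_exhaustive_pair_oracle(self):
        # groupA {1,2}, groupB {3,5}: mean |x-y| over 4 pairs = 2.5
        from pathwaybn import DiscretePanel

        states = pd.DataFrame([[1, 2, 3, 5]], index=["g"], columns=list("abcd"))
        pheno = pd.Series(["groupA", "groupA", "groupB", "groupB"], index=list("abcd"))
        kind = pd.Series(["mRNA"], index=["g"])
        panel = DiscretePanel(states, pheno, kind)
        score = phenotype_contrast(panel, ["g"])
        assert score.per_gene["g"] == pytest.approx(2.5)
        assert score.dataset_mean == pytest.approx(2.5)

    def test_maximal_separation_and_symmetry(self):
        from pathwaybn import DiscretePanel

        states = pd.DataFrame([[5, 5, 1, 1]], index=["g"], columns=list("abcd"))
        kind = pd.Series(["mRNA"], index=["g"])
        p1 = DiscretePanel(states, pd.Series(["groupA", "groupA", "groupB", "groupB"], index=list("abcd")), kind)
        p2 = DiscretePanel(states, pd.Series(["groupB", "groupB", "groupA", "groupA"], index=list("abcd")), kind)
        assert phenotype_contrast(p1, ["g"]).per_gene["g"] == pytest.approx(4.0)
        assert phenotype_contrast(p1, ["g"]).per_gene["g"] == pytest.approx(
            phenotype_contrast(p2, ["g"]).per_gene["g"]
        )

    def test_empty_phenotype_errors(self):
        from pathwaybn import DiscretePanel

        states = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        pheno = pd.Series(["groupA", "groupA"], index=["a", "b"])
        kind = pd.Series(["mRNA"], index=["g"])
        panel = DiscretePanel(states, pheno, kind)
        with pytest.raises(ValueError):
            phenotype_contrast(panel, ["g"])


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_all_methods_emit_valid_states(seed):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(30, 3)) * rng.uniform(0.5, 5)
    expr = make_expr(vals, phenotype=["groupA", "groupA", "groupB"])
    for method in (discretize_sigma_mu, discretize_quantile, discretize_pam):
        panel = method(expr)
        assert panel.states.shape == vals.shape
        assert panel.states.isin([1, 2, 3, 4, 5]).all().all()
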