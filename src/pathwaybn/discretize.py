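"""Discretization of expression panels into five ordered states.

Three alternative per-array (per-sample) methods are provided:

``sigma_mu``
    thresholds at 1 and 2 array standard deviations from the array mean;
``quantile``
    the 20/40/60/80% empirical quantile breakpoints of the array;
``pam``
    1-D k-medoids (PAM) clustering of the array's values into five clusters,
    relabelled 1..5 by ascending medoid.

Every method maps each microarray (column) independently, following the
per-array design of the upstream normalization.  Detection calls, when
available, override the state of Absent cells to 1 (very low).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DiscretePanel, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "discretize",
    "discretize_sigma_mu",
    "discretize_quantile",
    "discretize_pam",
    "apply_absent_override",
    "filter_features",
    "phenotype_contrast",
    "ContrastScore",
]


def _sigma_mu_column(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sigma = x.std(ddof=1)
    if sigma == 0:
        log.warning("array with zero standard deviation; all states set to 3")
        return np.full(x.shape, 3, dtype=int)
    d = x - mu
    states = np.full(x.shape, 3, dtype=int)
    states[d <= -sigma] = 2
    states[d <= -2 * sigma] = 1
    states[d >= sigma] = 4
    states[d >= 2 * sigma] = 5
    return states


def discretize_sigma_mu(expr: ExpressionMatrix) -> DiscretePanel:
    """Discretize by distance from the per-array mean in units of its sd.

    Values at least 2σ below/above μ map to 1/5, at least 1σ to 2/4, and
    values within 1σ of μ map to 3.  Boundaries go to the outer state.
    Sample (n−1) standard deviation is used.
    """
    vals = expr.values.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("sigma-mu discretization needs >= 2 values per array")
    states = np.column_stack([_sigma_mu_column(vals[:, j]) for j in range(vals.shape[1])])
    return DiscretePanel.like(expr, states, method="sigma_mu")


def _quantile_column(x: np.ndarray) -> np.ndarray:
    breaks = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    # left-closed intervals: a value equal to a breakpoint joins the interval
    # starting at that breakpoint; a constant array collapses to state 1.
    return 1 + (x[:, None] > breaks[None, :]).sum(axis=1)


def discretize_quantile(expr: ExpressionMatrix) -> DiscretePanel:
    """Discretize by the per-array 20/40/60/80% empirical quantiles."""
    vals = expr.values.to_numpy(dtype=float)
    states = np.column_stack([_quantile_column(vals[:, j]) for j in range(vals.shape[1])])
    return DiscretePanel.like(expr, states, method="quantile")


def _kmedoids_1d(x: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray | None:
    """1-D k-medoids (PAM); returns per-point states 1..k or None if fewer
    than k distinct values.

    Medoids are initialized at the data points closest to the
    0.1/0.3/…-quantiles, refined by alternating assignment/median updates,
    and then by PAM's swap phase (greedy medoid/non-medoid exchanges until
    no swap lowers the total L1 cost), which escapes the local optima of
    the alternating phase when cluster masses are unbalanced.  Final states
    are assigned by nearest ordered medoid, with midpoints going to the
    lower state, so the mapping is monotone non-decreasing in expression.
    """
    uniq = np.unique(x)
    if uniq.size < k:
        return None
    targets = np.quantile(x, (np.arange(k) * 2 + 1) / (2 * k))
    medoids: list[float] = []
    for t in targets:
        j = int(np.argmin(np.abs(uniq - t)))
        # keep medoids distinct: walk to the nearest unused unique value
        while uniq[j] in medoids and j + 1 < uniq.size:
            j += 1
        while uniq[j] in medoids and j > 0:
            j -= 1
        medoids.append(float(uniq[j]))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        m = np.asarray(medoids)
        assign = np.argmin(np.abs(x[:, None] - m[None, :]), axis=1)
        new = []
        for c in range(k):
            members = np.sort(x[assign == c])
            new.append(float(members[(members.size - 1) // 2]))
        new = sorted(new)
        if new == medoids:
            break
        medoids = new

    # swap phase: |x - candidate| for every distinct value, reused per sweep
    dist_all = np.abs(x[:, None] - uniq[None, :])
    cost = dist_all[:, np.searchsorted(uniq, medoids)].min(axis=1).sum()
    for _ in range(max_iter):
        m = np.asarray(medoids)
        dist_m = np.abs(x[:, None] - m[None, :])
        best_gain, best_swap = 0.0, None
        for i in range(k):
            others = np.delete(dist_m, i, axis=1).min(axis=1)
            swap_costs = np.minimum(others[:, None], dist_all).sum(axis=0)
            j = int(np.argmin(swap_costs))
            if uniq[j] in medoids:
                continue
            gain = cost - float(swap_costs[j])
            if gain > best_gain + 1e-12:
                best_gain, best_swap = gain, (i, float(uniq[j]))
        if best_swap is None:
            break
        i, value = best_swap
        medoids[i] = value
        medoids = sorted(medoids)
        cost -= best_gain

    m = np.sort(np.asarray(medoids))
    bounds = (m[:-1] + m[1:]) / 2.0
    return 1 + (x[:, None] > bounds[None, :]).sum(axis=1)


def discretize_pam(expr: ExpressionMatrix, k: int = 5) -> DiscretePanel:
    """Discretize each array by 1-D k-medoids (PAM) into ``k`` ordered clusters.

    Arrays with fewer than ``k`` distinct values fall back to the quantile
    method (logged).
    """
    vals = expr.values.to_numpy(dtype=float)
    cols = []
    for j in range(vals.shape[1]):
        states = _kmedoids_1d(vals[:, j], k)
        if states is None:
            log.warning(
                "array %s has < %d distinct values; falling back to quantile",
                expr.values.columns[j], k,
            )
            states = _quantile_column(vals[:, j])
        cols.append(states)
    return DiscretePanel.like(expr, np.column_stack(cols), method="pam")


_METHODS = {
    "sigma_mu": discretize_sigma_mu,
    "quantile": discretize_quantile,
    "pam": discretize_pam,
}


def discretize(expr: ExpressionMatrix, method: str = "pam") -> DiscretePanel:
    """Discretize with the named method and apply the Absent-call override."""
    try:
        panel = _METHODS[method](expr)
    except KeyError:
        raise ValueError(f"unknown discretization method {method!r}") from None
    return apply_absent_override(panel, expr.present_calls)


def apply_absent_override(panel: DiscretePanel, calls: pd.DataFrame | None) -> DiscretePanel:
    """Force cells whose detection call is Absent to state 1 (very low)."""
    if calls is None:
        return panel
    if calls.shape != panel.states.shape:
        raise ValueError("calls matrix shape does not match panel")
    calls = calls.loc[panel.states.index, panel.states.columns]
    states = panel.states.where(calls != "A", 1)
    return DiscretePanel(states, panel.phenotype, panel.feature_kind,
                         name=panel.name, method=panel.method)


def filter_features(
    expr: ExpressionMatrix,
    min_present_frac: float = 0.85,
    min_cv: float = 0.50,
) -> list[str]:
    """Feature filter: detection rate and coefficient of variability.

    A feature is kept iff (when calls exist) its fraction of Present-or-
    Marginal calls is strictly greater than ``min_present_frac``, and its
    CV (sd/mean on the given scale) is at least ``min_cv``.  Features with
    zero mean have undefined CV and are discarded (logged).  The thresholds
    are configurable for other platforms (e.g. a 20% CV rule).
    """
    kept = []
    vals = expr.values
    for fid in vals.index:
        x = vals.loc[fid].to_numpy(dtype=float)
        if expr.present_calls is not None:
            pm = (expr.present_calls.loc[fid] != "A").mean()
            if not pm > min_present_frac:
                continue
        mean = x.mean()
        if mean == 0:
            log.warning("feature %s has zero mean; CV undefined, discarded", fid)
            continue
        cv = x.std(ddof=1) / mean
        if cv >= min_cv:
            kept.append(fid)
    return kept


@dataclass
class ContrastScore:
    """Per-gene UPGMA contrast Δ between the two phenotypes, and its mean.

    Δ for a gene is the average absolute difference of discrete states over
    all cross-phenotype sample pairs; for 5-state data 0 ≤ Δ ≤ 4.
    """

    per_gene: dict[str, float]
    dataset_mean: float


def phenotype_contrast(panel: DiscretePanel, de_genes: list[str]) -> ContrastScore:
    """UPGMA contrast of discretized states between the two phenotype groups.

    Δ_gene = (1/|A||B|) Σ_{x∈A} Σ_{y∈B} |x − y| over the gene's states, and
    ``dataset_mean`` averages Δ over ``de_genes``.
    """
    groups = sorted(panel.phenotype.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two phenotype groups, got {groups}")
    a_cols = panel.samples_of(groups[0])
    b_cols = panel.samples_of(groups[1])
    if not a_cols or not b_cols:
        raise ValueError("each phenotype group must contain at least one sample")
    per_gene: dict[str, float] = {}
    for gene in de_genes:
        if gene not in panel.states.index:
            raise KeyError(f"DE gene {gene!r} not in panel")
        a = panel.states.loc[gene, a_cols].to_numpy(dtype=float)
        b = panel.states.loc[gene, b_cols].to_numpy(dtype=float)
        per_gene[gene] = float(np.abs(a[:, None] - b[None, :]).mean())
    mean = float(np.mean(list(per_gene.values()))) if per_gene else float("nan")
    return ContrastScore(per_gene=per_gene, dataset_mean=mean)
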