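"""Random-forest permutation importance for candidate regulators.

For each pathway gene a 5-class classification problem is formed: the
response is the gene's discretized state across microarrays, the predictors
are the discretized states of its candidate TFs (via their encoding genes)
or microRNAs.  A forest of CART trees is grown, each on a two-thirds
subsample drawn without replacement; the remaining third is that tree's
out-of-bag (OOB) set.  A predictor's importance is the mean, over trees, of
the drop in OOB accuracy when that predictor's OOB column is permuted
(Breiman's mean decrease of accuracy).  The goal is not a good classifier
but a ranking of regulators by their ability to track the gene's state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .containers import DiscretePanel

log = logging.getLogger(__name__)

__all__ = [
    "SupervisedTable",
    "ImportanceRanking",
    "build_training_table",
    "rank_by_permutation_importance",
    "select_top",
]


@dataclass
class SupervisedTable:
    """Per-gene training table: response y (M,) and predictors X (M, k)."""

    gene_id: str
    y: np.ndarray
    X: np.ndarray
    predictor_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        self.X = np.asarray(self.X, dtype=int).reshape(len(self.y), -1)
        if self.X.shape[1] != len(self.predictor_ids):
            raise ValueError("predictor_ids length does not match X columns")

    @property
    def M(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return len(self.predictor_ids)


@dataclass
class ImportanceRanking:
    """Regulators of one gene ordered by mean decrease of accuracy.

    Entries are (regulator_id, score) sorted by score descending, ties
    broken lexicographically by regulator id.
    """

    gene_id: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: (-e[1], e[0]))


def build_training_table(
    gene: str,
    panels: list[DiscretePanel],
    candidates: list[tuple[str, str]],
) -> SupervisedTable:
    """Assemble the supervised table for ``gene`` from a pool of panels.

    ``candidates`` is a list of (regulator_id, expression_feature_id) pairs;
    a candidate whose feature is missing from any pooled panel containing
    the gene is dropped (logged).  Rows are the pooled arrays of all panels
    that measure the gene.
    """
    used = [p for p in panels if gene in p.states.index]
    if not used:
        raise KeyError(f"gene {gene!r} absent from every panel in the pool")
    kept: list[tuple[str, str]] = []
    for reg, feat in candidates:
        if all(feat in p.states.index for p in used):
            kept.append((reg, feat))
        else:
            log.info("candidate %s (feature %s) lacks expression; dropped", reg, feat)
    y = np.concatenate([p.states.loc[gene].to_numpy() for p in used])
    if kept:
        X = np.column_stack(
            [np.concatenate([p.states.loc[feat].to_numpy() for p in used]) for _, feat in kept]
        )
    else:
        log.warning("gene %s has zero usable candidates", gene)
        X = np.empty((len(y), 0), dtype=int)
    return SupervisedTable(gene, y, X, [reg for reg, _ in kept])


def rank_by_permutation_importance(
    table: SupervisedTable,
    n_trees: int,
    mtry_frac: float = 1 / 3,
    oob_frac: float = 1 / 3,
    seed: int = 0,
) -> ImportanceRanking:
    """Rank predictors by OOB permutation importance in a seeded forest.

    Each tree trains on a ``1 - oob_frac`` subsample drawn without
    replacement and considers ``max(1, floor(mtry_frac * k))`` predictors at
    each split; states 1..5 are treated as numeric.  Deterministic for a
    fixed seed.
    """
    if table.k == 0:
        return ImportanceRanking(table.gene_id, [])
    M, k = table.M, table.k
    if M < 10:
        raise ValueError(f"need at least 10 arrays, got {M}")
    rng = np.random.default_rng(seed)
    X, y = table.X, table.y
    n_oob = max(1, int(np.floor(oob_frac * M)))
    totals = np.zeros(k)
    for _ in range(n_trees):
        order = rng.permutation(M)
        oob, train = order[:n_oob], order[n_oob:]
        tree = DecisionTreeClassifier(
            max_features=mtry_frac,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[train], y[train])
        y_oob = y[oob]
        X_oob = X[oob]
        base_acc = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(k):
            permuted = X_oob.copy()
            permuted[:, j] = permuted[rng.permutation(n_oob), j]
            perm_acc = np.mean(tree.predict(permuted) == y_oob)
            totals[j] += base_acc - perm_acc
    scores = totals / n_trees
    entries = [(table.predictor_ids[j], float(scores[j])) for j in range(k)]
    return ImportanceRanking(table.gene_id, entries)


def select_top(ranking: ImportanceRanking, n: int) -> list[str]:
    """The first min(n, #positive-score) regulator ids, in rank order.

    Regulators with zero or negative importance are never selected.
    """
    return [reg for reg, score in ranking.entries if score > 0][: max(n, 0)]
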