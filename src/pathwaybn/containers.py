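"""In-memory containers for expression panels.

Both containers are thin wrappers around pandas objects: ``values``/``states``
are feature × sample DataFrames, with per-sample phenotype labels and
per-feature kind labels (``mRNA`` or ``miRNA``) carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MRNA = "mRNA"
MIRNA = "miRNA"
STATES = (1, 2, 3, 4, 5)

#: human-readable names of the five ordered expression states
STATE_NAMES = {1: "very low", 2: "medium low", 3: "medium", 4: "medium high", 5: "very high"}


def _check_axes(values: pd.DataFrame, phenotype: pd.Series, feature_kind: pd.Series) -> None:
    if not values.columns.isin(phenotype.index).all():
        missing = values.columns.difference(phenotype.index)
        raise ValueError(f"samples without phenotype label: {list(missing)[:5]}")
    if not values.index.isin(feature_kind.index).all():
        missing = values.index.difference(feature_kind.index)
        raise ValueError(f"features without kind label: {list(missing)[:5]}")


@dataclass
class ExpressionMatrix:
    """Continuous (log-scale) feature × sample expression panel.

    Parameters
    ----------
    values
        Feature × sample matrix of normalized log intensities.
    phenotype
        Per-sample group label (two groups, e.g. ``groupA``/``groupB`` or
        ``ER+``/``ER-``), indexed by sample id.
    feature_kind
        Per-feature label, ``mRNA`` or ``miRNA``, indexed by feature id.
    present_calls
        Optional detection-call matrix with the same shape as ``values`` and
        entries in ``{P, M, A}``.
    name
        Dataset name (used by the dataset-selection rule downstream).
    """

    values: pd.DataFrame
    phenotype: pd.Series
    feature_kind: pd.Series
    present_calls: pd.DataFrame | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        _check_axes(self.values, self.phenotype, self.feature_kind)
        self.phenotype = self.phenotype.loc[self.values.columns]
        self.feature_kind = self.feature_kind.loc[self.values.index]
        if self.present_calls is not None:
            if self.present_calls.shape != self.values.shape:
                raise ValueError("present_calls shape does not match values")
            self.present_calls = self.present_calls.loc[self.values.index, self.values.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, phenotype: str) -> list[str]:
        return list(self.phenotype.index[self.phenotype == phenotype])


@dataclass
class DiscretePanel:
    """Five-state discrete panel sharing axes with its source ExpressionMatrix.

    Entries are integers 1..5 (very low … very high).
    """

    states: pd.DataFrame
    phenotype: pd.Series
    feature_kind: pd.Series
    name: str = "dataset"
    method: str = ""

    def __post_init__(self) -> None:
        _check_axes(self.states, self.phenotype, self.feature_kind)
        self.phenotype = self.phenotype.loc[self.states.columns]
        self.feature_kind = self.feature_kind.loc[self.states.index]
        arr = self.states.to_numpy()
        if not np.isin(arr, STATES).all():
            raise ValueError("discrete states must lie in {1..5}")
        self.states = self.states.astype(int)

    @classmethod
    def like(cls, expr: ExpressionMatrix, states: np.ndarray, method: str = "") -> "DiscretePanel":
        frame = pd.DataFrame(states, index=expr.values.index, columns=expr.values.columns)
        return cls(frame, expr.phenotype, expr.feature_kind, name=expr.name, method=method)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.states.columns)

    def samples_of(self, phenotype: str) -> list[str]:
        return list(self.phenotype.index[self.phenotype == phenotype])

    def mirna_features(self) -> set[str]:
        return set(self.feature_kind.index[self.feature_kind == MIRNA])
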