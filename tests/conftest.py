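import numpy as np
import pandas as pd
import pytest

from pathwaybn import ExpressionMatrix


def make_expr(values, phenotype=None, kinds=None, name="test", calls=None):
    """Build an ExpressionMatrix from a plain array (features x samples)."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = [f"f{i + 1}" for i in range(n_feat)]
    samples = [f"s{j + 1}" for j in range(n_samp)]
    if phenotype is None:
        half = n_samp // 2
        phenotype = ["groupA"] * half + ["groupB"] * (n_samp - half)
    pheno = pd.Series(phenotype, index=samples)
    kind = pd.Series(kinds or ["mRNA"] * n_feat, index=features)
    calls_df = None
    if calls is not None:
        calls_df = pd.DataFrame(calls, index=features, columns=samples)
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples),
        pheno, kind, present_calls=calls_df, name=name,
    )


@pytest.fixture
def single_array():
    """One-sample panel factory: column vector from a list of values."""

    def build(values):
        return make_expr(np.asarray(values, dtype=float)[:, None], phenotype=["groupA"])

    return build
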