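import numpy as np
import pandas as pd
import pytest

from otokit.matrix import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tpm():
    """The 3-gene x 2-cell hand-oracle matrix for median-of-ratios."""
    df = pd.DataFrame(
        [[2.0, 8.0], [4.0, 16.0], [0.0, 1.0]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2"],
    )
    return ExpressionMatrix(df, "TPM")


@pytest.fixture
def random_log2(rng):
    values = np.abs(rng.normal(5.0, 1.0, size=(40, 30)))
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(40)],
                     columns=[f"c{i}" for i in range(30)]),
        "log2nTPM",
    )


def make_matrix(values, units="nTPM", prefix=("g", "c")):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix[0]}{i}" for i in range(values.shape[0])],
            columns=[f"{prefix[1]}{i}" for i in range(values.shape[1])],
        ),
        units,
    )
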