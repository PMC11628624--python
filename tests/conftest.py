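import numpy as np
import pandas as pd
import pytest

from notchsig import (
    ExpressionMatrix,
    GeneSignature,
    load_packaged_signature,
)


@pytest.fixture(scope="session")
def notch77() -> GeneSignature:
    return load_packaged_signature("TNBC_NOTCH_77")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 samples, 2 genes with opposite orderings."""
    return ExpressionMatrix(
        pd.DataFrame(
            {
                "s1": [1.0, 4.0],
                "s2": [2.0, 3.0],
                "s3": [3.0, 2.0],
                "s4": [4.0, 1.0],
            },
            index=["G1", "G2"],
        )
    )
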