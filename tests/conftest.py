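import numpy as np
import pandas as pd
import pytest

from tsgcompare.expression import ExpressionMatrix
from tsgcompare.tsg import TissueGroupScheme


@pytest.fixture
def simple_scheme() -> TissueGroupScheme:
    """Three groups over four samples; 'siphons' is composite."""
    return TissueGroupScheme.from_dict(
        {
            "siphons": ["oral", "atrial"],
            "neural_complex": ["nc"],
            "heart": ["heart"],
        }
    )


@pytest.fixture
def ascidian_scheme() -> TissueGroupScheme:
    """The study's tissue grouping: 11 samples, 9 groups."""
    from tsgcompare.simulate import default_scheme

    return default_scheme()


def make_matrix(rows: dict[str, list[float]], samples: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=samples), units="rpkm"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
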