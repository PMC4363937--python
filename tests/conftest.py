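import numpy as np
import pandas as pd
import pytest

from coexnet.ranking import ExpressionMatrix


@pytest.fixture
def toy_expr():
    """4-sample matrix with hand-checkable correlation structure."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 4.0, 1.0, 5.0],
            "s2": [2.0, 4.0, 3.0, 1.0, 5.0],
            "s3": [3.0, 6.0, 2.0, 2.0, 5.0],
            "s4": [4.0, 8.0, 1.0, 1.0, 5.0],
        },
        index=["idx", "double", "anti", "bump", "flat"],
    )
    return ExpressionMatrix(values=values, classes=["a", "a", "b", "b"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
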