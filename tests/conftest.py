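import numpy as np
import pandas as pd
import pytest

from pairmir import ExpressionMatrix, PairedDesign, SamplePair


@pytest.fixture
def toy_design():
    return PairedDesign(
        [
            SamplePair("rat1", "A1", "V1"),
            SamplePair("rat2", "A2", "V2"),
            SamplePair("rat3", "A3", "V3"),
        ]
    )


@pytest.fixture
def toy_matrix(toy_design):
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8.0, 2.0, size=(20, 6)),
        index=[f"mir{i}" for i in range(20)],
        columns=["A1", "V1", "A2", "V2", "A3", "V3"],
    )
    return ExpressionMatrix(values, "log2")
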