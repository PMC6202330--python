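import numpy as np
import pandas as pd
import pytest

from slpen import GeneScoreMatrix, StatusCall
from slpen.rb_classify import DEFECTIVE, NOT_ALTERED


@pytest.fixture
def small_matrix() -> GeneScoreMatrix:
    """3 genes x 6 lines, one value missing."""
    df = pd.DataFrame(
        {
            "L1": [-2.5, 0.1, -0.3],
            "L2": [-3.0, 0.4, 0.2],
            "L3": [-2.2, np.nan, -0.1],
            "L4": [0.3, -0.2, 0.0],
            "L5": [0.8, 0.5, -0.4],
            "L6": [-0.1, -0.6, 0.6],
        },
        index=["SLG", "NULL1", "NULL2"],
    )
    return GeneScoreMatrix(df, "zgarp")


@pytest.fixture
def small_calls() -> list[StatusCall]:
    """L1-L3 defective, L4-L6 not altered."""
    return [
        StatusCall("L1", DEFECTIVE, frozenset({"mrna_low"})),
        StatusCall("L2", DEFECTIVE, frozenset({"truncating_mutation"})),
        StatusCall("L3", DEFECTIVE, frozenset({"protein_low"})),
        StatusCall("L4", NOT_ALTERED),
        StatusCall("L5", NOT_ALTERED),
        StatusCall("L6", NOT_ALTERED),
    ]
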