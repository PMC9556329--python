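import numpy as np
import pandas as pd
import pytest

from immunopred.features import AbundanceMatrix
from immunopred.panel import PanelDefinition, Tube


def make_matrix(values, timepoint="pre", prefix="T01", sample_prefix="S"):
    """Wrap a 2-D array as an AbundanceMatrix with parseable feature ids."""
    values = np.asarray(values, dtype=float)
    cols = [f"{prefix}:F{j}+" for j in range(values.shape[1])]
    idx = [f"{sample_prefix}{i:03d}" for i in range(values.shape[0])]
    return AbundanceMatrix(
        data=pd.DataFrame(values, index=idx, columns=cols), timepoint=timepoint
    )


@pytest.fixture
def three_marker_panel():
    """One tube of three markers plus the classic impossible-pair rule."""
    return PanelDefinition(
        tubes=(Tube(tube_id="T01", markers=("CD3", "CD19", "CD4")),),
        exclusion_rules=(frozenset({"CD3+", "CD19+"}),),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
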