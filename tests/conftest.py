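import numpy as np
import pandas as pd
import pytest

from immunotrack import RepertoireSample


def make_sample(counts, productive=None, sample_id="s", total_nucleated_cells=None):
    """Small repertoire from a list of template counts."""
    counts = list(counts)
    if productive is None:
        productive = [True] * len(counts)
    df = pd.DataFrame(
        {
            "rearrangement": [f"c{i}" for i in range(len(counts))],
            "amino_acid": "",
            "templates": counts,
            "productive": productive,
        }
    )
    return RepertoireSample(
        sample_id=sample_id, clonotypes=df, total_nucleated_cells=total_nucleated_cells
    )


@pytest.fixture
def simple_sample():
    return make_sample([5, 3, 2])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
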