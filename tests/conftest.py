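import numpy as np
import pandas as pd
import pytest

from epipattern.design import make_design
from epipattern.simulate import SimulationConfig


@pytest.fixture
def design():
    return make_design()


@pytest.fixture
def small_config():
    return SimulationConfig(n_genes=40, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def six_sample_groups():
    return ["A", "A", "A", "B", "B", "B"]


def methylation_frame(meth, total, sample_ids, chrom="chr1"):
    """Assemble a methylation count table from matrices."""
    n = meth.shape[0]
    table = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(n) * 100, "strand": "+"}
    )
    for j, s in enumerate(sample_ids):
        table[f"meth_{s}"] = meth[:, j]
        table[f"total_{s}"] = total[:, j]
    return table
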