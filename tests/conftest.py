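import numpy as np
import pandas as pd
import pytest

from cimp_atlas.core_io import CGI, BetaMatrix, GeneModel
from cimp_atlas.synthetic import SimConfig


@pytest.fixture
def small_beta():
    """Tiny beta matrix: 4 CGIs x 10 samples across 3 groups."""
    rng = np.random.default_rng(7)
    samples = [f"IDH_{i}" for i in range(4)] + [f"MES_{i}" for i in range(3)] + \
              [f"Normal_{i}" for i in range(3)]
    groups = {s: s.split("_")[0] for s in samples}
    values = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(4, len(samples))),
        index=[f"cgi_{i}" for i in range(4)],
        columns=samples,
    )
    return BetaMatrix(values, groups)


@pytest.fixture
def genes():
    return [
        GeneModel("geneA", "geneA", "chr1", "+", 10_000, 10_000, 15_000),
        GeneModel("geneB", "geneB", "chr1", "-", 29_999, 25_000, 30_000),
        GeneModel("geneC", "geneC", "chr2", "+", 1_000, 1_000, 5_000),
    ]


@pytest.fixture
def small_config():
    return SimConfig(n_cgi=500, n_planted_idh=40, n_planted_rtk2=40, seed=11)
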