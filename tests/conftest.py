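import numpy as np
import pandas as pd
import pytest

from argenrich.io_formats import (
    ROLE_ELUATE,
    ROLE_INPUT,
    IntensityTable,
    SampleDesign,
    SampleLabel,
)
from argenrich.synthetic_data import SimConfig, make_design, simulate_experiment


@pytest.fixture
def design3() -> SampleDesign:
    """Standard layout: 1 input + 3 eluate columns per genotype."""
    return make_design(3)


def make_table(values, design, protein_ids=None, genes=None, razor=None):
    """Small IntensityTable helper for hand-built fixtures."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(n)]
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    if razor is None:
        razor = pd.DataFrame({"WT": [5] * n, "KO": [5] * n}, index=protein_ids)
    return IntensityTable(protein_ids, genes, razor, design, values)


@pytest.fixture
def tiny_design() -> SampleDesign:
    """Minimal layout: 1 input + 2 eluate columns per genotype."""
    return make_design(2)


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated experiment shared across read-only tests."""
    cfg = SimConfig(n_proteins=80, seed=11)
    return cfg, simulate_experiment(cfg)
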