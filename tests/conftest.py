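import numpy as np
import pandas as pd
import pytest

from famevol import datasets
from famevol.simulate import (
    SimulationConfig,
    example_profile_panel,
    simulate_ct_table,
    simulate_fractionation,
)


@pytest.fixture(scope="session")
def copy_table():
    return datasets.load_copy_table()


@pytest.fixture(scope="session")
def species_tree():
    return datasets.load_species_tree()


@pytest.fixture(scope="session")
def presence_matrix():
    return datasets.load_presence_matrix()


@pytest.fixture(scope="session")
def gene_records():
    return datasets.load_gene_table()


@pytest.fixture(scope="session")
def noise_free_ct():
    """Noise-free simulated Ct table with the example planted panel."""
    config = SimulationConfig(seed=11, noise_sd=0.0)
    panel = example_profile_panel(config)
    return simulate_ct_table(config, panel), panel


@pytest.fixture()
def tiny_ct_table():
    """Hand-built one-gene Ct table realizing the ddCt worked example:
    treated target 20 vs reference 18, control target 22 vs reference 18,
    so ddCt = -2 and fold = 4."""
    rows = []
    for rep in (1, 2, 3):
        rows += [
            ("geneX", "ABA", 0.0, rep, "treated", 22.0),
            ("geneX", "ABA", 0.0, rep, "control", 22.0),
            ("geneX", "ABA", 24.0, rep, "treated", 20.0),
            ("geneX", "ABA", 24.0, rep, "control", 22.0),
            ("ref", "ABA", 0.0, rep, "treated", 18.0),
            ("ref", "ABA", 0.0, rep, "control", 18.0),
            ("ref", "ABA", 24.0, rep, "treated", 18.0),
            ("ref", "ABA", 24.0, rep, "control", 18.0),
        ]
    return pd.DataFrame(
        rows,
        columns=["gene", "treatment", "timepoint_h", "replicate", "sample_class", "ct"],
    )
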