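import numpy as np
import pandas as pd
import pytest

from drugsense.simulate import (SimulationConfig, generate_cell_line_panel,
                                generate_patient_cohorts)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=60, n_cell_lines=150, n_drugs=2,
                            n_gbm=40, n_control=40, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_cell_line_panel(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_panel):
    _, _, truth = small_panel
    return generate_patient_cohorts(small_config, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def toy_expression():
    """3-gene, 6-sample deterministic expression matrix."""
    return pd.DataFrame(
        np.arange(18, dtype=float).reshape(3, 6) ** 1.5,
        index=["GA", "GB", "GC"],
        columns=[f"S{i}" for i in range(6)])
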