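import warnings

import numpy as np
import pandas as pd
import pytest

from tmedyn.simulate import SimulationConfig, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient cohort with the default planted blocks (session-shared)."""
    config = SimulationConfig(n_patients=60, n_genes=350, seed=1)
    return simulate_cohort(config)


@pytest.fixture()
def tiny_expr():
    rng = np.random.default_rng(0)
    genes = [f"g{i + 1}" for i in range(5)]
    return pd.DataFrame(
        rng.uniform(0, 8, (5, 4)), index=genes, columns=["A", "B", "C", "D"]
    )
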