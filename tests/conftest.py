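import numpy as np
import pytest

from sixmodel import (
    DoseResponseTable,
    LogisticParams,
    PanelScenario,
    predict_growth,
)

EIGHT_DOSES = np.geomspace(0.02, 20.0, 8)


@pytest.fixture
def clean_params():
    """Truth satisfying every variant's constraints (a=100, d=0, b=1)."""
    return LogisticParams(a=100.0, b=1.0, c=2.0, d=0.0)


@pytest.fixture
def clean_table(clean_params):
    """Noise-free 8-dose table generated from clean_params, 3 replicates."""
    x = np.repeat(EIGHT_DOSES, 3)
    return DoseResponseTable("clean", x, predict_growth(clean_params, x))


@pytest.fixture
def noisy_table_factory():
    """Factory for seeded noisy tables from arbitrary truth."""

    def make(params: LogisticParams, seed: int, noise_sd: float = 5.0,
             n_replicates: int = 3, doses=EIGHT_DOSES) -> DoseResponseTable:
        scenario = PanelScenario(
            cell_ids=["cell"], true_params=[params], doses=np.asarray(doses),
            n_replicates=n_replicates, noise_sd=noise_sd, seed=seed,
        )
        from sixmodel import simulate_panel

        return simulate_panel(scenario)[0]

    return make
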