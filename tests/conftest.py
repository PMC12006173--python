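import numpy as np
import pytest

import camkii_spine as ck


@pytest.fixture(scope="session")
def params():
    return ck.load_params()


@pytest.fixture(scope="session")
def tables(params):
    return ck.build_rate_tables(params)


@pytest.fixture(scope="session")
def reduced_params():
    """Desk-scale reduced system: 6 holoenzymes, 29 CaM, 2 PP1."""
    return ck.load_params(
        counts={"n_holoenzymes": 6},
        concentrations={"conc_CaM_total_uM": 29 / (ck.AVOGADRO * 0.016e-15) * 1e6,
                        "conc_PP1_uM": 2 / (ck.AVOGADRO * 0.016e-15) * 1e6},
    )


@pytest.fixture(scope="session")
def default_trajectory(params):
    """One full default run (seed 0), reused by several checks."""
    return ck.run_simulation(params, ck.RunConfig(seed=0, t_end=11.0))
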