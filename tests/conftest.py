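import warnings

import numpy as np
import pytest

import pinenir as pn

# NIPALS early-stop and rank-truncation warnings are expected on tiny or
# noiseless fixtures; keep test output clean.
warnings.filterwarnings("ignore", message="NIPALS stopped")
warnings.filterwarnings("ignore", message="max_lv=")


@pytest.fixture(scope="session")
def default_set():
    """Synthetic seed set at pinned default conditions (seed 1)."""
    return pn.simulate(pn.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def clean_set():
    """All replicate disturbances off: spectra are exact component mixtures."""
    cfg = pn.SimulationConfig(seed=1, scatter_sd=0.0, baseline_offset_sd=0.0,
                              baseline_slope_sd=0.0, noise_sd=0.0,
                              water_replicate_sd=0.0)
    return pn.simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


REDUCED_COMBOS = [("R1",), ("R3",), ("R1", "R3"),
                  ("R1", "R2", "R3", "R4", "R5")]


@pytest.fixture(scope="session")
def reduced_combos():
    return list(REDUCED_COMBOS)
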