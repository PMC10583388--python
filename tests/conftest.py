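import copy

import pytest

from nevolt.config import RunConfig, load_presets


@pytest.fixture(scope="session")
def presets():
    return load_presets()


@pytest.fixture(scope="session")
def quiet_presets(presets):
    """Presets with all stochastic components switched off (noiseless runs)."""
    p = copy.deepcopy(presets)
    p["electrode"].update(
        noise_sd_nA=0.0, drift_rate_nA_per_min=0.0, drift_rw_sd_nA=0.0
    )
    p["subjects"]["gain_sigma"] = 0.0
    return p


@pytest.fixture()
def cfg():
    return RunConfig()
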