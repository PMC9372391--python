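import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from uavagb.extract import synthetic_feature_table
from uavagb.synthetic_scene import SceneConfig, generate_endmembers, generate_scene

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

#: one shared seed for the session-scoped fixtures
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def default_scene_fp():
    """One flowering-stage scene at the default (noisy) configuration."""
    config = SceneConfig(seed=FIXTURE_SEED, stage="FP")
    cube, dsm, dem, truth, plots = generate_scene(config)
    return {"config": config, "cube": cube, "dsm": dsm, "dem": dem,
            "truth": truth, "plots": plots,
            "lib": generate_endmembers("FP", FIXTURE_SEED)}


@pytest.fixture(scope="session")
def noisefree_scene_tp():
    """A noise-free tuber-stage scene (exact linear mixtures)."""
    config = SceneConfig(seed=FIXTURE_SEED, stage="TP", mixing_noise_sd=0.0)
    cube, dsm, dem, truth, plots = generate_scene(config)
    return {"config": config, "cube": cube, "dsm": dsm, "dem": dem,
            "truth": truth, "plots": plots,
            "lib": generate_endmembers("TP", FIXTURE_SEED)}


@pytest.fixture(scope="session")
def feature_table():
    """The pooled 144-sample, 39-candidate feature table (default trial)."""
    table, band, direction = synthetic_feature_table(FIXTURE_SEED)
    return {"table": table, "band": band, "direction": direction}
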