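import numpy as np
import pytest
from hypothesis import settings

from pigeongaze import (
    default_calibration,
    default_scene_config,
    generate_flock_trajectories,
    random_scenario,
    run_pipeline,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture()
def config():
    return default_scene_config()


@pytest.fixture()
def calib():
    return default_calibration()


@pytest.fixture(scope="session")
def flock():
    """One seeded 10-bird session shared by the recovery-style tests:
    scenario, emitted markers, ground truth and the full pipeline result."""
    cfg = default_scene_config()
    scenario = random_scenario(cfg, n_birds=10, seed=1, n_sub_threshold=5)
    cal = default_calibration()
    markers, truth = generate_flock_trajectories(scenario, cal, cfg)
    result = run_pipeline(
        markers, {b: cal for b in markers.bird_ids}, scenario.schedule, cfg
    )
    return {
        "config": cfg,
        "scenario": scenario,
        "calib": cal,
        "markers": markers,
        "truth": truth,
        "result": result,
    }
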