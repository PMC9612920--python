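import numpy as np
import pytest
from dataclasses import replace

from mmnadd.paradigm import DeviantType
from mmnadd.simulate import SimulationConfig, make_layout, simulate_subject


@pytest.fixture(scope="session")
def layout24():
    return make_layout(24, seed=0)


@pytest.fixture(scope="session")
def layout51():
    return make_layout(51, seed=1)


@pytest.fixture()
def quiet_config():
    """Small noise-free configuration with all kappas zero."""
    cfg = SimulationConfig(n_subjects_per_group=2, trials_per_deviant=4, n_pairs=24)
    return replace(
        cfg,
        noise=replace(cfg.noise, sigma=0.0, subject_cv=0.0),
        kappa={"musician": {}, "nonmusician": {}},
    )


@pytest.fixture()
def noisy_epochs(layout24):
    """One subject's raw epochs at default noise, no artifacts."""
    cfg = SimulationConfig(
        n_subjects_per_group=1,
        trials_per_deviant=6,
        n_pairs=24,
        conditions=(DeviantType.STD, DeviantType.F, DeviantType.I, DeviantType.FI),
    )
    return simulate_subject(cfg, layout24, "musician", 7, subject_id="s0")
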