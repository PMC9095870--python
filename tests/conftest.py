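import pytest

from laminamod import AnalysisConfig, SimConfig, generate_spikes, generate_trials, generate_units


@pytest.fixture(scope="session")
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim_cfg() -> SimConfig:
    return SimConfig(n_rs_per_layer=6, n_fs_per_layer=2, n_reps=4)


@pytest.fixture(scope="session")
def small_session(small_sim_cfg):
    """One small synthetic session shared by read-only tests."""
    units, truth = generate_units(small_sim_cfg, seed=7)
    trials = generate_trials(small_sim_cfg, seed=8)
    units = generate_spikes(units, trials, truth, seed=9, cfg=small_sim_cfg)
    return units, trials, truth
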