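import pytest

from opcond import default_config, run_ensemble


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def fast_config():
    """Small, quick protocol for tests that only need mechanics, not anchors."""
    return default_config().replace(
        **{
            "protocol.n_trials": 30,
            "protocol.steps_lever_out": 20,
            "protocol.steps_iti": 5,
            "network.n_pfc": 12,
        }
    )


@pytest.fixture(scope="session")
def ensemble_100(config):
    """The full tuned 100-model ensemble (shared across acceptance tests)."""
    import time

    t0 = time.perf_counter()
    traj = run_ensemble(config, n_models=100, base_seed=1)
    traj.wall_time_s = time.perf_counter() - t0
    return traj
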