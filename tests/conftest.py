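import numpy as np
import pytest

from lexidcm import dynamics, network, preprocess, synthetic
from lexidcm.forward import helmet_array


@pytest.fixture(scope="session")
def standard_network():
    return network.build_standard_network()


@pytest.fixture(scope="session")
def desk_space():
    """Two-source single-hemisphere network with forward, backward and joint
    self-modulation switches: an eight-model desk space."""
    net = network.build_test_network(2, ("left",))
    groups = network.independent_groups(net, include_self_group=True)
    return network.enumerate_model_space(net, groups)


@pytest.fixture(scope="session")
def desk_sensors():
    return helmet_array(32)


@pytest.fixture(scope="session")
def desk_true_index(desk_space):
    names = [g.name for g in desk_space.groups]
    return 1 << names.index("LOCC->LvOT")


def make_desk_dataset(desk_space, desk_sensors, true_index, seed, n_subjects=1,
                      gain=1.5, snr=10.0, n_trials=50):
    """One synthetic desk-scale MEG group plus robust-averaged evoked pairs."""
    cfg = synthetic.MEGSimConfig(
        space=desk_space,
        true_pattern_index=true_index,
        true_gains={"LOCC->LvOT": gain},
        n_trials=n_trials,
        n_catch=0,
        snr=snr,
        n_subjects=n_subjects,
        n_sensors=desk_sensors.n_sensors,
        window_ms=(-100.0, 250.0),
        seed=seed,
    )
    epochs, lf, truth = synthetic.generate_meg_group(cfg, desk_sensors)
    pairs = []
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ep in epochs:
            pairs.append(
                (
                    preprocess.robust_average(ep, "untrained"),
                    preprocess.robust_average(ep, "trained"),
                )
            )
    return pairs, lf, truth


@pytest.fixture(scope="session")
def desk_dataset(desk_space, desk_sensors, desk_true_index):
    """Single-subject generate-and-recover dataset reused across tests."""
    pairs, lf, truth = make_desk_dataset(desk_space, desk_sensors, desk_true_index, seed=42)
    return pairs[0], lf, truth


@pytest.fixture(scope="session")
def desk_base_params(desk_space):
    return dynamics.default_parameters(desk_space.network)
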