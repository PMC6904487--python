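import numpy as np
import pytest

import ssvepkit as sk


@pytest.fixture(scope="session")
def spec28():
    """Default 28-key QWERTY flicker design (10.0-15.4 Hz, 1.5pi-0.95pi)."""
    return sk.build_flicker_spec()


@pytest.fixture(scope="session")
def toy_spec():
    """Small 6-key design for fast classifier/sweep tests."""
    return sk.build_flicker_spec(n_keys=6)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return sk.SimConfig(noise_amplitude=0.0, alpha_amplitude=0.0, seed=1)


@pytest.fixture(scope="session")
def noiseless_bank28(spec28, noiseless_cfg):
    """Full-pipeline bank trained on noiseless 28-key data (shared)."""
    training = sk.preprocess(sk.simulate_training_set(spec28, noiseless_cfg, reps_per_key=2))
    channels = sk.select_channels(training, training.channel_names, k=4, spec=spec28)
    bank = sk.build_template_bank(
        training.select_channels(channels), spec28, selected_channels=channels
    )
    return bank


@pytest.fixture(scope="session")
def toy_noisy_setup(toy_spec):
    """Moderate-noise 6-key training set, channels and bank (shared)."""
    cfg = sk.SimConfig(noise_amplitude=2.0, seed=7)
    training = sk.preprocess(sk.simulate_training_set(toy_spec, cfg, reps_per_key=8))
    channels = sk.select_channels(training, training.channel_names, k=4, spec=toy_spec)
    bank = sk.build_template_bank(
        training.select_channels(channels), toy_spec, selected_channels=channels
    )
    return toy_spec, cfg, training, channels, bank


def pipeline_accuracy(spec, cfg, reps_per_key, test_cfg=None, n_test_cycles=1, double=False):
    """Simulate -> preprocess -> train -> classify; return test accuracy."""
    training = sk.preprocess(
        sk.simulate_training_set(spec, cfg, reps_per_key=reps_per_key, double_epoch=double)
    )
    channels = sk.select_channels(training, training.channel_names, k=4, spec=spec)
    bank = sk.build_template_bank(
        training.select_channels(channels), spec, selected_channels=channels
    )
    test_cfg = test_cfg or cfg.replace(seed=cfg.seed + 10_000)
    test = sk.preprocess(
        sk.simulate_typing_epochs(
            list(spec.key_order) * n_test_cycles, spec, test_cfg, double_epoch=double
        )
    )
    return sk.evaluate_accuracy(test, bank)
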