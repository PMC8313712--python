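import numpy as np
import pytest

from sctrnnpb import (
    NetworkConfig,
    TrainingConfig,
    generate_dataset,
    init_params,
    fit_and_scale,
    train,
)


@pytest.fixture(scope="session")
def small_raw_dataset():
    """6 emotions x 3 sequences, short, for fast preprocessing tests."""
    return generate_dataset(n_per_emotion=3, length_range=(5, 12), noise_sd=0.02, seed=42)


@pytest.fixture(scope="session")
def small_targets(small_raw_dataset):
    targets, scaler = fit_and_scale(small_raw_dataset)
    return targets, scaler


@pytest.fixture
def tiny_config():
    return NetworkConfig(n_input=2, n_lower=3, n_pb=2, K=1.0, tau_lower=2.0, seed=5)


@pytest.fixture
def tiny_params(tiny_config):
    return init_params(tiny_config)


@pytest.fixture(scope="session")
def study_runs():
    """The standard desk-scale study: heterogeneous (K=1000) and
    homogeneous (K=0.001) networks plus the no-normalization ablation,
    five seeds each.  Shared by the acceptance tests; this is the
    expensive fixture (roughly ten minutes of training)."""
    from sctrnnpb.study import K_HETEROGENEOUS, K_HOMOGENEOUS, run_study_condition

    runs = {}
    for seed in range(5):
        runs[("hetero", seed)] = run_study_condition(K_HETEROGENEOUS, seed)
        runs[("homo", seed)] = run_study_condition(K_HOMOGENEOUS, seed)
        runs[("nonorm", seed)] = run_study_condition(
            K_HETEROGENEOUS, seed, normalization_enabled=False,
            with_recognition=False,
        )
    return runs


@pytest.fixture(scope="session")
def trained_tiny_model():
    """A small network trained on a few short sequences until it fits well.

    Used by recognition and evaluation tests that need a converged model
    but not the full study scale.
    """
    data = generate_dataset(n_per_emotion=2, length_range=(8, 14), noise_sd=0.01, seed=3)
    targets, _ = fit_and_scale(data)
    config = NetworkConfig(n_input=9, n_lower=20, n_pb=2, K=1000.0, seed=3)
    tconfig = TrainingConfig(
        n_iterations=3000, eval_every=1000, input_noise_sd=0.1, seed=3
    )
    result = train(targets, config, tconfig)
    return config, result, targets
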