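import numpy as np
import pytest

from ppgid.synth import GeneratorConfig, build_dataset, make_subject_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile(rng):
    return make_subject_profile(rng, subject_id="S00")


@pytest.fixture(scope="session")
def small_raw_dataset():
    """3 subjects x 6 signals, defaults otherwise."""
    return build_dataset(GeneratorConfig(n_subjects=3, signals_per_subject=6, seed=7))


@pytest.fixture(scope="session")
def trained_tiny():
    """A quickly trained tiny model on a 4-subject cohort, shared read-only.

    Returns (result, config) where config carries the generator seed, so
    tests can re-derive the training subjects' profiles.
    """
    import dataclasses

    from ppgid.pipeline import parameter_recovery_run
    from ppgid.synth import GeneratorConfig

    cfg = dataclasses.replace(
        GeneratorConfig(n_subjects=4, signals_per_subject=30, noise_sd=300.0), seed=3
    )
    return parameter_recovery_run(seed=3, config=cfg, epochs=25), cfg
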