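"""Shared fixtures: all data is generated in-process by the simulator."""

import numpy as np
import pytest

import ecgverify as ev


@pytest.fixture(scope="session")
def separable_dataset():
    """Two zero-noise subjects with clearly distinct morphology, L=256."""
    cohort = ev.generate_cohort(
        2, duration=120, fs=500, seed=11, noise_sd=0.0, baseline_amp=0.0
    )
    dataset = {}
    for rec in cohort.records:
        for fm in ev.preprocess_record(rec, 256):
            dataset.setdefault(fm.subject_id, []).append(fm)
    return dataset


@pytest.fixture(scope="session")
def separable_training(separable_dataset):
    """Model trained to convergence on the separable two-subject task."""
    bundles = ev.build_bundles(
        separable_dataset, n_ref=3, n_pos=100, n_neg=100, seed=5
    )
    cfg = ev.EncoderConfig(epochs=20, seed=7, batch_size=32)
    result = ev.train(bundles, cfg)
    return result, bundles


@pytest.fixture(scope="session")
def init_model():
    """Untrained encoder (L=256) for contract tests that need no fitting."""
    return ev.SiameseModel.initialize(ev.EncoderConfig(seed=0), 256)


@pytest.fixture(scope="session")
def small_cohort():
    """Five noisy subjects, one 30 s record each at 500 Hz."""
    return ev.generate_cohort(5, duration=30, fs=500, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    dataset = {}
    for rec in small_cohort.records:
        for fm in ev.preprocess_record(rec, 256):
            dataset.setdefault(fm.subject_id, []).append(fm)
    return dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
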