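import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dvjrel.simulate import (
    DVJSpec,
    NoiseSpec,
    generate_static_trial,
    generate_trial,
)
from dvjrel.skeleton import build_skeleton
from dvjrel.trial import Subject

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def subject():
    return Subject("S01", 62.3, 169.3)


@pytest.fixture(scope="session")
def model(subject):
    return build_skeleton(subject)


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseSpec.zero()


@pytest.fixture(scope="session")
def clean_trial(model, zero_noise):
    """Zero-noise DVJ trial plus its ground truth."""
    trial, truth = generate_trial(model, DVJSpec(), zero_noise, seed=1)
    return trial, truth


@pytest.fixture(scope="session")
def clean_static(model, zero_noise):
    return generate_static_trial(model, zero_noise, seed=2)


@pytest.fixture(scope="session")
def noisy_trial(model):
    trial, truth = generate_trial(model, DVJSpec(), NoiseSpec(), seed=7)
    return trial, truth


def small_trial(n_frames=5, n_markers=3, ratio=5, seed=0, with_gap=False):
    """Tiny hand-rolled Trial for I/O tests."""
    from dvjrel.trial import ForcePlate, Trial

    rng = np.random.default_rng(seed)
    markers = rng.normal(size=(n_frames, n_markers, 3)) * 100.0
    valid = np.ones((n_frames, n_markers), dtype=bool)
    if with_gap:
        valid[1:3, 0] = False
        markers[1:3, 0] = np.nan
    plates = [
        ForcePlate(
            force=rng.normal(size=(n_frames * ratio, 3)),
            moment=rng.normal(size=(n_frames * ratio, 3)),
        )
    ]
    return Trial(
        markers=markers,
        valid=valid,
        labels=[f"M{i}" for i in range(n_markers)],
        marker_rate=240.0,
        plates=plates,
        force_rate=240.0 * ratio,
        subject=Subject("X1", 60.0, 170.0),
        site="A",
        trial_index=2,
        static=False,
    )
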