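"""Shared fixtures: synthetic bones are expensive, so build them once."""

import numpy as np
import pytest

from osteoreduce.anatomy import GenerationParams, generate_humerus, generate_pair, mirror_model
from osteoreduce.fracture import cut_supracondylar, displace_distal, random_perturbation
from osteoreduce.landmarks import detect_landmarks


@pytest.fixture(scope="session")
def default_params():
    return GenerationParams(seed=7)


@pytest.fixture(scope="session")
def right_model(default_params):
    """Noiseless right humerus with exact ground truth."""
    return generate_humerus(default_params, side="right")


@pytest.fixture(scope="session")
def noisy_model():
    """Right humerus with 0.2 mm surface noise."""
    return generate_humerus(
        GenerationParams(seed=13, surface_noise_sd=0.2), side="right"
    )


@pytest.fixture(scope="session")
def detected_intact(right_model):
    return detect_landmarks(right_model.mesh)


@pytest.fixture(scope="session")
def mirror_pair():
    """Exact mirror pair (asymmetry 0) from one seed."""
    return generate_pair(GenerationParams(seed=1))


@pytest.fixture(scope="session")
def template_landmarks(mirror_pair):
    """Detected landmarks of the mirrored healthy (left) bone."""
    _, left = mirror_pair
    return detect_landmarks(mirror_model(left).mesh)


@pytest.fixture(scope="session")
def displaced_state(mirror_pair):
    """Fractured + displaced right bone of the mirror pair."""
    right, _ = mirror_pair
    state = cut_supracondylar(right)
    rng = np.random.default_rng(42)
    return displace_distal(
        state, random_perturbation(rng, about=right.truth.fea.point)
    )
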