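import logging

import numpy as np
import pytest

from wingmorph.datatypes import Dataset, LandmarkConfiguration, Specimen

logging.getLogger("wingmorph").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20230424)


def make_landmark_dataset(shapes, populations):
    """Build a Dataset from a list of (k, 2) arrays and population labels."""
    configs = [
        LandmarkConfiguration(Specimen(f"{pop}_{i}", pop), np.asarray(arr, float))
        for i, (arr, pop) in enumerate(zip(shapes, populations))
    ]
    return Dataset.from_configurations(configs)


@pytest.fixture
def triangle():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])


def random_similarity(rng, coords):
    """Apply a random rotation, translation and positive scaling."""
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    scale = rng.uniform(0.5, 3.0)
    shift = rng.uniform(-10, 10, size=2)
    return coords @ rot.T * scale + shift
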