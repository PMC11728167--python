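"""Shared fixtures: synthetic datasets and fitted pipelines.

Session scope keeps the expensive artifacts (the full 300-kernel dataset
and the default fitted pipeline) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from kernelbreak.pipeline import BrokenRateModel
from kernelbreak.synth import generate_dataset


@pytest.fixture(scope="session")
def full_dataset():
    """The default study dataset: 180 broken / 120 unbroken, seed 2018."""
    return generate_dataset(seed=2018)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast unit tests."""
    return generate_dataset(n_broken=40, n_unbroken=30, seed=7)


@pytest.fixture(scope="session")
def default_results(full_dataset):
    """Default fitted pipeline: SVM classifier (grid-searched), LGBM/RF
    weight regressors at the shipped default hyperparameters."""
    return BrokenRateModel(full_dataset, seed=2018).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disc_mask(radius: int, pad: int = 5) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def ellipse_mask(a: float, b: float, rotation: float = 0.0, pad: int = 5) -> np.ndarray:
    half = int(np.ceil(max(a, b))) + pad
    size = 2 * half + 1
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - half, yy - half
    u = dx * np.cos(rotation) + dy * np.sin(rotation)
    v = -dx * np.sin(rotation) + dy * np.cos(rotation)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
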