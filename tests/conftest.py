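"""Shared fixtures: analytic patches, small phantoms and a small trained cascade.

Everything is generated programmatically at test time; the heavier trained
objects are session-scoped so the price is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from vitreoseg.autocontext import train_autocontext
from vitreoseg.features import PATCH_SIZE, learn_filter_bank
from vitreoseg.phantom import PhantomSpec, generate_phantom
from vitreoseg.region_model import RegionModelConfig

VMA_CYCLE = ("attached", "shallow_vma", "steep_vma", "complete_pvd")


def analytic_ridge(theta: float, size: int = PATCH_SIZE, sigma: float = 2.0) -> np.ndarray:
    """Gaussian ridge through the patch centre along direction ``theta``.

    Rendered directly from coordinates (no resampling), so its major axis is
    exactly ``theta`` modulo pi.
    """
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    x, y = xx - c, yy - c
    d = -x * np.sin(theta) + y * np.cos(theta)
    return np.exp(-(d**2) / (2.0 * sigma**2))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170607)


@pytest.fixture(scope="session")
def small_phantoms():
    """Four small ground-truthed phantoms, one per VMA class."""
    out = {}
    for i, cls in enumerate(VMA_CYCLE):
        spec = PhantomSpec(grid_shape=(8, 32, 64), vma_class=cls, noise_level=0.3, seed=40 + i)
        out[cls] = generate_phantom(spec)
    return out


@pytest.fixture(scope="session")
def noisefree_phantoms():
    out = {}
    for i, cls in enumerate(VMA_CYCLE):
        spec = PhantomSpec(grid_shape=(8, 32, 64), vma_class=cls, noise_level=0.0, seed=60 + i)
        out[cls] = generate_phantom(spec)
    return out


@pytest.fixture(scope="session")
def small_bank(small_phantoms):
    bscans = [
        vol.data[b]
        for cls in ("attached", "shallow_vma")
        for vol in [small_phantoms[cls][0]]
        for b in range(0, 8, 2)
    ]
    return learn_filter_bank(bscans, n_patches=1500, seed=0)


@pytest.fixture(scope="session")
def small_cascade(small_phantoms, small_bank):
    """One-iteration auto-context cascade trained on the small phantoms."""
    pairs = [(vol, truth.surfaces) for vol, truth in small_phantoms.values()]
    return train_autocontext(
        pairs,
        small_bank,
        n_iterations=1,
        model_config=RegionModelConfig(n_trees=15, per_class_cap=2000),
        seed=0,
    )
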