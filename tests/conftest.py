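"""Shared fixtures: canonical pixel shapes and small rendered fields."""

from __future__ import annotations

import numpy as np
import pytest

from angiomorph.markers import ScaleConfig
from angiomorph.synthetic import GeneratorParams, render_field, sample_field_spec


def digital_disc(radius: float, pad: int = 3) -> np.ndarray:
    """Binary mask of the digital disc x^2 + y^2 <= r^2."""
    n = int(2 * radius) + 1 + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def digital_annulus(r_outer: float, r_inner: float, pad: int = 3) -> np.ndarray:
    n = int(2 * r_outer) + 1 + 2 * pad
    yy, xx = np.mgrid[:n, :n]
    c = r_outer + pad
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    return (d2 <= r_outer**2) & (d2 > r_inner**2)


def random_blob(rng: np.random.Generator, size: int = 40, n_seeds: int = 4) -> np.ndarray:
    """A random connected-ish blob: union of a few random discs."""
    mask = np.zeros((size, size), dtype=bool)
    centres = rng.uniform(size * 0.3, size * 0.7, size=(n_seeds, 2))
    radii = rng.uniform(3, size * 0.18, size=n_seeds)
    yy, xx = np.mgrid[:size, :size]
    for (cy, cx), r in zip(centres, radii):
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


@pytest.fixture(scope="session")
def small_field():
    """One rendered 900 px field with a dozen vessels and its ground truth."""
    params = GeneratorParams(
        n_vessels=12, height_px=900, width_px=900, n_specks=20
    )
    spec = sample_field_spec(params, seed=7)
    image, truth = render_field(spec)
    return image, truth


@pytest.fixture(scope="session")
def scale_cfg():
    return ScaleConfig(seed=11)
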