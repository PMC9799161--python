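"""Shared fixtures.

Full-scale retinal computations (2048-pixel kernels and convolutions) are
expensive, so every target's retina is computed once per session and
shared by the reproduction tests; unit tests stick to toy geometries.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import retinaglare as rg

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

MONDRIAN_SEED = 1


@pytest.fixture(scope="session")
def kernel_2048():
    return rg.get_kernel(rg.AngularGeometry((2048, 2048), 10.0))


@pytest.fixture(scope="session")
def ca_bundles():
    return {v: rg.make_contrast_assimilation(v) for v in "ABCD"}


@pytest.fixture(scope="session")
def ca_retinas(ca_bundles, kernel_2048):
    return {
        v: rg.convolve(b.scene_luminance(), kernel_2048)
        for v, b in ca_bundles.items()
    }


@pytest.fixture(scope="session")
def mondrian_bundle():
    return rg.make_mondrian(MONDRIAN_SEED)


@pytest.fixture(scope="session")
def mondrian_retina(mondrian_bundle, kernel_2048):
    return rg.convolve(mondrian_bundle.scene_luminance(), kernel_2048)


@pytest.fixture(scope="session")
def mondrian_negative(mondrian_bundle):
    return rg.invert(mondrian_bundle, appearance_order=[("circle_top", "circle_bottom")])


@pytest.fixture(scope="session")
def mondrian_negative_retina(mondrian_negative, kernel_2048):
    return rg.convolve(mondrian_negative.scene_luminance(), kernel_2048)


@pytest.fixture(scope="session")
def todorovic_bundle():
    return rg.make_todorovic()


@pytest.fixture(scope="session")
def todorovic_retina(todorovic_bundle):
    kernel = rg.get_kernel(todorovic_bundle.geometry)
    return rg.convolve(todorovic_bundle.scene_luminance(), kernel)


@pytest.fixture
def toy_geometry():
    """16x16 image at a coarse pitch: kernel side 35, cheap to brute-force."""
    return rg.AngularGeometry((16, 16), field_of_view_deg=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
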