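"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from cdtmorph.gmf import build_dictionary
from cdtmorph.io_formats import GradientTable
from cdtmorph.synthetic import PhantomSpec, default_gradient_table, make_phantom


@pytest.fixture(scope="session")
def small_dictionary():
    """12 orientations + isotropic atom: the desk-scale registration dictionary."""
    return build_dictionary(n_orient=12)


@pytest.fixture(scope="session")
def default_dictionary():
    return build_dictionary()


@pytest.fixture(scope="session")
def gradient_table() -> GradientTable:
    return default_gradient_table()


@pytest.fixture(scope="session")
def noisefree_phantom():
    """Base phantom without noise, with its ground-truth GMF (default dictionary)."""
    spec = PhantomSpec(snr=np.inf, seed=1)
    dwi, truth = make_phantom(spec)
    return spec, dwi, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Small, small-dictionary phantom used by registration-heavy tests."""
    spec = PhantomSpec(shape=(24, 24, 16), snr=np.inf, seed=2, n_orient=12)
    dwi, truth = make_phantom(spec)
    return spec, dwi, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
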