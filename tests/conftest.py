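"""Shared fixtures: a small spherical forward model reused across tests."""

import numpy as np
import pytest

from mmnloc import forward as fw


@pytest.fixture(scope="session")
def head():
    return fw.default_head_model()


@pytest.fixture(scope="session")
def montage32(head):
    return fw.make_standard_montage(32, head)


@pytest.fixture(scope="session")
def montage64(head):
    return fw.make_standard_montage(64, head)


@pytest.fixture(scope="session")
def grid20(head):
    return fw.build_source_grid(head, 20.0)


@pytest.fixture(scope="session")
def grid12(head):
    return fw.build_source_grid(head, 12.0)


@pytest.fixture(scope="session")
def lead32(head, montage32, grid20):
    return fw.compute_leadfield(head, montage32, grid20, n_terms=80)


@pytest.fixture(scope="session")
def lead32_norm(lead32):
    return fw.normalize_leadfield(lead32)


@pytest.fixture(scope="session")
def lead48(head, grid12):
    montage = fw.make_standard_montage(48, head)
    return montage, fw.compute_leadfield(head, montage, grid12, n_terms=80)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
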