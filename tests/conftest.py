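"""Shared fixtures.

Expensive session-scoped objects (the default 3-mm grid/atlas and one fully
simulated + decomposed default-SNR subject) are built once and shared between
the unit suite and the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from icanet.ica import ICDecomposition, decompose_subject
from icanet.networks import default_group_effects
from icanet.preprocess import preprocess_subject
from icanet.synthdata import CohortConfig, make_network_atlas, simulate_subject
from icanet.volume import Grid, Volume4D, brain_mask, default_grid

settings.register_profile("ci", max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid3() -> Grid:
    return default_grid()


@pytest.fixture(scope="session")
def mask3(grid3):
    return brain_mask(grid3)


@pytest.fixture(scope="session")
def atlas3(grid3):
    return make_network_atlas(grid=grid3)


@dataclass
class DefaultSubject:
    volume: Volume4D
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    truth: object
    preprocessed: Volume4D
    decomp: ICDecomposition


@pytest.fixture(scope="session")
def default_subject(atlas3, mask3) -> DefaultSubject:
    """One default-SNR subject, preprocessed and decomposed at 30 components."""
    cfg = CohortConfig()
    vol, wm, csf, truth = simulate_subject(
        atlas3, default_group_effects(), "HC", cfg, seed=12345, subject_id="HCfix"
    )
    pre = preprocess_subject(vol, wm, csf)
    decomp = decompose_subject(pre, mask3, n_components=30, seed=12446)
    return DefaultSubject(vol, wm, csf, truth, pre, decomp)


@pytest.fixture()
def small_grid() -> Grid:
    """A cheap grid for construction-based unit tests."""
    return Grid(origin=(-24.0, -24.0, -24.0), voxel_mm=3.0, shape=(17, 17, 17))
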