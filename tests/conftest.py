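"""Shared fixtures: one synthetic study reused across the suite.

The expensive end-to-end artefacts (trajectory study, labelled frames,
curated dataset, fitted network) are session-scoped so unit tests and the
acceptance tests share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from modetime.bnn import BNNConfig, DissociationTimeBNN
from modetime.curation import assemble
from modetime.dynamics import Trajectory, default_study_potential, generate_study
from modetime.fixtures import build_diatomic, build_synthetic_system
from modetime.harmonic import normal_mode_analysis
from modetime.labels import label_study
from modetime.wigner import VibrationalStateSpec


def make_cc_trajectory(cc: list[float], dt: float = 1.0) -> Trajectory:
    """A minimal trajectory with a prescribed C-C distance series."""
    cc_arr = np.asarray(cc, dtype=float)
    n = cc_arr.size
    return Trajectory(
        times=np.arange(n) * dt,
        r_frames=np.zeros((n, 2)),
        v_frames=np.zeros((n, 2)),
        cc_distance=cc_arr,
        dt=dt,
        dissociated=bool(np.any(cc_arr > 2.4)),
    )


@pytest.fixture(scope="session")
def system8():
    return build_synthetic_system(8, seed=0)


@pytest.fixture(scope="session")
def basis(system8):
    return normal_mode_analysis(system8)


@pytest.fixture(scope="session")
def diatomic_basis():
    return normal_mode_analysis(build_diatomic(), linear=True)


@pytest.fixture(scope="session")
def potential(basis):
    return default_study_potential(basis)


@pytest.fixture(scope="session")
def ground_study(basis, potential):
    """One 200-trajectory ground-state study (the default study conditions)."""
    spec = VibrationalStateSpec(quanta={}, ensemble_size=200)
    return generate_study(basis, potential, [spec], seed=1)["ground"]


@pytest.fixture(scope="session")
def frames_posvel(ground_study):
    return label_study(ground_study, stride=5, with_velocities=True)


@pytest.fixture(scope="session")
def dataset(frames_posvel):
    return assemble(frames_posvel, seed=1)


@pytest.fixture(scope="session")
def fitted(dataset):
    """A fitted position+velocity model on the session study."""
    return DissociationTimeBNN(dataset, BNNConfig(seed=1)).fit()
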