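import numpy as np
import pytest

from enzstab import StudySpec, TrajectorySpec, generate_study, generate_trajectory
from enzstab.datasets import load_published_inputs


@pytest.fixture(scope="session")
def published():
    return load_published_inputs()


@pytest.fixture(scope="session")
def printed_stability(published):
    """Published per-temperature (T, kd) pairs and the fitted E_d."""
    s = published["stability"]
    return list(zip(s["temperatures_K"], s["kd_per_month"])), s["Ed_J_mol"]


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study: 3 batches x 5 vials, published truth."""
    spec = StudySpec(vials_per_batch=5, seed=42)
    return spec, generate_study(spec)


@pytest.fixture()
def gaussian_traj():
    spec = TrajectorySpec(n_residues=30, n_frames=400,
                          amplitude_profile=(0.4,) * 30, seed=7)
    return spec, generate_trajectory(spec)
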