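"""Shared fixtures.

The default phantom and its pipeline run are session-scoped: several test
modules check different aspects of the same run, and centerline extraction
is the expensive step.
"""

import numpy as np
import pytest
import trimesh

from tavimetrics.measure import run_pipeline
from tavimetrics.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """(mesh, landmarks, truth) of the default TAVI-like phantom."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_report(default_phantom):
    """The pipeline report for the default phantom (one full run)."""
    mesh, landmarks, _ = default_phantom
    return run_pipeline(mesh, landmarks)


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Closed cylinder, radius 10 mm, length 80 mm, axis +z."""
    return trimesh.creation.cylinder(radius=10.0, height=80.0, sections=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


def random_rigid(rng):
    """A uniformly random rotation matrix and a translation in ±50 mm."""
    from scipy.spatial.transform import Rotation
    seed = int(rng.integers(0, 2**31 - 1))
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.uniform(-50.0, 50.0, size=3)
    return R, t


def apply_rigid(mesh: trimesh.Trimesh, R: np.ndarray, t: np.ndarray):
    out = mesh.copy()
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = t
    out.apply_transform(T)
    return out
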