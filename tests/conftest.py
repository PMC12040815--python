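import numpy as np
import pytest

import cbctbrachy as cb
from cbctbrachy.synthetic import PhantomGeometry


@pytest.fixture(scope="session")
def default_truth():
    return cb.ScenarioTruth(seed=3)


@pytest.fixture(scope="session")
def phantom(default_truth):
    """One full-size phantom shared across the session (seed 3)."""
    vol, masks = cb.generate_phantom_volume(default_truth)
    return vol, masks


@pytest.fixture(scope="session")
def phantom_geometry(phantom):
    vol, _ = phantom
    return PhantomGeometry.proportional(vol.extent_mm())


@pytest.fixture(scope="session")
def world_tracks(default_truth, phantom_geometry):
    """Implant tracks positioned in the phantom's world frame."""
    return [
        cb.ApplicatorTrack(t.points + phantom_geometry.implant_origin, t.kind, t.name)
        for t in cb.generate_implant(default_truth.implant)
    ]


def random_rigid(rng, max_angle_rad, max_translation_mm):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_rad, max_angle_rad)
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return cb.RigidTransform.from_axis_angle(axis, angle, t)
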