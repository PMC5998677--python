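"""Shared fixtures: phantoms are generated at session scope and reused."""

from __future__ import annotations

import numpy as np
import pytest

from avp.geometry import (
    Angulation,
    RigidTransform,
    VoxelSpec,
    rotation_from_angulation,
)
from avp.phantom import make_phantom, perturb_subject


@pytest.fixture(scope="session")
def quick_phantom():
    """One 96^3 @ 2 mm template head plus its tissue maps."""
    return make_phantom((96, 96, 96), 2.0, seed=7)


@pytest.fixture(scope="session")
def template(quick_phantom):
    return quick_phantom[0]


@pytest.fixture(scope="session")
def pve_maps(quick_phantom):
    return quick_phantom[1]


@pytest.fixture(scope="session")
def dlpfc_spec(template):
    """The study's target prescription: 15 x 20 x 15 mm, rotated pose."""
    return VoxelSpec(
        study="demo",
        description="l_dlpfc",
        dims=(15.0, 20.0, 15.0),
        center=(32.0, 25.0, 22.5),
        angulation=Angulation(7.0, 20.0, 15.0),
        orientation=template.orientation,
    )


@pytest.fixture(scope="session")
def extreme_pose_subject(template):
    """A subject image at a realistically extreme head pose, with ground truth."""
    gt = RigidTransform.from_parts(
        rotation_from_angulation((9.9, -14.2, 10.3)), (-9.0, -5.0, 12.5)
    )
    subject, _ = perturb_subject(template, gt, seed=8)
    return subject, gt
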