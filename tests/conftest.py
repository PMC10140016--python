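"""Shared fixtures: small seeded phantoms and field sets.

Everything is generated at test time; the tiny 12^3 phantom keeps oracle
tests (grid searches, Monte-Carlo checks) fast, while the 24^3 demo phantom
with the 8-channel fractionated-dipole array exercises realistic problem
sizes.
"""

import numpy as np
import pytest

from ptxbench.arrays import ArraySpec, make_array_spec
from ptxbench.fields import ChannelFieldSet, simulate_fields
from ptxbench.phantom import PhantomConfig, build_phantom
from ptxbench.sar import average_10g, build_q_matrices


def tiny_config() -> PhantomConfig:
    return PhantomConfig(
        voxel_size=8.0,
        fov=(96.0, 96.0, 96.0),
        torso_semiaxes=(40.0, 44.0),
        skin_thickness=4.0,
        fat_thickness=6.0,
        heart_center=(4.0, -4.0, 0.0),
        heart_semiaxes=(14.0, 16.0, 14.0),
        lung_centers=((-4.0, -24.0, 0.0), (-4.0, 24.0, 0.0)),
        lung_semiaxes=(14.0, 12.0, 30.0),
    )


def custom_array(centers, frequency=297.2e6, length=120.0) -> ArraySpec:
    centers = np.asarray(centers, dtype=float)
    return ArraySpec(
        building_block="custom",
        setup="test",
        n_channels=len(centers),
        element_centers=centers,
        element_orientation=np.tile([0.0, 0.0, 1.0], (len(centers), 1)),
        element_length=length,
        frequency=frequency,
    )


@pytest.fixture(scope="session")
def tiny_phantom():
    return build_phantom(tiny_config())


@pytest.fixture(scope="session")
def fieldset3(tiny_phantom) -> ChannelFieldSet:
    """3-channel set on the tiny phantom (ROI has < 30 voxels)."""
    spec = custom_array([(60.0, -25.0, 0.0), (60.0, 25.0, 0.0),
                         (-60.0, 0.0, 0.0)])
    return simulate_fields(tiny_phantom, spec, seed=7, jitter_mm=0.0)


@pytest.fixture(scope="session")
def fieldset4(tiny_phantom) -> ChannelFieldSet:
    spec = custom_array([(60.0, -25.0, 10.0), (60.0, 25.0, -10.0),
                         (-60.0, -25.0, 0.0), (-60.0, 25.0, 0.0)])
    return simulate_fields(tiny_phantom, spec, seed=11, jitter_mm=0.0)


@pytest.fixture(scope="session")
def q10_tiny4(fieldset4, tiny_phantom):
    return average_10g(build_q_matrices(fieldset4), tiny_phantom,
                       frequency=fieldset4.frequency)


@pytest.fixture(scope="session")
def demo_phantom():
    return build_phantom(PhantomConfig.demo())


@pytest.fixture(scope="session")
def demo_fieldset8(demo_phantom) -> ChannelFieldSet:
    """8-channel fractionated-dipole baseline array on the 24^3 demo phantom."""
    spec = make_array_spec("FD", "BL-7T", demo_phantom, scale=0.6)
    return simulate_fields(demo_phantom, spec, seed=1)


@pytest.fixture(scope="session")
def q10_demo(demo_fieldset8, demo_phantom):
    return average_10g(build_q_matrices(demo_fieldset8), demo_phantom,
                       frequency=demo_fieldset8.frequency)
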