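"""Cardiac transmit-array layouts for the three dipole building blocks.

Three element types are supported: self-grounded bow-tie (SGBT), bow-tie (BT)
and fractionated dipole (FD), each in three configurations: the 7.0 T baseline
(BL-7T), the 14.0 T same-channel-count setup (SCC-14T, identical element
centers, smaller elements) and the 14.0 T double-channel-count setup
(DCC-14T).  Elements are arranged in anterior and posterior planar matrices
conformal to the torso surface, dipole currents along z (head-feet).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import F_7T_HZ, F_14T_HZ
from .errors import ConfigurationError
from .phantom import Phantom

__all__ = ["ArraySpec", "make_array_spec", "CHANNEL_COUNTS"]

BUILDING_BLOCKS = ("SGBT", "BT", "FD")
SETUPS = ("BL-7T", "SCC-14T", "DCC-14T")

#: Channel counts per (building block, setup) pair.
CHANNEL_COUNTS = {
    ("SGBT", "BL-7T"): 32, ("SGBT", "SCC-14T"): 32, ("SGBT", "DCC-14T"): 64,
    ("BT", "BL-7T"): 16, ("BT", "SCC-14T"): 16, ("BT", "DCC-14T"): 32,
    ("FD", "BL-7T"): 8, ("FD", "SCC-14T"): 8, ("FD", "DCC-14T"): 16,
}

# Per-face matrix patterns (element counts per row along y, rows stacked in z)
# and nearest-neighbor pitches in mm.  BL and SCC share the same centers; DCC
# doubles the per-face element count.
_LAYOUTS = {
    ("SGBT", "BL-7T"): dict(rows=(5, 6, 5), pitch_y=48.0, pitch_z=90.0),
    ("SGBT", "SCC-14T"): dict(rows=(5, 6, 5), pitch_y=48.0, pitch_z=90.0),
    ("SGBT", "DCC-14T"): dict(rows=(7, 9, 9, 7), pitch_y=24.0, pitch_z=45.0),
    ("BT", "BL-7T"): dict(rows=(4, 4), pitch_y=86.0, pitch_z=166.0),
    ("BT", "SCC-14T"): dict(rows=(4, 4), pitch_y=86.0, pitch_z=166.0),
    ("BT", "DCC-14T"): dict(rows=(5, 6, 5), pitch_y=48.0, pitch_z=88.0),
    ("FD", "BL-7T"): dict(rows=(4,), pitch_y=70.0, pitch_z=0.0),
    ("FD", "SCC-14T"): dict(rows=(4,), pitch_y=70.0, pitch_z=0.0),
    ("FD", "DCC-14T"): dict(rows=(8,), pitch_y=30.0, pitch_z=0.0),
}

# Dipole (current-carrying) length along z, mm; 14 T elements are halved.
_ELEMENT_LENGTH = {
    ("SGBT", "BL-7T"): 89.3, ("SGBT", "SCC-14T"): 44.7, ("SGBT", "DCC-14T"): 44.7,
    ("BT", "BL-7T"): 156.0, ("BT", "SCC-14T"): 78.0, ("BT", "DCC-14T"): 78.0,
    ("FD", "BL-7T"): 304.0, ("FD", "SCC-14T"): 152.0, ("FD", "DCC-14T"): 152.0,
}


@dataclass(frozen=True)
class ArraySpec:
    """Geometric specification of one transmit/receive array configuration."""

    building_block: str
    setup: str
    n_channels: int
    element_centers: np.ndarray  # (n, 3) mm
    element_orientation: np.ndarray  # (n, 3) unit vectors
    element_length: float  # mm
    frequency: float  # Hz

    def __post_init__(self):
        if self.element_centers.shape != (self.n_channels, 3):
            raise ConfigurationError("element_centers shape mismatch")
        expected = CHANNEL_COUNTS.get((self.building_block, self.setup))
        if expected is not None and expected != self.n_channels:
            raise ConfigurationError(
                f"{self.building_block}/{self.setup} must have {expected} channels"
            )


def make_array_spec(
    building_block: str,
    setup: str,
    phantom: Phantom,
    standoff_mm: float = 15.0,
    scale: float = 1.0,
) -> ArraySpec:
    """Lay out an array on the anterior and posterior torso faces.

    ``scale`` shrinks the matrix pitches uniformly (useful on the small demo
    phantom); element centers for BL and SCC setups are identical by
    construction.
    """
    key = (building_block, setup)
    if key not in _LAYOUTS:
        raise ConfigurationError(
            f"unknown (building_block, setup) pair {key}; "
            f"valid: {sorted(_LAYOUTS)}"
        )
    if phantom.config is None:
        raise ConfigurationError("phantom carries no geometry config")
    lay = _LAYOUTS[key]
    a, b = phantom.config.torso_semiaxes
    frequency = F_7T_HZ if setup == "BL-7T" else F_14T_HZ

    # SCC reuses the BL pitches, so BL/SCC centers coincide exactly.
    pitch_y = lay["pitch_y"] * scale
    pitch_z = lay["pitch_z"] * scale
    rows = lay["rows"]
    nrows = len(rows)

    centers = []
    for sign in (+1.0, -1.0):  # anterior, posterior
        for irow, count in enumerate(rows):
            z = (irow - (nrows - 1) / 2.0) * pitch_z
            for j in range(count):
                y = (j - (count - 1) / 2.0) * pitch_y
                # conformal surface height of the outer torso ellipse
                h = a * np.sqrt(max(0.0, 1.0 - (y / b) ** 2))
                x = sign * (h + standoff_mm)
                centers.append((x, y, z))
    centers = np.asarray(centers)
    orientation = np.tile([0.0, 0.0, 1.0], (len(centers), 1))

    return ArraySpec(
        building_block=building_block,
        setup=setup,
        n_channels=len(centers),
        element_centers=centers,
        element_orientation=orientation,
        element_length=_ELEMENT_LENGTH[key],
        frequency=frequency,
    )
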