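"""SENSE geometry-factor maps for 1-D Cartesian acceleration.

On an axial plane through the heart, per-channel receive sensitivities (from
the B1- maps) and a channel noise covariance Psi give the SENSE noise
amplification at reduction factor R:

    g_j = sqrt( [(S^H Psi^-1 S)^-1]_jj * [S^H Psi^-1 S]_jj )

where S collects the sensitivities of the R voxels that alias onto voxel j
(cyclic FOV wrap, air-only alias positions dropped).  g >= 1 wherever the
unfolding problem is well posed; voxels with a singular normal matrix are
flagged unresolvable and excluded from the summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fields import ChannelFieldSet

__all__ = ["SensitivitySet", "GFactorMap", "extract_sensitivities", "sense_g",
           "g_report"]

PE_AXES = {"x": 0, "y": 1}  # A-P and L-R on the axial plane


@dataclass
class SensitivitySet:
    """Per-channel complex sensitivities on one axial plane."""

    maps: np.ndarray  # (nch, nx, ny) complex
    psi: np.ndarray  # (nch, nch) Hermitian positive-definite
    mask: np.ndarray  # (nx, ny) tissue mask
    roi: np.ndarray  # (nx, ny) cardiac ROI slice
    fov_mm: tuple[float, float]
    voxel_size: float

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=complex)
        if not np.allclose(psi, psi.conj().T, atol=1e-9 * max(1.0, np.abs(psi).max())):
            raise ConfigurationError("Psi must be Hermitian")
        if np.linalg.eigvalsh(psi)[0] <= 0:
            raise ConfigurationError("Psi must be positive definite")
        self.psi = psi

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]

    @property
    def matrix(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass
class GFactorMap:
    """SENSE g-factor map at one (R, phase-encoding axis) combination."""

    g: np.ndarray  # (nx, ny), NaN outside mask / at unresolvable voxels
    r: int
    pe_axis: str
    g_mean: float  # over the cardiac ROI slice
    g_max: float
    n_unresolvable: int


def extract_sensitivities(
    fieldset: ChannelFieldSet,
    plane_z: int | None = None,
    psi: np.ndarray | str = "identity",
) -> SensitivitySet:
    """Receive sensitivities on the axial plane through the heart center.

    ``psi`` may be "identity", or any Hermitian positive-definite channel
    noise covariance (e.g. a sample-loss power correlation matrix).
    """
    if plane_z is None:
        plane_z = fieldset.phantom.heart_center_index()[2]
    nz = fieldset.phantom.shape[2]
    if not 0 <= plane_z < nz:
        raise ConfigurationError(f"plane_z={plane_z} outside grid (nz={nz})")
    maps = fieldset.b1_minus[:, :, :, plane_z].copy()
    mask = fieldset.phantom.body_mask[:, :, plane_z]
    roi = fieldset.phantom.roi_mask[:, :, plane_z]
    maps[:, ~mask] = 0.0
    if isinstance(psi, str):
        if psi != "identity":
            raise ConfigurationError("psi must be 'identity' or a matrix")
        psi_m = np.eye(fieldset.n_channels)
    else:
        psi_m = np.asarray(psi, dtype=complex)
    vs = fieldset.phantom.voxel_size
    nx, ny = mask.shape
    return SensitivitySet(
        maps=maps, psi=psi_m, mask=mask, roi=roi,
        fov_mm=(nx * vs, ny * vs), voxel_size=vs,
    )


def _alias_indices(n: int, r: int, j: int) -> np.ndarray:
    """The r cyclic alias positions of index j at reduction r (spacing n/r)."""
    pos = (j + np.round(np.arange(r) * n / r).astype(int)) % n
    return np.unique(pos)


def sense_g(sens: SensitivitySet, r: int, pe_axis: str = "y") -> GFactorMap:
    """SENSE g-factor map at integer reduction ``r`` along one axis."""
    if pe_axis not in PE_AXES:
        raise ConfigurationError("pe_axis must be 'x' (A-P) or 'y' (L-R)")
    if r < 1 or int(r) != r:
        raise ConfigurationError("r must be a positive integer")
    ax = PE_AXES[pe_axis]
    maps = sens.maps if ax == 1 else np.swapaxes(sens.maps, 1, 2)
    mask = sens.mask if ax == 1 else sens.mask.T
    n_ro, n_pe = mask.shape
    psi_inv = np.linalg.inv(sens.psi)

    g = np.full((n_ro, n_pe), np.nan)
    unresolvable = 0
    for j in range(n_pe):
        alias = _alias_indices(n_pe, r, j)
        for i in range(n_ro):
            if not mask[i, j]:
                continue
            cols = [a for a in alias if mask[i, a]]
            s = maps[:, i, cols]  # (nch, n_alias)
            m = s.conj().T @ psi_inv @ s
            jj = cols.index(j)
            try:
                minv = np.linalg.inv(m)
            except np.linalg.LinAlgError:
                unresolvable += 1
                continue
            val = np.real(minv[jj, jj] * m[jj, jj])
            if val < 0 or not np.isfinite(val) or np.linalg.cond(m) > 1e12:
                unresolvable += 1
                continue
            g[i, j] = np.sqrt(val)
    if ax == 0:
        g = g.T
    roi_vals = g[sens.roi]
    roi_vals = roi_vals[np.isfinite(roi_vals)]
    if len(roi_vals) == 0:
        g_mean = g_max = float("nan")
    else:
        g_mean, g_max = float(roi_vals.mean()), float(roi_vals.max())
    return GFactorMap(
        g=g, r=int(r), pe_axis=pe_axis, g_mean=g_mean, g_max=g_max,
        n_unresolvable=unresolvable,
    )


def g_report(
    fieldset: ChannelFieldSet,
    r_list=(2, 3, 4),
    axes=("y", "x"),
    plane_z: int | None = None,
    psi="identity",
    label: str = "",
) -> pd.DataFrame:
    """Mean/max cardiac-ROI g-factors for each (R, phase-encode axis) cell."""
    sens = extract_sensitivities(fieldset, plane_z=plane_z, psi=psi)
    rows = []
    for axis in axes:
        for r in r_list:
            gm = sense_g(sens, r, axis)
            rows.append({
                "setup": label,
                "pe_axis": axis,
                "r": r,
                "g_mean": gm.g_mean,
                "g_max": gm.g_max,
                "n_unresolvable": gm.n_unresolvable,
            })
    return pd.DataFrame(rows)
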