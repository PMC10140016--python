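"""Surrogate per-channel RF field synthesis and field-container I/O.

Each array element is modeled as a finite straight dipole: its magnetic field
follows the Biot-Savart closed form of a current segment and its electric
field the quasi-static vector potential (E = -i w A, parallel to the dipole
axis).  Propagation into tissue is captured by a scalar attenuation
``exp(-depth/delta)`` with the frequency-dependent skin depth
``delta = sqrt(2 / (w mu0 sigma))`` and a propagation phase
``exp(-i 2 pi depth / lambda_tissue)``, where ``depth`` is the straight-line
path length inside the torso from the element to the voxel.  At 600 MHz both
the decay and the phase advance per mm are stronger than at 297.2 MHz, which
is the qualitative behavior the surrogate must reproduce.

Conventions
-----------
* B1+ = (Bx + i By) / 2 and B1- = conj(Bx - i By) / 2 (the two circularly
  polarized components of the transverse RF field; "+" is the component
  co-rotating with spin precession).
* Field maps are stored in uT (B1) and V/m (E) per unit excitation weight,
  normalized so that the power dissipated in the sample by one channel at
  unit weight is ``sample_loss_fraction * per_channel_power`` (default
  0.75 * 1 W, i.e. sample losses never exceed the accepted power).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

from .constants import C0, MU0
from .errors import FieldFormatError, FieldModelError, SarUnavailableError
from .arrays import ArraySpec
from .phantom import MUSCLE, Phantom, load_tissue_table

__all__ = [
    "ChannelFieldSet",
    "element_fields",
    "simulate_fields",
    "io_fieldset",
    "read_fieldset",
    "write_fieldset",
    "export_nifti",
    "skin_depth",
    "tissue_wavelength",
]


def skin_depth(frequency: float, sigma: float) -> float:
    """Conductive skin depth sqrt(2 / (w mu0 sigma)), m."""
    w = 2.0 * np.pi * frequency
    return float(np.sqrt(2.0 / (w * MU0 * sigma)))


def tissue_wavelength(frequency: float, eps_r: float) -> float:
    """RF wavelength in a dielectric, m."""
    return C0 / (frequency * np.sqrt(eps_r))


@dataclass
class ChannelFieldSet:
    """Per-channel complex B1+/B1-/E maps on a phantom grid.

    ``e_field`` may be None (e.g. a container written without E data); any
    SAR computation then raises ``SarUnavailableError`` instead of silently
    using zeros.
    """

    b1_plus: np.ndarray  # (nch, nx, ny, nz) complex, uT per unit weight
    b1_minus: np.ndarray  # (nch, nx, ny, nz) complex, uT per unit weight
    e_field: np.ndarray | None  # (nch, 3, nx, ny, nz) complex, V/m per unit weight
    phantom: Phantom
    frequency: float  # Hz
    per_channel_power: float = 1.0  # W at unit excitation weight

    def __post_init__(self):
        shp = self.phantom.shape
        if self.b1_plus.shape[1:] != shp or self.b1_minus.shape[1:] != shp:
            raise FieldFormatError("B1 maps do not match the phantom grid")
        if self.b1_plus.shape[0] != self.b1_minus.shape[0]:
            raise FieldFormatError("channel count mismatch between B1+ and B1-")
        if self.e_field is not None and self.e_field.shape != (
            self.n_channels, 3, *shp
        ):
            raise FieldFormatError("E-field shape mismatch")
        if self.per_channel_power <= 0:
            raise FieldFormatError("per_channel_power must be positive")

    @property
    def n_channels(self) -> int:
        return self.b1_plus.shape[0]

    @property
    def has_sar_inputs(self) -> bool:
        return self.e_field is not None

    def require_e_field(self) -> np.ndarray:
        if self.e_field is None:
            raise SarUnavailableError(
                "this field set has no E-field data; SAR quantities "
                "(power correlation sample term, Q matrices) are unavailable"
            )
        return self.e_field

    def superpose(self, weights: np.ndarray) -> np.ndarray:
        """Complex B1+ superposition sum_ch w_ch * B1+_ch, uT."""
        w = np.asarray(weights, dtype=complex)
        if w.shape != (self.n_channels,):
            raise FieldModelError(
                f"expected {self.n_channels} weights, got shape {w.shape}"
            )
        return np.tensordot(w, self.b1_plus, axes=(0, 0))


def _segment_geometry(points_m, center_m, direction, half_len_m):
    a = points_m - center_m
    u = a @ direction
    rho_vec = a - np.outer(u, direction)
    rho = np.linalg.norm(rho_vec, axis=1)
    rho = np.maximum(rho, 1e-6)
    return u, rho_vec, rho


def _tissue_path_depth(points_m, center_m, semiaxes_m):
    """Straight-line path length inside the outer torso ellipse, m.

    The torso is an elliptical cylinder along z, so the intersection reduces
    to a 2-D quadratic in the (x, y) plane.
    """
    a, b = semiaxes_m
    p = center_m[:2]
    d = points_m[:, :2] - p
    qa = (d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2
    qb = 2.0 * (p[0] * d[:, 0] / a**2 + p[1] * d[:, 1] / b**2)
    qc = (p[0] / a) ** 2 + (p[1] / b) ** 2 - 1.0
    disc = qb**2 - 4.0 * qa * qc
    dist = np.linalg.norm(points_m - center_m, axis=1)
    depth = np.zeros(len(points_m))
    hit = (disc > 0) & (qa > 0)
    sq = np.sqrt(np.maximum(disc[hit], 0.0))
    t1 = (-qb[hit] - sq) / (2.0 * qa[hit])
    t2 = (-qb[hit] + sq) / (2.0 * qa[hit])
    t_in = np.clip(t1, 0.0, 1.0)
    t_out = np.clip(t2, 0.0, 1.0)
    depth[hit] = np.maximum(t_out - t_in, 0.0) * dist[hit]
    return depth


def element_fields(
    phantom: Phantom,
    center_mm,
    orientation,
    length_mm: float,
    frequency: float,
    normalize: bool = True,
    per_channel_power: float = 1.0,
    sample_loss_fraction: float = 0.75,
):
    """B1+/B1-/E maps of a single finite-dipole element at unit drive.

    Returns ``(b1_plus, b1_minus, e_field)`` with shapes ``(nx,ny,nz)``,
    ``(nx,ny,nz)`` and ``(3,nx,ny,nz)``.  With ``normalize=True`` the fields
    are rescaled so the sample-dissipated power equals
    ``sample_loss_fraction * per_channel_power``.
    """
    center = np.asarray(center_mm, dtype=float) * 1e-3
    direction = np.asarray(orientation, dtype=float)
    direction = direction / np.linalg.norm(direction)
    half_len = 0.5 * length_mm * 1e-3

    if phantom.config is None:
        raise FieldModelError("phantom carries no geometry config")
    a_mm, b_mm = phantom.config.torso_semiaxes
    if ((center[0] / (a_mm * 1e-3)) ** 2 + (center[1] / (b_mm * 1e-3)) ** 2) < 1.0:
        raise FieldModelError("element center lies inside the torso tissue")

    xs, ys, zs = phantom.grid_mm()
    pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]) * 1e-3

    u, rho_vec, rho = _segment_geometry(pts, center, direction, half_len)
    s1 = (half_len - u) / np.hypot(rho, half_len - u)
    s2 = (half_len + u) / np.hypot(rho, half_len + u)
    b_mag = MU0 / (4.0 * np.pi * rho) * (s1 + s2)  # T at I = 1 A
    phi_hat = np.cross(np.broadcast_to(direction, rho_vec.shape), rho_vec)
    phi_hat /= rho[:, None]
    b_vec = b_mag[:, None] * phi_hat

    w = 2.0 * np.pi * frequency
    integral = np.arcsinh((half_len - u) / rho) + np.arcsinh((half_len + u) / rho)
    e_vec = (-1j * w * MU0 / (4.0 * np.pi)) * integral[:, None] * direction

    # scalar depth attenuation with muscle as the effective propagation medium
    muscle = load_tissue_table(frequency)[MUSCLE]
    delta = skin_depth(frequency, muscle.sigma)
    lam = tissue_wavelength(frequency, muscle.eps_r)
    semiaxes_m = (a_mm * 1e-3, b_mm * 1e-3)
    depth = _tissue_path_depth(pts, center, semiaxes_m)
    atten = np.exp(-depth / delta - 2j * np.pi * depth / lam)

    b_vec = b_vec * atten[:, None]
    e_vec = e_vec * atten[:, None]

    shape = phantom.shape
    bx = b_vec[:, 0].reshape(shape)
    by = b_vec[:, 1].reshape(shape)
    b1p = 0.5 * (bx + 1j * by) * 1e6  # uT
    b1m = 0.5 * np.conj(bx - 1j * by) * 1e6
    e_field = np.moveaxis(e_vec.reshape(*shape, 3), -1, 0)

    if normalize:
        sigma, _, _ = phantom.property_maps(frequency)
        p_sample = 0.5 * np.sum(
            sigma * np.sum(np.abs(e_field) ** 2, axis=0)
        ) * phantom.voxel_volume_m3
        if p_sample <= 0:
            raise FieldModelError("element deposits no power in the sample")
        s = np.sqrt(sample_loss_fraction * per_channel_power / p_sample)
        b1p, b1m, e_field = b1p * s, b1m * s, e_field * s

    return b1p, b1m, e_field


def simulate_fields(
    phantom: Phantom,
    array_spec: ArraySpec,
    seed: int = 0,
    jitter_mm: float = 1.5,
    amp_ripple: float = 0.03,
    sample_loss_fraction: float = 0.75,
    per_channel_power: float = 1.0,
) -> ChannelFieldSet:
    """Synthesize the per-channel field set for an array on a phantom.

    Seeded perturbations (element position jitter, amplitude ripple and small
    phase offsets) keep the channels non-degenerate, as they would be after a
    real construction and co-simulation step.
    """
    rng = np.random.default_rng(seed)
    nch = array_spec.n_channels
    shape = phantom.shape
    b1p = np.empty((nch, *shape), dtype=complex)
    b1m = np.empty((nch, *shape), dtype=complex)
    e = np.empty((nch, 3, *shape), dtype=complex)
    for ch in range(nch):
        center = array_spec.element_centers[ch] + rng.normal(0.0, jitter_mm, 3)
        gain = (1.0 + amp_ripple * rng.standard_normal()) * np.exp(
            1j * rng.normal(0.0, 0.05)
        )
        p, m, ef = element_fields(
            phantom,
            center,
            array_spec.element_orientation[ch],
            array_spec.element_length,
            array_spec.frequency,
            normalize=True,
            per_channel_power=per_channel_power,
            sample_loss_fraction=sample_loss_fraction,
        )
        b1p[ch] = p * gain
        b1m[ch] = m * np.conj(gain)
        e[ch] = ef * gain
    return ChannelFieldSet(
        b1_plus=b1p,
        b1_minus=b1m,
        e_field=e,
        phantom=phantom,
        frequency=array_spec.frequency,
        per_channel_power=per_channel_power,
    )


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_fieldset(path, fieldset: ChannelFieldSet) -> None:
    """Write a field set to an HDF5 container (round-trip exact)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("b1_plus", data=fieldset.b1_plus)
        f.create_dataset("b1_minus", data=fieldset.b1_minus)
        if fieldset.e_field is not None:
            f.create_dataset("e_field", data=fieldset.e_field)
        g = f.create_group("phantom")
        g.create_dataset("tissue_label", data=fieldset.phantom.tissue_label)
        g.create_dataset("roi_mask", data=fieldset.phantom.roi_mask)
        f.attrs["frequency_hz"] = fieldset.frequency
        f.attrs["voxel_size_mm"] = fieldset.phantom.voxel_size
        f.attrs["per_channel_power_w"] = fieldset.per_channel_power


def read_fieldset(path) -> ChannelFieldSet:
    """Read a field set written by :func:`write_fieldset`.

    Channels keep their stored order.  A container without an ``e_field``
    group yields ``e_field = None`` (SAR explicitly unavailable).
    """
    with h5py.File(path, "r") as f:
        for key in ("b1_plus", "b1_minus", "phantom/tissue_label",
                    "phantom/roi_mask"):
            if key not in f:
                raise FieldFormatError(f"container is missing dataset {key!r}")
        b1p = f["b1_plus"][...]
        b1m = f["b1_minus"][...]
        e = f["e_field"][...] if "e_field" in f else None
        phantom = Phantom(
            voxel_size=float(f.attrs["voxel_size_mm"]),
            tissue_label=f["phantom/tissue_label"][...],
            roi_mask=f["phantom/roi_mask"][...].astype(bool),
            config=None,
        )
        if b1p.shape != b1m.shape:
            raise FieldFormatError("B1+/B1- shape mismatch between channels")
        return ChannelFieldSet(
            b1_plus=b1p,
            b1_minus=b1m,
            e_field=e,
            phantom=phantom,
            frequency=float(f.attrs["frequency_hz"]),
            per_channel_power=float(f.attrs["per_channel_power_w"]),
        )


def io_fieldset(path, mode: str, fieldset: ChannelFieldSet | None = None):
    """Dispatching wrapper around :func:`read_fieldset`/:func:`write_fieldset`."""
    if mode == "read":
        return read_fieldset(path)
    if mode == "write":
        if fieldset is None:
            raise FieldFormatError("mode='write' requires a fieldset")
        write_fieldset(path, fieldset)
        return fieldset
    raise FieldFormatError(f"mode must be 'read' or 'write', got {mode!r}")


def export_nifti(map3d: np.ndarray, phantom: Phantom, path) -> None:
    """Export one 3-D map as NIfTI with the phantom's voxel size in the affine."""
    import nibabel as nib

    affine = np.diag([phantom.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(map3d, dtype=np.float64), affine)
    nib.save(img, str(path))


def strip_e_field(fieldset: ChannelFieldSet) -> ChannelFieldSet:
    """Copy of a field set without E-field data (SAR flagged unavailable)."""
    return replace(fieldset, e_field=None)
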