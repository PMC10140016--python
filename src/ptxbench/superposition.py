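"""Optimal per-voxel transmit-efficiency (TXE) and intrinsic-SNR superposition.

For each voxel the best achievable ratio of signal (B1+ for transmission,
B1- for reception) to dissipated RF power over all channel combinations

    max_w |b(r)^H w| / sqrt(w^H Phi w)  =  sqrt(b(r)^H Phi^{-1} b(r))

is the largest generalized eigenvalue of the rank-one signal form against the
power correlation matrix Phi.  ``intrinsic`` mode accounts for sample losses
only; ``realistic`` mode adds coil and coupling losses.  The ratio of the two
maps (realistic / intrinsic, in %) is the performance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import ConfigurationError, SarUnavailableError
from .fields import ChannelFieldSet

__all__ = [
    "PowerCorrelationMatrix",
    "SuperpositionMap",
    "power_correlation",
    "optimal_superposition",
    "performance_ratio",
    "CoilLossModel",
    "CouplingLossModel",
    "roi_statistics",
]


@dataclass(frozen=True)
class CoilLossModel:
    """Per-channel conductor/component loss as a fraction of accepted power."""

    fraction: float = 0.15

    def matrix(self, fieldset: ChannelFieldSet) -> np.ndarray:
        p = self.fraction * fieldset.per_channel_power
        return p * np.eye(fieldset.n_channels)


@dataclass(frozen=True)
class CouplingLossModel:
    """Inter-channel loss with exponential distance decay.

    The Laplacian kernel exp(-d/decay) is positive definite, so the coupling
    term is PSD by construction.  Without element positions a channel-index
    distance is used.
    """

    fraction: float = 0.10
    decay_mm: float = 80.0
    element_centers: np.ndarray | None = None

    def matrix(self, fieldset: ChannelFieldSet) -> np.ndarray:
        n = fieldset.n_channels
        if self.element_centers is not None:
            d = np.linalg.norm(
                self.element_centers[:, None, :] - self.element_centers[None, :, :],
                axis=-1,
            )
            k = np.exp(-d / self.decay_mm)
        else:
            idx = np.arange(n, dtype=float)
            k = np.exp(-np.abs(np.subtract.outer(idx, idx)) / 2.0)
        return self.fraction * fieldset.per_channel_power * k


@dataclass
class PowerCorrelationMatrix:
    """Hermitian loss partition: dissipated power for drive w is w^H Phi w."""

    phi_sample: np.ndarray
    phi_coil: np.ndarray
    phi_coupling: np.ndarray

    def __post_init__(self):
        for name in ("phi_sample", "phi_coil", "phi_coupling"):
            m = np.asarray(getattr(self, name), dtype=complex)
            if not np.allclose(m, m.conj().T, atol=1e-9 * max(1.0, np.abs(m).max())):
                raise ConfigurationError(f"{name} must be Hermitian")
            setattr(self, name, 0.5 * (m + m.conj().T))

    @property
    def n_channels(self) -> int:
        return self.phi_sample.shape[0]

    def total(self, mode: str = "realistic") -> np.ndarray:
        if mode == "intrinsic":
            return self.phi_sample
        if mode == "realistic":
            return self.phi_sample + self.phi_coil + self.phi_coupling
        raise ConfigurationError(f"mode must be intrinsic|realistic, got {mode!r}")


@dataclass
class SuperpositionMap:
    """Optimal-combination efficiency map with ROI bookkeeping."""

    values: np.ndarray  # 3-D, uT/sqrt(kW) (TXE) or a.u./sqrt(kW) (iSNR)
    which: str  # TXE | iSNR
    mode: str  # intrinsic | realistic
    mask: np.ndarray  # where the map is defined


def power_correlation(
    fieldset: ChannelFieldSet,
    coil_loss_model: CoilLossModel | None = None,
    coupling_loss_model: CouplingLossModel | None = None,
) -> PowerCorrelationMatrix:
    """Power correlation matrices from the E-field sample term plus loss models.

    The sample term is the conjugate inner product of the channel E-fields
    weighted by sigma/2 over the voxel volume; it is Hermitian PSD by
    construction.  Coil/coupling terms default to zero when no model is given.
    """
    try:
        e = fieldset.require_e_field()
    except SarUnavailableError as err:
        raise SarUnavailableError(
            "power correlation sample term needs E-fields: " + str(err)
        ) from err
    sigma, _, _ = fieldset.phantom.property_maps(fieldset.frequency)
    nch = fieldset.n_channels
    ef = e.reshape(nch, 3, -1)
    wgt = (0.5 * sigma.reshape(-1) * fieldset.phantom.voxel_volume_m3)
    phi_sample = np.einsum("icv,v,jcv->ij", np.conj(ef), wgt, ef)
    phi_sample = 0.5 * (phi_sample + phi_sample.conj().T)
    zero = np.zeros((nch, nch))
    phi_coil = coil_loss_model.matrix(fieldset) if coil_loss_model else zero.copy()
    phi_coup = (coupling_loss_model.matrix(fieldset)
                if coupling_loss_model else zero.copy())
    return PowerCorrelationMatrix(phi_sample, phi_coil, phi_coup)


def _regularized_cholesky(phi: np.ndarray, cond_limit: float = 1e12):
    """Cholesky factor of Phi, ridge-regularized when badly conditioned."""
    phi = np.asarray(phi, dtype=complex)
    n = phi.shape[0]
    ridge = 0.0
    cond = np.linalg.cond(phi)
    if not np.isfinite(cond) or cond > cond_limit:
        ridge = 1e-9 * np.real(np.trace(phi)) / n
        phi = phi + ridge * np.eye(n)
    try:
        return linalg.cholesky(phi, lower=True), ridge
    except linalg.LinAlgError as err:
        raise ConfigurationError(
            "power correlation matrix is singular; pass loss models or "
            "increase the regularization ridge"
        ) from err


def optimal_superposition(
    fieldset: ChannelFieldSet,
    phi: PowerCorrelationMatrix | np.ndarray,
    which: str = "TXE",
    mode: str = "realistic",
) -> SuperpositionMap:
    """Per-voxel optimal efficiency map sqrt(b^H Phi^{-1} b), scaled to /sqrt(kW).

    ``which`` selects the B1+ (TXE) or B1- (iSNR) channel vectors.  ``phi``
    may be a prebuilt matrix, in which case ``mode`` is only a label.
    """
    if which not in ("TXE", "iSNR"):
        raise ConfigurationError("which must be 'TXE' or 'iSNR'")
    if isinstance(phi, PowerCorrelationMatrix):
        phi_m = phi.total(mode)
    else:
        phi_m = np.asarray(phi, dtype=complex)
    if phi_m.shape != (fieldset.n_channels,) * 2:
        raise ConfigurationError("Phi dimension does not match the field set")
    chol, _ = _regularized_cholesky(phi_m)

    maps = fieldset.b1_plus if which == "TXE" else fieldset.b1_minus
    nch = fieldset.n_channels
    b = maps.reshape(nch, -1)
    y = linalg.solve_triangular(chol, b, lower=True)
    # fields are per unit weight with per_channel_power W accepted each, and
    # Phi is W per |w|^2, so the ratio is (uT)^2/W; x1000 rescales to per kW
    vals = np.sqrt(np.sum(np.abs(y) ** 2, axis=0) * 1e3)
    values = vals.reshape(fieldset.phantom.shape)
    mask = fieldset.phantom.body_mask
    values = np.where(mask, values, 0.0)
    return SuperpositionMap(values=values, which=which, mode=mode, mask=mask)


def performance_ratio(
    map_intrinsic: SuperpositionMap, map_realistic: SuperpositionMap
) -> np.ndarray:
    """100 * realistic / intrinsic (%), NaN where intrinsic is zero."""
    if map_intrinsic.values.shape != map_realistic.values.shape:
        raise ConfigurationError("superposition maps are on different grids")
    out = np.full(map_intrinsic.values.shape, np.nan)
    ok = map_intrinsic.mask & (map_intrinsic.values > 0)
    out[ok] = 100.0 * map_realistic.values[ok] / map_intrinsic.values[ok]
    return out


def roi_statistics(map3d: np.ndarray, roi_mask: np.ndarray) -> dict:
    """mean / SD / min over the ROI (the Fig.-2-style annotation block)."""
    vals = np.asarray(map3d)[roi_mask]
    vals = vals[np.isfinite(vals)]
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std()),
        "min": float(vals.min()),
    }
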