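"""Voxelized torso surrogate phantom with a 3-D heart region of interest.

The phantom is a layered elliptical cylinder (skin / fat / muscle) containing
two ellipsoidal lungs and an ellipsoidal heart.  It stands in for a licensed
anatomical voxel model: coarse, deterministic, and fully parameterized, but
with realistic tissue classes and dielectric properties at the two supported
Larmor frequencies (297.2 MHz and 600 MHz).

Axes convention: x = anterior-posterior, y = left-right, z = head-feet.
Voxel centers sit at ``(i + 0.5) * voxel_size`` relative to the grid corner;
all geometry is expressed in mm in a frame centered on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "TissueProperty",
    "load_tissue_table",
    "PhantomConfig",
    "Phantom",
    "build_phantom",
]


@dataclass(frozen=True)
class TissueProperty:
    """Dielectric and density properties of one tissue class at one frequency."""

    label: int
    name: str
    sigma: float  # electrical conductivity, S/m
    eps_r: float  # relative permittivity
    rho: float  # mass density, kg/m^3
    frequency: float  # Hz

    def __post_init__(self):
        if self.sigma < 0 or self.eps_r < 1 or self.rho <= 0:
            raise ConfigurationError(
                f"invalid tissue property for {self.name!r}: "
                f"sigma={self.sigma}, eps_r={self.eps_r}, rho={self.rho}"
            )


def _tissue_data() -> dict:
    text = resources.files("ptxbench.data").joinpath("tissues.yaml").read_text()
    return yaml.safe_load(text)


def load_tissue_table(frequency: float) -> dict[int, TissueProperty]:
    """Return the tissue table (label -> TissueProperty) for one frequency.

    Only the two supported Larmor frequencies are tabulated; anything else
    raises ``ConfigurationError``.
    """
    data = _tissue_data()["frequencies"]
    for freq_key, tissues in data.items():
        if abs(float(freq_key) - frequency) < 1.0:
            return {
                t["label"]: TissueProperty(
                    label=t["label"],
                    name=name,
                    sigma=t["sigma"],
                    eps_r=t["eps_r"],
                    rho=t["rho"],
                    frequency=float(freq_key),
                )
                for name, t in tissues.items()
            }
    raise ConfigurationError(
        f"no tissue table for frequency {frequency} Hz; "
        f"supported: {sorted(float(k) for k in data)}"
    )


# tissue labels
AIR, SKIN, FAT, MUSCLE, LUNG, HEART = 0, 1, 2, 3, 4, 5


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the layered torso surrogate (all lengths in mm)."""

    voxel_size: float = 4.0
    fov: tuple[float, float, float] = (232.0, 324.0, 192.0)
    torso_semiaxes: tuple[float, float] = (105.0, 150.0)  # (x, y)
    skin_thickness: float = 4.0
    fat_thickness: float = 8.0
    heart_center: tuple[float, float, float] = (15.0, -20.0, 0.0)
    heart_semiaxes: tuple[float, float, float] = (42.0, 48.0, 44.0)
    lung_centers: tuple = ((-10.0, -85.0, 0.0), (-10.0, 85.0, 0.0))
    lung_semiaxes: tuple[float, float, float] = (55.0, 42.0, 80.0)

    @classmethod
    def demo(cls) -> "PhantomConfig":
        """Small 24x24x24 grid (8 mm voxels) used by fast demo scenarios."""
        return cls(
            voxel_size=8.0,
            fov=(192.0, 192.0, 192.0),
            torso_semiaxes=(78.0, 90.0),
            skin_thickness=5.0,
            fat_thickness=9.0,
            heart_center=(10.0, -10.0, 0.0),
            heart_semiaxes=(34.0, 38.0, 36.0),
            lung_centers=((-8.0, -52.0, 0.0), (-8.0, 52.0, 0.0)),
            lung_semiaxes=(36.0, 28.0, 70.0),
        )


@dataclass
class Phantom:
    """Voxelized torso with per-voxel tissue labels and a heart ROI mask."""

    voxel_size: float  # mm, isotropic
    tissue_label: np.ndarray  # uint8, (nx, ny, nz)
    roi_mask: np.ndarray  # bool, (nx, ny, nz)
    config: PhantomConfig | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tissue_label.shape

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size

    @property
    def voxel_volume_m3(self) -> float:
        return (self.voxel_size * 1e-3) ** 3

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinates, mm, centered on the grid."""
        return tuple(
            (np.arange(n) + 0.5) * self.voxel_size - n * self.voxel_size / 2.0
            for n in self.shape
        )

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax = self.axes_mm()
        return np.meshgrid(*ax, indexing="ij")

    @property
    def body_mask(self) -> np.ndarray:
        return self.tissue_label != AIR

    def property_maps(self, frequency: float):
        """Per-voxel (sigma, eps_r, rho) maps at the given frequency.

        Background voxels get sigma = 0, eps_r = 1, rho = 0.
        """
        table = load_tissue_table(frequency)
        sigma = np.zeros(self.shape)
        eps_r = np.ones(self.shape)
        rho = np.zeros(self.shape)
        for label, prop in table.items():
            sel = self.tissue_label == label
            sigma[sel] = prop.sigma
            eps_r[sel] = prop.eps_r
            rho[sel] = prop.rho
        return sigma, eps_r, rho

    def heart_center_mm(self) -> np.ndarray:
        """Centroid of the ROI mask, mm."""
        xs, ys, zs = self.grid_mm()
        m = self.roi_mask
        return np.array([xs[m].mean(), ys[m].mean(), zs[m].mean()])

    def heart_center_index(self) -> tuple[int, int, int]:
        """Voxel index closest to the ROI centroid."""
        c = self.heart_center_mm()
        ax = self.axes_mm()
        return tuple(int(np.argmin(np.abs(a - ci))) for a, ci in zip(ax, c))


def _inside_ellipsoid(xs, ys, zs, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0


def build_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Build the layered elliptical-cylinder torso phantom.

    Deterministic for a fixed config.  Raises ``ConfigurationError`` when the
    heart ellipsoid is degenerate or not strictly inside the torso tissue.
    """
    cfg = config or PhantomConfig()
    if cfg.voxel_size <= 0:
        raise ConfigurationError("voxel_size must be positive")
    if min(cfg.torso_semiaxes) <= 0 or min(cfg.heart_semiaxes) <= 0:
        raise ConfigurationError("semi-axes must be positive")
    shell = cfg.skin_thickness + cfg.fat_thickness
    if shell >= min(cfg.torso_semiaxes):
        raise ConfigurationError("skin+fat shell thicker than the torso semi-axis")

    shape = tuple(int(round(f / cfg.voxel_size)) for f in cfg.fov)
    if min(shape) < 2:
        raise ConfigurationError("voxel_size too coarse for the requested FOV")

    axes = [
        (np.arange(n) + 0.5) * cfg.voxel_size - n * cfg.voxel_size / 2.0
        for n in shape
    ]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")

    a, b = cfg.torso_semiaxes
    rho2 = (xs / a) ** 2 + (ys / b) ** 2
    body = rho2 <= 1.0
    inner_fat = ((xs / (a - cfg.skin_thickness)) ** 2
                 + (ys / (b - cfg.skin_thickness)) ** 2) <= 1.0
    inner_muscle = ((xs / (a - shell)) ** 2 + (ys / (b - shell)) ** 2) <= 1.0

    label = np.zeros(shape, dtype=np.uint8)
    label[body] = SKIN
    label[inner_fat] = FAT
    label[inner_muscle] = MUSCLE
    for lc in cfg.lung_centers:
        lung = _inside_ellipsoid(xs, ys, zs, lc, cfg.lung_semiaxes) & inner_muscle
        label[lung] = LUNG

    heart = _inside_ellipsoid(xs, ys, zs, cfg.heart_center, cfg.heart_semiaxes)
    if not heart.any():
        raise ConfigurationError("heart ROI is empty on this grid")
    if not inner_muscle[heart].all():
        raise ConfigurationError("heart ellipsoid is not strictly inside the torso")
    label[heart] = HEART

    return Phantom(
        voxel_size=cfg.voxel_size,
        tissue_label=label,
        roi_mask=heart,
        config=cfg,
    )
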