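"""Channel-wise tuning and matching with lossy lumped elements.

A light-weight stand-in for a full multiport co-simulation: each channel sees
a two-element L-network in one of the three per-building-block topologies

* SGBT: parallel capacitor + serial inductor,
* BT:   serial capacitor + parallel capacitor,
* FD:   parallel inductor + serial capacitor,

solved in closed form where a real-valued solution exists and by a bounded
numerical search otherwise.  Component losses follow a shipped capacitor-ESR
table and an inductor Q-factor model (R = wL/Q).  The multiport S-matrix of a
matched array is obtained by augmenting the port impedance matrix with the
per-channel ladders through their ABCD representations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from .errors import ConfigurationError, FieldModelError

__all__ = [
    "MatchTopology",
    "PortNetwork",
    "match_channel",
    "sparameters",
    "synthesize_port_network",
    "ladder_power_split",
    "matching_report",
    "DB_FLOOR",
]

#: Reports never go below this reflection/coupling floor (dB).
DB_FLOOR = -100.0

TOPOLOGY_KINDS = {
    "SGBT": "parallel-C + series-L",
    "BT": "series-C + parallel-C",
    "FD": "parallel-L + series-C",
}


def _esr_table():
    text = resources.files("ptxbench.data").joinpath("capacitor_esr.yaml").read_text()
    return yaml.safe_load(text)


def capacitor_esr(c_farad: float, f_hz: float) -> float:
    """Capacitor equivalent series resistance from the shipped table, Ohm."""
    if c_farad <= 0:
        return 0.0
    tab = _esr_table()
    c_pf = np.asarray(tab["capacitance_pf"])
    f_mhz = np.asarray(tab["frequency_mhz"])
    esr = np.asarray(tab["esr_ohm"])  # (n_c, n_f)
    c = np.clip(c_farad * 1e12, c_pf[0], c_pf[-1])
    f = np.clip(f_hz * 1e-6, f_mhz[0], f_mhz[-1])
    col = np.interp(f, f_mhz, np.arange(len(f_mhz), dtype=float))
    lo, hi = int(np.floor(col)), int(np.ceil(col))
    wf = col - np.floor(col)
    esr_f = esr[:, lo] * (1 - wf) + esr[:, hi] * wf
    return float(np.interp(np.log(c), np.log(c_pf), esr_f))


@dataclass(frozen=True)
class MatchTopology:
    """Two-element matching network family for one building block."""

    building_block: str  # SGBT | BT | FD
    component_q: float = 100.0  # inductor quality factor
    lossy: bool = True

    def __post_init__(self):
        if self.building_block not in TOPOLOGY_KINDS:
            raise ConfigurationError(
                f"unknown topology {self.building_block!r}; valid: "
                f"{sorted(TOPOLOGY_KINDS)}"
            )
        if self.component_q <= 0:
            raise ConfigurationError("component_Q must be positive")

    @property
    def kind(self) -> str:
        return TOPOLOGY_KINDS[self.building_block]


@dataclass
class PortNetwork:
    """Reciprocal N-port impedance matrix at a single frequency."""

    z_matrix: np.ndarray  # complex (n, n), Ohm
    f0: float  # Hz

    def __post_init__(self):
        z = np.asarray(self.z_matrix, dtype=complex)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ConfigurationError("z_matrix must be square")
        if not np.allclose(z, z.T, atol=1e-9 * max(1.0, np.abs(z).max())):
            raise ConfigurationError("z_matrix must be symmetric (reciprocal)")
        if np.any(np.real(np.diag(z)) <= 0):
            raise ConfigurationError("diagonal real parts must be positive")
        self.z_matrix = z

    @property
    def n_ports(self) -> int:
        return self.z_matrix.shape[0]


# ---------------------------------------------------------------------------
# single-channel matching
# ---------------------------------------------------------------------------

def _element_impedance(kind: str, value: float, f0: float, topology: MatchTopology):
    """Complex impedance of one lumped element, including loss if enabled."""
    w = 2.0 * np.pi * f0
    if value <= 0:
        return None  # degenerate element, omitted from the ladder
    if kind == "C":
        z = 1.0 / (1j * w * value)
        if topology.lossy:
            z = z + capacitor_esr(value, f0)
        return z
    if kind == "L":
        z = 1j * w * value
        if topology.lossy:
            z = z + w * value / topology.component_q
        return z
    raise ConfigurationError(f"unknown element kind {kind!r}")


def _ladder_elements(topology: MatchTopology, components: dict, f0: float):
    """Ordered (placement, impedance) list from the load toward the source."""
    bb = topology.building_block
    out = []
    if bb == "SGBT":
        # serial inductor at the element, parallel capacitor at the feed
        pairs = [("series", "L", components.get("L", 0.0)),
                 ("shunt", "C", components.get("C", 0.0))]
    elif bb == "BT":
        pairs = [("series", "C", components.get("C_series", 0.0)),
                 ("shunt", "C", components.get("C_parallel", 0.0))]
    else:  # FD
        pairs = [("shunt", "L", components.get("L", 0.0)),
                 ("series", "C", components.get("C", 0.0))]
    for placement, kind, value in pairs:
        z = _element_impedance(kind, value, f0, topology)
        if z is not None:
            out.append((placement, z))
    return out


def ladder_input_impedance(elements, z_load: complex) -> complex:
    """Input impedance of a series/shunt ladder terminated by ``z_load``."""
    z = z_load
    for placement, ze in elements:
        if placement == "series":
            z = z + ze
        else:
            z = 1.0 / (1.0 / z + 1.0 / ze)
    return z


def _s11(z: complex, z0: float) -> complex:
    return (z - z0) / (z + z0)


def _db(x: float) -> float:
    return max(DB_FLOOR, 20.0 * np.log10(max(float(x), 1e-300)))


def _closed_form(z_in: complex, topology: MatchTopology, f0: float, z0: float):
    """Lossless closed-form L-network solution, or None when not real-valued."""
    w = 2.0 * np.pi * f0
    bb = topology.building_block
    if bb == "SGBT":
        # series L at the load, shunt C at the feed: works for Re(z_in) < z0
        r, x = z_in.real, z_in.imag
        if r > z0:
            return None
        xp = np.sqrt(r * (z0 - r))
        xl = xp - x  # series inductor reactance
        if xl <= 0:
            return None
        wc = xp / (r * r + xp * xp)  # feed-side shunt susceptance
        return {"L": xl / w, "C": wc / w}
    if bb == "FD":
        # shunt L at the load, series C at the feed
        y = 1.0 / z_in
        g, b = y.real, y.imag
        disc = g / z0 - g * g
        if disc < 0:
            return None
        root = np.sqrt(disc)
        inv_wl = b + root
        if inv_wl <= 0:
            return None
        zp = 1.0 / (g - 1j * root)
        xc = zp.imag  # series C must cancel +xc
        if xc <= 0:
            return None
        return {"L": 1.0 / (w * inv_wl), "C": 1.0 / (w * xc)}
    # BT: series C then shunt C
    r, x = z_in.real, z_in.imag
    if r > z0:
        return None
    xp = np.sqrt(r * (z0 - r))
    if x <= xp:
        return None  # series capacitor would need the wrong sign
    c_series = 1.0 / (w * (x - xp))
    wc2 = xp / (r * r + xp * xp)
    return {"C_series": c_series, "C_parallel": wc2 / w}


def _numeric_search(z_in, topology, f0, z0):
    """Bounded search over log-component values for best-achievable s11."""
    w = 2.0 * np.pi * f0
    keys = {"SGBT": ("C", "L"), "BT": ("C_series", "C_parallel"),
            "FD": ("L", "C")}[topology.building_block]
    bounds = []
    for k in keys:
        if k.startswith("C"):
            bounds.append((np.log(0.05e-12), np.log(1e-9)))
        else:
            bounds.append((np.log(0.1e-9), np.log(300e-9)))

    def cost(logv):
        comps = {k: float(np.exp(v)) for k, v in zip(keys, logv)}
        elems = _ladder_elements(topology, comps, f0)
        return abs(_s11(ladder_input_impedance(elems, z_in), z0))

    best = None
    for x0 in _numeric_starts(bounds):
        res = optimize.minimize(cost, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    return {k: float(np.exp(v)) for k, v in zip(keys, best.x)}


def _numeric_starts(bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for frac in ((0.3, 0.3), (0.5, 0.5), (0.7, 0.7), (0.3, 0.7), (0.7, 0.3)):
        yield lo + np.asarray(frac) * (hi - lo)


def match_channel(
    z_in: complex,
    topology: MatchTopology,
    f0: float,
    z0: float = 50.0,
):
    """Match one port impedance to ``z0`` with the building block's L-network.

    Returns ``(components, s11_db)``.  ``components`` maps element names to
    values in F/H; ``s11_db`` is evaluated with the lossy component models.
    Raises ``FieldModelError`` for non-passive inputs (Re z_in <= 0).
    """
    z_in = complex(z_in)
    if z_in.real <= 0:
        raise FieldModelError(f"non-passive input impedance {z_in}")
    comps = _closed_form(z_in, topology, f0, z0)
    if comps is None:
        comps = _numeric_search(z_in, topology, f0, z0)
    elems = _ladder_elements(topology, comps, f0)
    s11 = _s11(ladder_input_impedance(elems, z_in), z0)
    return comps, _db(abs(s11))


def ladder_power_split(topology: MatchTopology, components: dict,
                       z_load: complex, f0: float, z0: float = 50.0):
    """Power bookkeeping of a matched channel at 1 W incident power.

    Returns ``(reflected, delivered_to_load, dissipated_in_network)`` as
    fractions of the incident power; the three always sum to 1.
    """
    elems = _ladder_elements(topology, components, f0)
    z_total = ladder_input_impedance(elems, z_load)
    gamma = _s11(z_total, z0)
    # unit incident power: source voltage 2*sqrt(2*z0) behind z0
    v_s = 2.0 * np.sqrt(2.0 * z0)
    i1 = v_s / (z0 + z_total)
    v1 = i1 * z_total
    # walk the ladder from the source side toward the load
    v, i = v1, i1
    for placement, ze in reversed(elems):
        if placement == "series":
            v = v - i * ze
        else:
            i = i - v / ze
    p_load = 0.5 * np.real(v * np.conj(i))
    p_in = 0.5 * np.real(v1 * np.conj(i1))
    reflected = abs(gamma) ** 2
    return reflected, p_load, p_in - p_load


# ---------------------------------------------------------------------------
# multiport S-parameters
# ---------------------------------------------------------------------------

def _ladder_abcd(elements) -> np.ndarray:
    """ABCD matrix of a ladder, external (source) side to array (load) side."""
    m = np.eye(2, dtype=complex)
    for placement, ze in reversed(elements):
        if placement == "series":
            stage = np.array([[1.0, ze], [0.0, 1.0]], dtype=complex)
        else:
            stage = np.array([[1.0, 0.0], [1.0 / ze, 1.0]], dtype=complex)
        m = m @ stage
    return m


def sparameters(
    network: PortNetwork,
    components: list[dict] | None = None,
    topology: MatchTopology | None = None,
    z0: float = 50.0,
):
    """S-matrix of the (optionally matched) array, plus max reflection/coupling.

    Returns ``(s_matrix, max_reflection_db, max_coupling_db)``.  When
    ``components`` is given it must hold one component dict per channel and
    ``topology`` must be set; the port matrix is then augmented by the
    per-channel matching ladders before the Z-to-S conversion.
    """
    z = network.z_matrix
    n = network.n_ports
    if components is not None:
        if topology is None:
            raise ConfigurationError("components given without a topology")
        if len(components) != n:
            raise ConfigurationError("need component values for every channel")
        a = np.ones(n, dtype=complex)
        b = np.zeros(n, dtype=complex)
        c = np.zeros(n, dtype=complex)
        d = np.ones(n, dtype=complex)
        for ch, comp in enumerate(components):
            m = _ladder_abcd(_ladder_elements(topology, comp, network.f0))
            a[ch], b[ch], c[ch], d[ch] = m[0, 0], m[0, 1], m[1, 0], m[1, 1]
        num = a[:, None] * z + np.diag(b)
        den = c[:, None] * z + np.diag(d)
        try:
            z = num @ np.linalg.inv(den)
        except np.linalg.LinAlgError as err:
            raise FieldModelError(f"singular augmented network: {err}") from err
    eye = np.eye(n)
    try:
        s = (z - z0 * eye) @ np.linalg.inv(z + z0 * eye)
    except np.linalg.LinAlgError as err:
        raise FieldModelError(f"singular (Z + z0 I): {err}") from err
    refl = np.abs(np.diag(s)).max()
    off = np.abs(s - np.diag(np.diag(s)))
    coup = off.max() if n > 1 else 0.0
    return s, _db(refl), _db(coup)


def synthesize_port_network(
    n_channels: int,
    f0: float,
    seed: int = 0,
    element_centers: np.ndarray | None = None,
    coupling_strength: float = 0.15,
    decay_mm: float = 80.0,
    r_range: tuple[float, float] = (30.0, 70.0),
    x_range: tuple[float, float] = (-30.0, 30.0),
) -> PortNetwork:
    """Synthetic passive reciprocal port matrix with distance-decay coupling.

    The real part is kept positive semi-definite (shrinking the off-diagonal
    block if needed) so the network is passive by construction.
    """
    rng = np.random.default_rng(seed)
    r_diag = rng.uniform(*r_range, n_channels)
    x_diag = rng.uniform(*x_range, n_channels)
    if element_centers is not None:
        d = np.linalg.norm(
            element_centers[:, None, :] - element_centers[None, :, :], axis=-1
        )
        k = np.exp(-d / decay_mm)
    else:
        k = np.exp(-np.abs(np.subtract.outer(np.arange(n_channels),
                                             np.arange(n_channels))) / 2.0)
    np.fill_diagonal(k, 0.0)
    r_off = coupling_strength * k * np.sqrt(np.outer(r_diag, r_diag))
    r = np.diag(r_diag) + r_off
    # enforce passivity of the resistive part
    lam_min = np.linalg.eigvalsh(r).min()
    while lam_min <= 1e-9:
        r_off *= 0.5
        r = np.diag(r_diag) + r_off
        lam_min = np.linalg.eigvalsh(r).min()
    x_off = coupling_strength * k * 20.0 * rng.uniform(-1.0, 1.0, (n_channels,) * 2)
    x_off = 0.5 * (x_off + x_off.T)
    np.fill_diagonal(x_off, 0.0)
    z = r + 1j * (np.diag(x_diag) + x_off)
    return PortNetwork(z_matrix=z, f0=f0)


def matching_report(
    network: PortNetwork,
    topology: MatchTopology,
    z0: float = 50.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Match every channel to its self impedance and tabulate the results.

    Returns a per-channel DataFrame (component values, matched s11) plus the
    component list, and appends a summary row with the multiport worst-case
    reflection and coupling after matching.
    """
    rows = []
    components = []
    for ch in range(network.n_ports):
        comps, s11_db = match_channel(
            network.z_matrix[ch, ch], topology, network.f0, z0
        )
        components.append(comps)
        row = {"channel": ch + 1, "s11_db": s11_db}
        row.update({k: v for k, v in comps.items()})
        rows.append(row)
    _, refl_db, coup_db = sparameters(network, components, topology, z0)
    df = pd.DataFrame(rows)
    df.attrs["max_reflection_db"] = refl_db
    df.attrs["max_coupling_db"] = coup_db
    return df, components
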