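"""Static pTx field shaping: power bookkeeping, shimming, SAR-aware MOO.

One complex weight per channel shapes the superposed transmit field

    B1+(r; w) = sum_ch B1+_ch(r) * w_ch.

Forward power is booked per port against the 2 kW amplifier reference,

    P_fwd = w^H (I * U^2 / R) w,   U = sqrt(2000 * 50) V, R = 50 Ohm,

while efficiency maps are rescaled to a total incident power P_In of 1 kW
(the field-set normalization), so every reported B1+ metric is in uT/sqrt(kW).

Three shim drivers are provided: max-min B1+ over the heart ROI (avoids
signal dropouts), coefficient-of-variation minimization (homogeneity), and a
bi-objective trade-off (max min-B1+ vs. min VOP-bounded max SAR10g) whose
Pareto front is re-evaluated on the uncompressed SAR set; the headline point
maximizes min B1+ / sqrt(SAR10g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as sciopt
from scipy.special import logsumexp

from .constants import R_REF_OHM, U_REF_V
from .errors import ConfigurationError, OptimizationError
from .fields import ChannelFieldSet
from .optimize import GAConfig, ga_minimize, nsga2
from .sar import QMatrixSet, VOPSet, evaluate_sar

__all__ = [
    "ExcitationVector",
    "ShimResult",
    "ParetoFront",
    "forward_power",
    "superpose_scaled",
    "shim",
    "shim_moo",
    "roi_metrics",
    "equal_phase_baseline",
]

MODES = ("phase-only", "phase-amplitude")


@dataclass
class ExcitationVector:
    """Complex per-channel drive with port power bookkeeping."""

    weights: np.ndarray
    mode: str = "phase-only"
    u_ref: float = U_REF_V  # port voltage for 2 kW at 50 Ohm
    r_ref: float = R_REF_OHM

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=complex).ravel()
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        if self.mode == "phase-only":
            amp = np.abs(self.weights)
            if amp.min() <= 0:
                raise ConfigurationError("phase-only weights must be nonzero")
            if not np.allclose(amp, 1.0, atol=1e-9):
                self.weights = self.weights / amp  # exc / abs(exc)

    @property
    def n_channels(self) -> int:
        return len(self.weights)


def forward_power(exc: ExcitationVector) -> float:
    """Total forward power P_fwd = (U^2/R) * sum |w|^2, in kW."""
    return float(
        (exc.u_ref**2 / exc.r_ref) * np.sum(np.abs(exc.weights) ** 2) / 1e3
    )


def _weights(exc) -> np.ndarray:
    return exc.weights if isinstance(exc, ExcitationVector) else np.asarray(
        exc, dtype=complex
    )


def superpose_scaled(
    fieldset: ChannelFieldSet,
    exc,
    p_in_kw: float = 1.0,
) -> np.ndarray:
    """|B1+| efficiency map rescaled to a total incident power of ``p_in_kw``.

    Invariant under a global phase of the excitation; units uT/sqrt(kW) for
    the default 1 kW reference.
    """
    w = _weights(exc)
    cmap = fieldset.superpose(w)
    p_inc_w = np.sum(np.abs(w) ** 2) * fieldset.per_channel_power
    if p_inc_w <= 0:
        raise ConfigurationError("excitation has zero incident power")
    return np.abs(cmap) * np.sqrt(p_in_kw * 1e3 / p_inc_w)


def roi_metrics(
    fieldset: ChannelFieldSet,
    roi: np.ndarray,
    exc,
    q10g: QMatrixSet | VOPSet | None = None,
    p_in_kw: float = 1.0,
) -> "ShimResult":
    """ShimResult metric block for one excitation (all on the 1 kW scale)."""
    w = _weights(exc)
    emap = superpose_scaled(fieldset, w, p_in_kw)
    vals = emap[roi]
    mean = float(vals.mean())
    cov = float(100.0 * vals.std() / mean) if mean > 0 else float("nan")
    max_sar = float("nan")
    if q10g is not None:
        # local SAR is referred to P_In = 1 W (the printed-table convention)
        p_inc_w = np.sum(np.abs(w) ** 2) * fieldset.per_channel_power
        w_1w = w * np.sqrt(1.0 / p_inc_w)
        max_sar, _ = evaluate_sar(w_1w, q10g)
    exc_obj = exc if isinstance(exc, ExcitationVector) else ExcitationVector(
        w, mode="phase-amplitude"
    )
    return ShimResult(
        exc=exc_obj,
        mean_b1_roi=mean,
        min_b1_roi=float(vals.min()),
        cov_roi=cov,
        max_sar10g=max_sar,
        p_fwd_kw=forward_power(exc_obj),
        p_in_kw=p_in_kw,
    )


@dataclass
class ShimResult:
    """Shim metrics over the heart ROI, on the 1 kW incident-power scale."""

    exc: ExcitationVector
    mean_b1_roi: float  # uT/sqrt(kW)
    min_b1_roi: float  # uT/sqrt(kW)
    cov_roi: float  # %
    max_sar10g: float  # W/kg at P_In = 1 kW (nan if no SAR set given)
    p_fwd_kw: float
    p_in_kw: float = 1.0


@dataclass
class ParetoFront:
    """Non-dominated trade-off set from the bi-objective shim."""

    excitations: list  # ExcitationVector per point
    min_b1: np.ndarray  # uT/sqrt(kW)
    max_sar_vop: np.ndarray  # W/kg (VOP bound, used during optimization)
    max_sar_full: np.ndarray  # W/kg (re-evaluated, uncompressed set)
    selected: int  # argmax min_b1 / sqrt(max_sar_full)


# ---------------------------------------------------------------------------
# decision-vector plumbing
# ---------------------------------------------------------------------------

_LOG_AMP_MIN = -3.0  # amplitude floor exp(-3) ~ 0.05; cap |w| <= 1


def _bounds(n_ch: int, mode: str):
    if mode == "phase-only":
        lower = np.zeros(n_ch)
        upper = np.full(n_ch, 2.0 * np.pi)
        periodic = np.ones(n_ch, dtype=bool)
    else:
        lower = np.concatenate([np.zeros(n_ch), np.full(n_ch, _LOG_AMP_MIN)])
        upper = np.concatenate([np.full(n_ch, 2.0 * np.pi), np.zeros(n_ch)])
        periodic = np.concatenate(
            [np.ones(n_ch, dtype=bool), np.zeros(n_ch, dtype=bool)]
        )
    return lower, upper, periodic


def _decode(x: np.ndarray, n_ch: int, mode: str) -> np.ndarray:
    """Decision vectors (pop, dim) -> complex weights (pop, n_ch)."""
    x = np.atleast_2d(x)
    phases = x[:, :n_ch]
    if mode == "phase-only":
        return np.exp(1j * phases)
    amps = np.exp(x[:, n_ch:])
    return amps * np.exp(1j * phases)


def _scaled_roi_maps(b_roi: np.ndarray, w: np.ndarray, per_channel_power: float):
    """|B1+| over ROI voxels at P_In = 1 kW, batched over excitations."""
    maps = np.abs(w @ b_roi.T)  # (pop, nvox)
    p_inc = np.sum(np.abs(w) ** 2, axis=1) * per_channel_power
    return maps * np.sqrt(1e3 / p_inc)[:, None]


def _objective(kind: str, b_roi, per_channel_power, n_ch, mode):
    def fun(x):
        w = _decode(x, n_ch, mode)
        m = _scaled_roi_maps(b_roi, w, per_channel_power)
        if kind == "MINB1":
            return -m.min(axis=1)
        mean = m.mean(axis=1)
        return np.where(mean > 0, m.std(axis=1) / mean, np.inf)

    return fun


def _soft_objective(kind: str, b_roi, per_channel_power, n_ch, mode,
                    beta: float = 50.0):
    """Smooth surrogate for the local refiner (softmin via log-sum-exp)."""

    def fun(x):
        w = _decode(x, n_ch, mode)
        m = _scaled_roi_maps(b_roi, w, per_channel_power)[0]
        if kind == "MINB1":
            return float(logsumexp(-beta * m) / beta)  # ~ -min
        mean = m.mean()
        return float(m.std() / mean) if mean > 0 else np.inf

    return fun


def shim(
    fieldset: ChannelFieldSet,
    roi: np.ndarray,
    objective: str = "MINB1",
    mode: str = "phase-only",
    ga_config: GAConfig | None = None,
    seed: int = 0,
    q10g: QMatrixSet | VOPSet | None = None,
    local_refine: bool = True,
) -> ShimResult:
    """Static shim under one objective: GA global search + local refinement.

    ``MINB1`` maximizes the ROI minimum of the 1 kW-scaled |B1+|; ``COV``
    minimizes SD/mean.  Deterministic for a fixed seed.
    """
    if objective not in ("MINB1", "COV"):
        raise ConfigurationError("objective must be MINB1 or COV")
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ConfigurationError("ROI is empty")
    b_roi = fieldset.b1_plus[:, roi].T  # (nvox, nch)
    if not np.all(np.isfinite(b_roi)):
        raise ConfigurationError("non-finite fields inside the ROI")
    n_ch = fieldset.n_channels
    rng = np.random.default_rng(seed)

    fun = _objective(objective, b_roi, fieldset.per_channel_power, n_ch, mode)
    lower, upper, periodic = _bounds(n_ch, mode)
    x_best, f_best = ga_minimize(fun, lower, upper, periodic, ga_config, rng)

    if local_refine:
        soft = _soft_objective(objective, b_roi, fieldset.per_channel_power,
                               n_ch, mode)
        res = sciopt.minimize(
            soft, x_best, method="L-BFGS-B",
            bounds=list(zip(lower - (periodic * 2 * np.pi), upper + 0.0)),
        )
        f_ref = float(fun(res.x[None])[0])
        if f_ref < f_best:
            x_best, f_best = res.x, f_ref

    w = _decode(x_best, n_ch, mode)[0]
    exc = ExcitationVector(w, mode=mode)
    return roi_metrics(fieldset, roi, exc, q10g=q10g)


def equal_phase_baseline(
    fieldset: ChannelFieldSet,
    roi: np.ndarray,
    q10g: QMatrixSet | VOPSet | None = None,
) -> ShimResult:
    """Baseline drive: equal phase (0 deg) and amplitude (1) on all channels."""
    w = np.ones(fieldset.n_channels, dtype=complex)
    return roi_metrics(fieldset, roi, ExcitationVector(w), q10g=q10g)


def shim_moo(
    fieldset: ChannelFieldSet,
    roi: np.ndarray,
    vops: VOPSet,
    qfull: QMatrixSet,
    mode: str = "phase-amplitude",
    ga_config: GAConfig | None = None,
    seed: int = 0,
) -> ParetoFront:
    """Bi-objective shim: (-min B1+_ROI, VOP-bounded max SAR10g).

    The returned front is re-evaluated on the uncompressed set and the
    selected point maximizes min B1+ / sqrt(SAR10g_full).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ConfigurationError("ROI is empty")
    if vops.n_channels != fieldset.n_channels or qfull.n_channels != fieldset.n_channels:
        raise ConfigurationError("SAR sets do not match the field set")
    b_roi = fieldset.b1_plus[:, roi].T
    n_ch = fieldset.n_channels
    pcp = fieldset.per_channel_power
    rng = np.random.default_rng(seed)

    vop_mats = vops.vops

    def fun(x):
        w = _decode(x, n_ch, mode)
        m = _scaled_roi_maps(b_roi, w, pcp)
        # SAR objective at P_In = 1 W, matching the reported convention
        scale = np.sqrt(1.0 / (np.sum(np.abs(w) ** 2, axis=1) * pcp))
        w1 = w * scale[:, None]
        sar = np.einsum("pe,vef,pf->pv", np.conj(w1), vop_mats, w1,
                        optimize=True).real.max(axis=1)
        return np.column_stack([-m.min(axis=1), sar])

    lower, upper, periodic = _bounds(n_ch, mode)
    xs, fs = nsga2(fun, lower, upper, periodic, ga_config, rng)
    if len(xs) == 0:
        raise OptimizationError("multi-objective shim produced an empty front")

    excs, sar_full = [], []
    for x in xs:
        w = _decode(x, n_ch, mode)[0]
        exc = ExcitationVector(w, mode=mode)
        excs.append(exc)
        p_inc = np.sum(np.abs(w) ** 2) * pcp
        s, _ = evaluate_sar(w * np.sqrt(1.0 / p_inc), qfull)
        sar_full.append(s)
    min_b1 = -fs[:, 0]
    sar_full = np.asarray(sar_full)
    with np.errstate(divide="ignore"):
        score = np.where(sar_full > 0, min_b1 / np.sqrt(sar_full), -np.inf)
    return ParetoFront(
        excitations=excs,
        min_b1=min_b1,
        max_sar_vop=fs[:, 1],
        max_sar_full=sar_full,
        selected=int(np.argmax(score)),
    )
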