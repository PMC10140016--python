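"""End-to-end scenario orchestration and table-style reporting.

A Scenario names an array (building block + setup), a phantom, seeds and
optimizer budgets; ``run_scenario`` executes field synthesis, optimal
superposition, the three static shims plus the equal-drive baseline, the
SAR-aware multi-objective shim, kT-point designs and the SENSE g-factor
table, writing CSV/JSON outputs with a config-hash manifest so a rerun with
the same scenario reproduces every file byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arrays import CHANNEL_COUNTS, make_array_spec
from .errors import ConfigurationError, PtxBenchError
from .fields import simulate_fields
from .gfactor import g_report
from .optimize import GAConfig
from .phantom import PhantomConfig, build_phantom
from .dynamic_ptx import (design_kt, pulse_forward_power, scale_efficiency,
                          simulate_fa)
from .sar import average_10g, build_q_matrices, compress_vop, pulse_sar
from .static_ptx import equal_phase_baseline, roi_metrics, shim, shim_moo
from .superposition import (CoilLossModel, CouplingLossModel,
                            optimal_superposition, performance_ratio,
                            power_correlation, roi_statistics)

__all__ = ["Scenario", "run_scenario", "relative_change", "METRICS_COLUMNS",
           "StageError"]

#: Shared column schema of the static/dynamic metric tables.
METRICS_COLUMNS = [
    "scenario",
    "method",
    "mean_b1_uT_per_sqrt_kW",
    "min_b1_uT_per_sqrt_kW",
    "cov_percent",
    "max_sar10g_W_per_kg",
    "p_fwd_kW",
]

SUPERPOSITION_COLUMNS = [
    "scenario", "which", "mode", "roi_mean", "roi_sd", "roi_min",
    "mean_performance_ratio_percent",
]


class StageError(PtxBenchError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class Scenario:
    """One pipeline run: array, phantom, seeds and optimizer budgets."""

    name: str = "demo"
    building_block: str = "FD"
    setup: str = "BL-7T"
    phantom: str = "demo"  # demo | default
    array_scale: float = 0.6
    seed: int = 0
    mode: str = "phase-amplitude"
    ga_population: int = 80
    ga_generations: int = 30
    kt_points: tuple = (4,)
    kt_candidates_per_axis: int = 3
    vop_target_percent: float = 15.0
    vop_max_matrices: int = 800
    vop_test_excitations: int = 300
    gfactor_r: tuple = (2, 3, 4)
    gfactor_axes: tuple = ("y", "x")

    def __post_init__(self):
        if (self.building_block, self.setup) not in CHANNEL_COUNTS:
            raise ConfigurationError(
                f"unknown array {(self.building_block, self.setup)}"
            )
        if self.phantom not in ("demo", "default"):
            raise ConfigurationError("phantom must be 'demo' or 'default'")

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        for key in ("kt_points", "gfactor_r", "gfactor_axes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig.demo() if self.phantom == "demo" else PhantomConfig()

    def ga_config(self) -> GAConfig:
        return GAConfig(population=self.ga_population,
                        generations=self.ga_generations)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _metric_row(scenario: str, method: str, mean, minimum, cov, sar, pfwd):
    return dict(zip(METRICS_COLUMNS, [
        scenario, method,
        round(float(mean), 6), round(float(minimum), 6),
        round(float(cov), 6),
        round(float(sar), 6) if np.isfinite(sar) else float("nan"),
        round(float(pfwd), 6),
    ]))


def run_scenario(scenario: Scenario, outdir) -> dict:
    """Run every stage of a scenario; returns the output tables.

    Outputs: ``manifest.json``, ``metrics.csv`` (Tables-2-to-6-style shared
    schema), ``superposition.csv`` and ``gfactors.csv`` inside ``outdir``.
    A stage failure raises :class:`StageError` naming the stage; tables
    produced by earlier stages remain on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        manifest = {
            "scenario": asdict(scenario),
            "config_hash": scenario.digest(),
            "seed": scenario.seed,
            "versions": {
                "ptxbench": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))

        stage = "phantom"
        phantom = build_phantom(scenario.phantom_config())
        roi = phantom.roi_mask

        stage = "fields"
        spec = make_array_spec(scenario.building_block, scenario.setup,
                               phantom, scale=scenario.array_scale)
        fieldset = simulate_fields(phantom, spec, seed=scenario.seed)

        stage = "superposition"
        phi = power_correlation(
            fieldset,
            CoilLossModel(),
            CouplingLossModel(element_centers=spec.element_centers),
        )
        sup_rows = []
        for which in ("TXE", "iSNR"):
            intr = optimal_superposition(fieldset, phi, which, "intrinsic")
            real = optimal_superposition(fieldset, phi, which, "realistic")
            ratio = performance_ratio(intr, real)
            stats = roi_statistics(real.values, roi)
            sup_rows.append(dict(zip(SUPERPOSITION_COLUMNS, [
                scenario.name, which, "realistic",
                round(stats["mean"], 6), round(stats["sd"], 6),
                round(stats["min"], 6),
                round(float(np.nanmean(ratio[roi])), 6),
            ])))
        pd.DataFrame(sup_rows, columns=SUPERPOSITION_COLUMNS).to_csv(
            out / "superposition.csv", index=False)

        stage = "sar"
        q_point = build_q_matrices(fieldset)
        q10 = average_10g(q_point, phantom, frequency=fieldset.frequency)
        # cap the compression workload on large grids (seeded subsample)
        if q10.n_matrices > scenario.vop_max_matrices:
            rng = np.random.default_rng(scenario.seed)
            pick = rng.choice(q10.n_matrices, scenario.vop_max_matrices,
                              replace=False)
            pick.sort()
            from .sar import QMatrixSet
            q10_opt = QMatrixSet(q=q10.q[pick], location=q10.location[pick],
                                 averaged=True)
        else:
            q10_opt = q10
        vops = compress_vop(
            q10_opt,
            target_mean_overestimation=scenario.vop_target_percent,
            n_test_excitations=scenario.vop_test_excitations,
            seed=scenario.seed,
        )

        stage = "static_ptx"
        rows = []
        base = equal_phase_baseline(fieldset, roi, q10g=q10)
        rows.append(_metric_row(scenario.name, "baseline", base.mean_b1_roi,
                                base.min_b1_roi, base.cov_roi,
                                base.max_sar10g, base.p_fwd_kw))
        for objective, label in (("MINB1", "minB1"), ("COV", "CoV")):
            res = shim(fieldset, roi, objective=objective, mode=scenario.mode,
                       ga_config=scenario.ga_config(), seed=scenario.seed,
                       q10g=q10)
            rows.append(_metric_row(scenario.name, label, res.mean_b1_roi,
                                    res.min_b1_roi, res.cov_roi,
                                    res.max_sar10g, res.p_fwd_kw))

        stage = "moo"
        front = shim_moo(fieldset, roi, vops, q10, mode=scenario.mode,
                         ga_config=scenario.ga_config(), seed=scenario.seed)
        sel = front.excitations[front.selected]
        moo_res = roi_metrics(fieldset, roi, sel, q10g=q10)
        rows.append(_metric_row(scenario.name, "MOO", moo_res.mean_b1_roi,
                                moo_res.min_b1_roi, moo_res.cov_roi,
                                moo_res.max_sar10g, moo_res.p_fwd_kw))

        stage = "dynamic_ptx"
        for n_points in scenario.kt_points:
            pulse = design_kt(
                fieldset, roi, n_points=n_points, seed=scenario.seed,
                n_candidates_per_axis=scenario.kt_candidates_per_axis,
            )
            fa = simulate_fa(pulse, fieldset, method="STA", mask=roi)
            eff = scale_efficiency(fa, pulse, fieldset.per_channel_power)
            vals = eff[roi]
            fa_vals = fa.fa[roi]
            cov = 100.0 * fa_vals.std() / fa_vals.mean()
            sar, _ = pulse_sar(pulse.sub_weights, q10, p_in_w=1.0,
                               per_channel_power=fieldset.per_channel_power)
            rows.append(_metric_row(
                scenario.name, f"{n_points}kT", vals.mean(), vals.min(), cov,
                sar, pulse_forward_power(pulse)))
        pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(
            out / "metrics.csv", index=False)

        stage = "gfactor"
        gdf = g_report(fieldset, r_list=scenario.gfactor_r,
                       axes=scenario.gfactor_axes, label=scenario.name)
        gdf.to_csv(out / "gfactors.csv", index=False)
    except PtxBenchError:
        raise
    except Exception as err:  # surface the failing stage
        raise StageError(stage, err) from err

    return {
        "metrics": pd.read_csv(out / "metrics.csv"),
        "superposition": pd.read_csv(out / "superposition.csv"),
        "gfactors": pd.read_csv(out / "gfactors.csv"),
        "manifest": manifest,
    }


def relative_change(row, reference) -> dict:
    """Percent change per metric between two matching metric rows.

    ``100 * (value - ref) / ref``; a zero reference yields NaN and is listed
    under ``undefined``.
    """
    row = dict(row)
    reference = dict(reference)
    if row.get("method") != reference.get("method"):
        raise ConfigurationError("relative_change requires matching methods")
    out, undefined = {}, []
    for key in METRICS_COLUMNS[2:]:
        ref = float(reference[key])
        val = float(row[key])
        if ref == 0 or not np.isfinite(ref):
            out[key] = float("nan")
            undefined.append(key)
        else:
            out[key] = 100.0 * (val - ref) / ref
    out["undefined"] = undefined
    return out
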