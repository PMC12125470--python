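"""Configuration-driven study pipeline.

Reproduces the four analyses end-to-end on a synthetic nose: network flow
with dimensionless screening and the secondary-flow statistic, the odorant
solubility sweep with absorption maps, the parallel-coil vs elongated-tube
gas-chromatograph comparison, and the particle deposition curve. Every
numeric output carries a provenance header (config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatography as gc
from . import flow as flowmod
from . import nose as nosemod
from . import particles as pmod
from . import uptake as upmod
from .odorants import MucosaSpec, default_odorants, load_odorant_table

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "species_preset", "run_study", "load_config"]

ML_MIN_TO_M3_S = 1e-6 / 60.0

#: Restful breathing frequencies, Hz (mouse ~3-5, rat ~2).
BREATHING_HZ = {"mouse": 4.0, "rat": 2.0}
#: Restful breathing flow rates, mL/min.
FLOW_ML_MIN = {"mouse": 25.0, "rat": 200.0}
#: Plausible physiological flow ranges, mL/min.
FLOW_RANGE_ML_MIN = {"mouse": (10.0, 35.0), "rat": (100.0, 450.0)}

PAPER_PARTICLE_SIZES_UM = (1.5, 3.0, 5.0, 8.0, 12.0, 15.0, 25.0, 43.0)
ALL_STAGES = ("flow", "uptake", "gc", "particles")


@dataclass(frozen=True)
class StudyConfig:
    """One study run: a species (or explicit nose spec) plus protocol knobs."""

    species: str = "mouse"
    Q_ml_min: float | None = None  # default: species value
    breathing_frequency: float | None = None  # Hz
    odorant_table: str | None = None  # path; default: built-in panel
    beta_grid: tuple[float, ...] = tuple(np.logspace(-10, 0, 21))
    gc_beta: float = 0.01  # partition coefficient of the GC comparison odorant
    gc_film_term: bool = False
    particle_sizes_um: tuple[float, ...] = PAPER_PARTICLE_SIZES_UM
    particles_per_size: int = 2000
    particle_density: float = 1000.0  # kg/m³
    uptake_resolution: tuple[int, int] = (200, 64)
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    outdir: str = "results/study"
    nose_spec: nosemod.SyntheticNoseSpec | None = None

    def __post_init__(self) -> None:
        if self.Q_ml_min is not None and not self.Q_ml_min > 0:
            raise ValueError("Q_ml_min must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def flow_rate_ml_min(self) -> float:
        return self.Q_ml_min if self.Q_ml_min is not None else FLOW_ML_MIN[self.species]

    @property
    def frequency_hz(self) -> float:
        if self.breathing_frequency is not None:
            return self.breathing_frequency
        return BREATHING_HZ.get(self.species, 4.0)

    def spec(self) -> nosemod.SyntheticNoseSpec:
        if self.nose_spec is not None:
            return self.nose_spec
        try:
            return nosemod.SPECIES_SPECS[self.species](seed=self.seed)
        except KeyError:
            raise ValueError(
                f"unknown species {self.species!r}; available presets: "
                f"{sorted(nosemod.SPECIES_SPECS)}"
            ) from None

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # the science, not the output location
        if payload["nose_spec"] is not None:
            payload["nose_spec"] = dataclasses.asdict(self.nose_spec)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def species_preset(name: str) -> StudyConfig:
    """Default study configuration for a species preset.

    Mouse: 25 mL/min; rat: 200 mL/min (restful-breathing medians; the
    plausible ranges are 10-35 and 100-450 mL/min respectively).
    """
    if name not in nosemod.SPECIES_SPECS:
        raise ValueError(
            f"unknown species {name!r}; available presets: {sorted(nosemod.SPECIES_SPECS)}"
        )
    q = FLOW_ML_MIN[name]
    lo, hi = FLOW_RANGE_ML_MIN[name]
    assert lo <= q <= hi
    return StudyConfig(species=name, Q_ml_min=q)


def load_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from a single-document YAML file."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if "nose_spec" in raw and raw["nose_spec"] is not None:
        raw["nose_spec"] = nosemod.SyntheticNoseSpec(**raw["nose_spec"])
    for key in ("beta_grid", "particle_sizes_um", "stages"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if "uptake_resolution" in raw:
        raw["uptake_resolution"] = tuple(raw["uptake_resolution"])
    return StudyConfig(**raw)


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with path.open("w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def run_study(config: StudyConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a bundle dict with the network, flows, and per-stage results;
    writes tables and a provenance block under ``config.outdir``. Stage
    failures preserve earlier outputs and are recorded in ``manifest.json``;
    the bundle's ``"ok"`` flag reflects them.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    prov_header = f"# nosegc study config={chash} seed={config.seed}\n"
    manifest: dict = {"config_hash": chash, "seed": config.seed, "stages": {}, "errors": {}}
    bundle: dict = {"config": config, "ok": True}

    spec = config.spec()
    network = nosemod.build_nose(spec)
    network = nosemod.calibrate_to_morphometry(
        network, spec.target_surface_area, spec.target_volume
    )
    tube = nosemod.elongated_tube_variant(network)
    q_total = config.flow_rate_ml_min * ML_MIN_TO_M3_S
    net_flow = flowmod.solve_flow(network, q_total, spec.dm_flow_fraction)
    tube_flow = flowmod.solve_flow(tube, q_total, spec.dm_flow_fraction)
    bundle.update(network=network, tube=tube, flow=net_flow, tube_flow=tube_flow)
    (outdir / "network.json").write_text(network.to_json())
    nosemod.write_vtk_centerlines(network, outdir / "network_centerlines.vtk")

    mucosa = MucosaSpec()
    if config.odorant_table:
        odorants, row_errors = load_odorant_table(config.odorant_table, mucosa)
        if row_errors:
            manifest["errors"]["odorant_table_rows"] = row_errors
    else:
        odorants = default_odorants()
    bundle["odorants"] = odorants

    def run_stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {"ok": True, "seconds": time.perf_counter() - t0}
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            manifest["stages"][name] = {"ok": False, "seconds": time.perf_counter() - t0}
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"
            bundle["ok"] = False
            log.exception("stage %s failed", name)

    # -- flow stage --------------------------------------------------------
    def stage_flow():
        rows = []
        for s in network.segments:
            rep = flowmod.dimensionless_numbers(s, net_flow, config.frequency_hz)
            rows.append(
                {
                    "segment": s.id,
                    "epithelium": s.epithelium,
                    "flow_m3_s": net_flow.flow[s.id],
                    "mean_velocity_m_s": net_flow.mean_velocity[s.id],
                    "hydraulic_diameter_m": s.hydraulic_diameter,
                    "Re": rep.Re,
                    "W0": rep.W0,
                    "S": rep.S,
                    "quasi_steady": rep.assumptions_ok["quasi_steady"],
                    "laminar": rep.assumptions_ok["laminar"],
                }
            )
        df = pd.DataFrame(rows)
        _write_csv(df, outdir / "flow_table.csv", prov_header)
        # secondary-flow statistic exercised on synthetic swirl planes:
        # strong swirl stands in for an olfactory-recess plane, weak swirl
        # for an anterior plane.
        ss_rows = []
        for label, ratio in (("anterior_like", 0.2), ("olfactory_like", 2.0)):
            field_ = flowmod.synthetic_swirl_field(swirl_ratio=ratio)
            _, mean, rep = flowmod.secondary_strength(field_)
            ss_rows.append({"plane": label, "swirl_ratio": ratio, "mean_SS": mean, **rep})
        _write_csv(pd.DataFrame(ss_rows), outdir / "secondary_flow.csv", prov_header)
        bundle["flow_table"] = df
        bundle["secondary_flow"] = pd.DataFrame(ss_rows)

    # -- uptake stage ------------------------------------------------------
    def stage_uptake():
        nax, ntr = config.uptake_resolution
        sweep = upmod.solubility_sweep(
            network, net_flow, mucosa, config.beta_grid, n_axial=nax, n_transverse=ntr
        )
        _write_csv(sweep, outdir / "solubility_sweep.csv", prov_header)
        maps = {}
        for od in odorants:
            amap = upmod.absorption_map(
                network, net_flow, od, mucosa, n_axial=nax, n_transverse=ntr
            )
            fname = f"absorption_map_{od.name.lower().replace(' ', '_')}.csv"
            _write_csv(amap, outdir / fname, prov_header)
            maps[od.name] = amap
        bundle["solubility_sweep"] = sweep
        bundle["absorption_maps"] = maps

    # -- GC stage ----------------------------------------------------------
    def stage_gc():
        od = default_odorants()[1].with_beta(config.gc_beta)
        report = gc.compare_architectures(
            network, net_flow, tube, tube_flow, od, mucosa, film_term=config.gc_film_term
        )
        (outdir / "gc_comparison.json").write_text(gc.comparison_report_json(report))
        u_grid = np.logspace(-3, 0.5, 200)
        curves = []
        for label in ("parallel", "tube"):
            col = report["_columns"][label]
            curve = gc.plate_number_curve(col, u_grid)
            band = gc.velocity_robustness(curve, 0.8)
            report[label]["bandwidth_80pct_log_width"] = band["log_width"]
            curves.append(
                pd.DataFrame(
                    {"architecture": label, "u_m_s": curve.u, "H_m": curve.H, "N": curve.N}
                )
            )
        _write_csv(pd.concat(curves, ignore_index=True), outdir / "plate_curves.csv", prov_header)
        bundle["gc_report"] = report

    # -- particle stage ----------------------------------------------------
    def stage_particles():
        curve = pmod.run_deposition_study(
            network,
            net_flow,
            config.particle_sizes_um,
            config.particles_per_size,
            rho_p=config.particle_density,
            seed=config.seed,
        )
        _write_csv(curve, outdir / "deposition_curve.csv", prov_header)
        bundle["deposition_curve"] = curve

    run_stage("flow", stage_flow)
    run_stage("uptake", stage_uptake)
    run_stage("gc", stage_gc)
    run_stage("particles", stage_particles)

    manifest["provenance"] = {
        "config": {
            k: (v if not dataclasses.is_dataclass(v) else dataclasses.asdict(v))
            for k, v in dataclasses.asdict(config).items()
        },
        "calibration": network.calibration_report,
        "flow_rate_ml_min": config.flow_rate_ml_min,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle
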