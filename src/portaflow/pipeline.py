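"""Longitudinal study orchestration: geometry → mesh → solve → metrics.

``run_timepoint`` executes one timepoint end to end and writes its artifacts
(mesh + fields VTU, monitor/residual CSV, report JSON, resolved config);
``run_longitudinal`` runs the configured timepoints and assembles per-metric
trajectories with percent changes; ``grid_independence`` runs a mesh-size
ladder and flags the first consecutive pair whose indicators (max velocity,
trans-stenotic gradient, max WSS) all differ by less than 1%;
``compare_to_reference`` tabulates computed metrics against the clinical /
3D-simulation reference values — informative only, never a gate.

Everything is deterministic: zero-field initial guesses, no randomness, and
fixed float formatting in the CSV writers, so repeated runs produce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import metrics as met
from . import network as net
from . import windkessel as wk
from .geometry import (BoundaryLayerSpec, VesselTimepointSpec, build_axisymmetric_profile,
                       build_mesh, make_timepoint_spec, MM)
from .geometry_io import write_vtu_fields, export_mesh
from .rheology import CarreauYasudaParams, FluidProps, reynolds_number
from .solver import SolverConfig, inlet_profile, solve_steady

__all__ = [
    "StudyConfig",
    "GridStudyResult",
    "run_timepoint",
    "run_longitudinal",
    "grid_independence",
    "compare_to_reference",
    "build_fluid",
    "build_network",
]

GRID_CRITERION_PCT = 1.0   # grid-independence threshold on consecutive diffs


@dataclass
class StudyConfig:
    """Resolved study configuration (SI units internally; YAML takes mm)."""

    timepoints: list = field(default_factory=lambda: ["preop", "week1", "month6"])
    max_cell_size: float = 0.65 * MM
    boundary_layer: BoundaryLayerSpec = field(default_factory=BoundaryLayerSpec)
    n_profile_samples: int = 200
    geometry_overrides: dict = field(default_factory=dict)   # spec field -> SI value
    fluid: FluidProps = field(default_factory=FluidProps)
    outlets: dict = field(default_factory=lambda: dict(wk.DEFAULT_OUTLETS))
    solver: SolverConfig = field(default_factory=SolverConfig)
    grid_sizes: list = field(default_factory=lambda: [s * MM for s in (0.85, 0.75, 0.65, 0.60)])
    expansion_coefficient: float = 1.0
    inlet_kind: str = "parabolic"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.timepoints:
            raise ValueError("at least one timepoint is required")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        kw: dict = {}
        if "timepoints" in raw:
            kw["timepoints"] = list(raw["timepoints"])
        geo = raw.get("geometry", {})
        if "max_cell_size" in geo:
            kw["max_cell_size"] = float(geo["max_cell_size"]) * MM
        if "boundary_layer" in geo:
            b = geo["boundary_layer"]
            kw["boundary_layer"] = BoundaryLayerSpec(
                first_layer_height=float(b.get("first_layer_height", 0.065)) * MM,
                growth_rate=float(b.get("growth_rate", 1.2)),
                n_layers=int(b.get("n_layers", 5)))
        if "n_samples" in geo:
            kw["n_profile_samples"] = int(geo["n_samples"])
        if "overrides" in geo:
            kw["geometry_overrides"] = {k: float(v) * MM
                                        for k, v in geo["overrides"].items()}
        if "fluid" in raw:
            kw["fluid"] = build_fluid(raw["fluid"])
        if "outlets" in raw:
            kw["outlets"] = {
                tag: wk.WK3Params(Rc=float(p["Rc"]), Rd=float(p["Rd"]),
                                  C=float(p["C"]), Pd=float(p.get("Pd", 0.0)))
                for tag, p in raw["outlets"].items()}
        if "solver" in raw:
            s = raw["solver"]
            defaults = SolverConfig()
            kw["solver"] = SolverConfig(
                dt=float(s.get("dt", defaults.dt)),
                max_steps=int(s.get("max_steps", defaults.max_steps)),
                residual_tol=float(s.get("residual_tol", defaults.residual_tol)),
                monitor_window=int(s.get("monitor_window", defaults.monitor_window)),
                monitor_tol=float(s.get("monitor_tol", defaults.monitor_tol)),
                wk3_coupling=s.get("wk3_coupling", defaults.wk3_coupling))
        if "grid_study" in raw and "sizes" in raw["grid_study"]:
            kw["grid_sizes"] = [float(s) * MM for s in raw["grid_study"]["sizes"]]
        if "network" in raw:
            kw["expansion_coefficient"] = float(
                raw["network"].get("expansion_coefficient", 1.0))
        if "inlet" in raw:
            kw["inlet_kind"] = raw["inlet"].get("profile", "parabolic")
        if "out_dir" in raw:
            kw["out_dir"] = raw["out_dir"]
        return cls(**kw)

    def resolved_dict(self) -> dict:
        """Plain-serializable snapshot written next to every output."""
        fl = self.fluid
        rhe = (dataclasses.asdict(fl.rheology)
               if isinstance(fl.rheology, CarreauYasudaParams)
               else {"mu": float(fl.rheology)})
        return {
            "timepoints": list(self.timepoints),
            "geometry": {"max_cell_size_mm": self.max_cell_size / MM,
                         "boundary_layer": dataclasses.asdict(self.boundary_layer),
                         "n_samples": self.n_profile_samples,
                         "overrides_m": self.geometry_overrides},
            "fluid": {"density": fl.density, "rheology": rhe},
            "outlets": {t: dataclasses.asdict(p) for t, p in self.outlets.items()},
            "solver": dataclasses.asdict(self.solver),
            "grid_sizes_mm": [s / MM for s in self.grid_sizes],
            "network": {"expansion_coefficient": self.expansion_coefficient},
            "inlet": {"profile": self.inlet_kind},
        }


def build_fluid(raw: dict) -> FluidProps:
    """Build FluidProps from a ``fluid:`` config block."""
    density = float(raw.get("density", 1060.0))
    model = raw.get("model", "carreau_yasuda")
    if model == "newtonian":
        return FluidProps(density=density, rheology=float(raw.get("mu", 0.0035)))
    if model != "carreau_yasuda":
        raise ValueError(f"unknown rheology model {model!r}; "
                         "use 'carreau_yasuda' or 'newtonian'")
    cy = CarreauYasudaParams(
        mu0=float(raw.get("mu0", 0.056)),
        mu_inf=float(raw.get("mu_inf", 0.00345)),
        lam=float(raw.get("lambda", raw.get("lam", 3.313))),
        a=float(raw.get("a", 2.0)),
        n=float(raw.get("n", 0.3568)))
    return FluidProps(density=density, rheology=cy)


def _spec_for(label: str, config: StudyConfig) -> VesselTimepointSpec:
    spec = make_timepoint_spec(label)
    if config.geometry_overrides:
        spec = dataclasses.replace(spec, **config.geometry_overrides)
    return spec


def build_network(spec: VesselTimepointSpec, config: StudyConfig,
                  profile=None) -> net.BifurcationNetwork:
    """0D network for a timepoint: trunk + stenosis element + two branches."""
    if profile is None:
        profile = build_axisymmetric_profile(spec, config.n_profile_samples)
    a_throat = np.pi * (spec.throat_diameter / 2.0) ** 2
    a_ref = np.pi * (spec.downstream_trunk_diameter / 2.0) ** 2
    trunk = net.Segment(length=profile.length, profile=profile)
    r_visc = net.segment_resistance(trunk, config.fluid.mu_inf)
    stenosis = net.StenosisElement(
        throat_area=a_throat, reference_area=a_ref,
        viscous_resistance=r_visc,
        expansion_coefficient=config.expansion_coefficient)
    branches = {
        "RAPV": net.Segment(length=spec.branch_lengths[0],
                            radius=spec.branch_diameters[0] / 2.0),
        "RPPV": net.Segment(length=spec.branch_lengths[1],
                            radius=spec.branch_diameters[1] / 2.0),
    }
    terminals = {t: config.outlets[t] for t in branches}
    return net.BifurcationNetwork(trunk=None, branches=branches,
                                  terminals=terminals, stenosis=stenosis)


def run_timepoint(label: str, config: StudyConfig,
                  out_dir: str | None = None) -> met.HemodynamicReport:
    """Simulate one timepoint and assemble its clinical report.

    Artifacts (mesh+fields VTU, STL surface, monitors CSV, report JSON,
    resolved config YAML) are written under ``out_dir/<label>/`` when an
    output directory is given.  Non-convergence raises after writing the
    partial artifacts, with the last residual in the message.
    """
    spec = _spec_for(label, config)
    profile = build_axisymmetric_profile(spec, config.n_profile_samples)
    mesh = build_mesh(profile, config.max_cell_size, config.boundary_layer)
    inlet = inlet_profile(spec.inlet_peak_velocity, spec.inlet_diameter / 2.0,
                          config.inlet_kind)
    wk_eq = wk.parallel_equivalent([config.outlets[t] for t in sorted(config.outlets)])
    field_ = solve_steady(mesh, config.fluid, inlet, wk_eq, config.solver)

    # 0D branch split driven by the computed trunk flow
    network = build_network(spec, config, profile)
    sol = net.solve_network(field_.outlet_flux, network, fluid=config.fluid)

    v_max = float(field_.speed.max())
    re_max = reynolds_number(config.fluid.density, v_max, spec.throat_diameter,
                             config.fluid.mu_inf) if v_max > 0 else 0.0
    report = met.build_report(label, field_, branch_flows=sol.branch_flows,
                              reynolds_max=re_max)

    if out_dir is not None:
        d = os.path.join(out_dir, label)
        os.makedirs(d, exist_ok=True)
        _write_artifacts(d, config, mesh, field_, report)
    if not field_.converged:
        raise RuntimeError(
            f"timepoint {label!r} did not converge within "
            f"{config.solver.max_steps} steps (last residual "
            f"{field_.residual_history[-1]:.3e}); partial artifacts kept")
    return report


def _write_artifacts(d, config, mesh, field_, report):
    write_vtu_fields(
        mesh, os.path.join(d, "fields.vtu"),
        point_data={"velocity": np.column_stack(
            [field_.velocity[:, 1], field_.velocity[:, 0], np.zeros(len(field_.velocity))]),
            "pressure": field_.pressure},
        cell_data={})
    export_mesh(mesh, os.path.join(d, "mesh.vtu"))
    export_mesh(mesh, os.path.join(d, "surface.stl"))
    mon = pd.DataFrame({
        "step": np.arange(1, len(field_.residual_history) + 1),
        "residual": field_.residual_history,
        "outlet_flow_m3_s": field_.monitors["outlet_flow"],
        "outlet_pressure_pa": field_.monitors["outlet_pressure"]})
    mon.to_csv(os.path.join(d, "monitors.csv"), index=False, float_format="%.12g")
    report.to_json(os.path.join(d, "report.json"))
    with open(os.path.join(d, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.resolved_dict(), fh, sort_keys=True)


TRACKED_METRICS = ("pvv_ratio", "trans_stenotic_gradient", "wss_max_stenotic",
                   "peak_velocity_stenotic", "branch_flow_ratio")


def run_longitudinal(config: StudyConfig, out_dir: str | None = None):
    """Run every configured timepoint and build per-metric trajectories.

    Returns ``(reports, comparisons)``: reports maps timepoint -> report;
    comparisons maps metric name -> :class:`LongitudinalComparison` with the
    consecutive percent changes.  Requires >= 2 timepoints.
    """
    if len(config.timepoints) < 2:
        raise ValueError("longitudinal analysis needs at least two timepoints")
    out_dir = out_dir if out_dir is not None else config.out_dir
    reports = {}
    for label in config.timepoints:
        reports[label] = run_timepoint(label, config, out_dir)

    comparisons = {}
    for metric in TRACKED_METRICS:
        values = {}
        for label, rep in reports.items():
            if metric == "pvv_ratio":
                values[label] = rep.pvv_ratio
            elif metric == "trans_stenotic_gradient":
                values[label] = rep.trans_stenotic_gradient
            elif metric == "wss_max_stenotic":
                values[label] = rep.wss_max["stenotic"]
            elif metric == "peak_velocity_stenotic":
                values[label] = rep.peak_velocity["stenotic"]
            elif metric == "branch_flow_ratio":
                if rep.branch_flow_ratio is None:
                    continue
                values[label] = rep.branch_flow_ratio
        if len(values) == len(reports):
            comparisons[metric] = met.LongitudinalComparison.from_values(metric, values)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        met.write_reports_csv(reports, os.path.join(out_dir, "reports.csv"))
        rows = []
        for m, comp in comparisons.items():
            for k, v in comp.percent_changes.items():
                rows.append({"metric": m, "interval": k, "percent_change": v})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "percent_changes.csv"),
                                  index=False, float_format="%.10g")
    return reports, comparisons


@dataclass
class GridStudyResult:
    """Mesh-size ladder with the three indicators and consecutive differences."""

    sizes: list                      # m, strictly decreasing
    cell_counts: list
    max_velocity: list               # m/s
    gradient: list                   # Pa
    max_wss: list                    # Pa
    converged: list
    pairwise_diff_pct: pd.DataFrame = None   # rows: size pairs
    independent_at: tuple | None = None      # first pair meeting the criterion

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size_mm": [s / MM for s in self.sizes],
            "cells": self.cell_counts,
            "max_velocity_m_s": self.max_velocity,
            "gradient_pa": self.gradient,
            "max_wss_pa": self.max_wss,
            "converged": self.converged})


def grid_independence(config: StudyConfig, sizes=None,
                      spec: VesselTimepointSpec | None = None,
                      out_dir: str | None = None,
                      scale_boundary_layer: bool = False) -> GridStudyResult:
    """Run the indicator triple over a strictly decreasing mesh-size ladder.

    Indicators per size: cell count, maximum velocity magnitude,
    trans-stenotic (plane-to-plane) pressure gradient, maximum WSS.
    Flags the first consecutive pair with all relative differences < 1%.
    A size failing to converge is flagged and the study continues.

    With ``scale_boundary_layer`` the wall-layer first height scales with the
    mesh size (relative to the coarsest size), so the whole mesh refines
    uniformly — the Richardson-style mode used for closed-form verification
    ladders.  The default keeps the clinical fixed boundary layer.
    """
    sizes = list(sizes if sizes is not None else config.grid_sizes)
    if len(sizes) < 2:
        raise ValueError("grid study needs at least two mesh sizes")
    if any(b >= a for a, b in zip(sizes[:-1], sizes[1:])):
        raise ValueError("mesh sizes must be strictly decreasing")
    if spec is None:
        spec = _spec_for(config.timepoints[0], config)
    profile = build_axisymmetric_profile(spec, config.n_profile_samples)
    inlet = inlet_profile(spec.inlet_peak_velocity, spec.inlet_diameter / 2.0,
                          config.inlet_kind)
    wk_eq = wk.parallel_equivalent([config.outlets[t] for t in sorted(config.outlets)])

    counts, vmax, grad, wssm, conv = [], [], [], [], []
    for h in sizes:
        bl = config.boundary_layer
        if scale_boundary_layer:
            bl = dataclasses.replace(
                bl, first_layer_height=bl.first_layer_height * h / sizes[0])
        mesh = build_mesh(profile, h, bl)
        field_ = solve_steady(mesh, config.fluid, inlet, wk_eq, config.solver)
        rep = met.build_report(spec.label, field_)
        counts.append(mesh.n_cells)
        vmax.append(float(field_.speed.max()))
        grad.append(rep.trans_stenotic_gradient)
        wssm.append(float(field_.wall_shear.max()))
        conv.append(bool(field_.converged))

    rows = []
    independent_at = None
    for k in range(len(sizes) - 1):
        diffs = {
            "max_velocity": _rel_pct(vmax[k], vmax[k + 1]),
            "gradient": _rel_pct(grad[k], grad[k + 1]),
            "max_wss": _rel_pct(wssm[k], wssm[k + 1]),
        }
        ok = all(v < GRID_CRITERION_PCT for v in diffs.values()) \
            and conv[k] and conv[k + 1]
        rows.append({"coarse_mm": sizes[k] / MM, "fine_mm": sizes[k + 1] / MM,
                     **{f"{n}_diff_pct": v for n, v in diffs.items()},
                     "grid_independent": ok})
        if ok and independent_at is None:
            independent_at = (sizes[k], sizes[k + 1])

    result = GridStudyResult(
        sizes=sizes, cell_counts=counts, max_velocity=vmax, gradient=grad,
        max_wss=wssm, converged=conv,
        pairwise_diff_pct=pd.DataFrame(rows), independent_at=independent_at)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        result.to_frame().to_csv(os.path.join(out_dir, "grid_study.csv"),
                                 index=False, float_format="%.10g")
        result.pairwise_diff_pct.to_csv(os.path.join(out_dir, "grid_diffs.csv"),
                                        index=False, float_format="%.10g")
    return result


def _rel_pct(a: float, b: float) -> float:
    denom = max(abs(a), abs(b), 1e-300)
    return 100.0 * abs(a - b) / denom


_REF_MAP = {
    # report accessor -> (reference metric, scale from report SI to ref units)
    "peak_velocity_stenotic": ("peak_velocity_stenotic", 100.0),
    "peak_velocity_prestenotic": ("peak_velocity_prestenotic", 100.0),
    "pvv_ratio": ("pvv_ratio", 1.0),
    "trans_stenotic_gradient": ("trans_stenotic_gradient", 1.0),
    "wss_max_stenotic": ("wss_max_stenotic", 1.0),
    "wss_ratio": ("wss_ratio", 1.0),
    "branch_flow_RAPV": ("branch_flow_anterior", 6e7),
    "branch_flow_RPPV": ("branch_flow_posterior", 6e7),
    "branch_flow_ratio": ("branch_flow_ratio", 1.0),
}


def compare_to_reference(reports: dict, out_path=None) -> pd.DataFrame:
    """Side-by-side table of computed metrics vs the case reference values.

    Purely informative: the idealized geometry is not expected to reproduce
    the patient-specific 3D absolutes; relative deviations are reported, and
    a timepoint absent from ``reports`` yields rows marked absent rather
    than an error.
    """
    ref = met.load_reference_table()
    rows = []
    for tp in ("preop", "week1", "month6"):
        rep = reports.get(tp)
        for key, (ref_metric, scale) in _REF_MAP.items():
            sel = ref[(ref.timepoint == tp) & (ref.metric == ref_metric)
                      & (ref.source == "simulation_3d")]
            if sel.empty:
                continue
            ref_val = float(sel.value.iloc[0])
            units = sel.units.iloc[0]
            if rep is None:
                rows.append({"timepoint": tp, "metric": key, "computed": np.nan,
                             "reference": ref_val, "units": units,
                             "deviation_pct": np.nan, "status": "absent"})
                continue
            val = _report_value(rep, key)
            if val is None:
                continue
            val *= scale
            dev = _rel_pct(val, ref_val) * np.sign(val - ref_val) \
                if ref_val != 0 else np.nan
            rows.append({"timepoint": tp, "metric": key, "computed": val,
                         "reference": ref_val, "units": units,
                         "deviation_pct": 100.0 * (val - ref_val) / ref_val,
                         "status": "ok"})
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False, float_format="%.10g")
    return df


def _report_value(rep: met.HemodynamicReport, key: str):
    if key.startswith("peak_velocity_"):
        region = {"stenotic": "stenotic", "prestenotic": "pre_stenotic"}[
            key.split("_", 2)[2]]
        return rep.peak_velocity[region]
    if key == "pvv_ratio":
        return rep.pvv_ratio
    if key == "trans_stenotic_gradient":
        return rep.trans_stenotic_gradient
    if key == "wss_max_stenotic":
        return rep.wss_max["stenotic"]
    if key == "wss_ratio":
        return rep.wss_ratio
    if key.startswith("branch_flow_"):
        tag = key.split("_", 2)[2]
        if tag == "ratio":
            return rep.branch_flow_ratio
        return rep.branch_flows.get(tag)
    return None
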