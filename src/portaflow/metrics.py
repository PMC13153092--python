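"""Clinical hemodynamic indices and per-timepoint reports.

The quantities a clinician tracks across the angioplasty timeline:

* **PVV ratio** — peak portal venous velocity at the stenotic site divided by
  the pre-stenotic (upstream) peak; the standard Doppler severity marker.
* **Trans-stenotic pressure gradient** — difference of the cross-sectional
  area-averaged pressures on planes upstream and downstream of the stenosis
  (reported in Pa and mmHg; 1 mmHg = 133.322 Pa).
* **WSS extrema and ratio** — maximum wall shear stress per region and the
  post-stenotic/pre-stenotic maximum ratio.
* **Branch flow ratio** — right anterior / right posterior branch flow.
* **Percent reduction** between consecutive timepoints,
  100*(earlier - later)/earlier.

Probe planes default to: pre-stenotic at the axial position of maximum
radius (nearest the stenosis), stenotic at the throat, post-stenotic one
throat-diameter downstream of the stenosis exit — all configurable.  "Peak
velocity" in a region is the maximum velocity magnitude over the region's
cross-sections (Doppler peak semantics); WSS maxima are taken over the wall
surface.  Region extents are recorded in every report for auditability.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import VolumeMesh
from .solver import FlowField

__all__ = [
    "MMHG_PA",
    "ProbePlane",
    "HemodynamicReport",
    "LongitudinalComparison",
    "area_averaged_pressure",
    "pvv_ratio",
    "wss_ratio",
    "percent_reduction",
    "flow_ratio",
    "pa_to_mmhg",
    "mmhg_to_pa",
    "region_peak_velocity",
    "region_max_wss",
    "build_report",
    "load_reference_table",
]

#: Pascals per millimetre of mercury.
MMHG_PA = 133.322

REGIONS = ("pre_stenotic", "stenotic", "post_stenotic")


@dataclass(frozen=True)
class ProbePlane:
    """A cross-sectional sampling plane at axial position z (m)."""

    z: float
    region_label: str = "stenotic"

    def __post_init__(self) -> None:
        if self.region_label not in REGIONS:
            raise ValueError(f"region_label must be one of {REGIONS}")


def pa_to_mmhg(p: float) -> float:
    """Convert pressure from Pa to mmHg (p / 133.322)."""
    return p / MMHG_PA


def mmhg_to_pa(p: float) -> float:
    """Convert pressure from mmHg to Pa."""
    return p * MMHG_PA


def pvv_ratio(stenotic_peak: float, prestenotic_peak: float) -> float:
    """Peak-velocity ratio stenotic/upstream (dimensionless severity index)."""
    if prestenotic_peak == 0.0:
        raise ZeroDivisionError("pre-stenotic peak velocity must be nonzero")
    return stenotic_peak / prestenotic_peak


def wss_ratio(post_max: float, pre_max: float) -> float:
    """WSS ratio: post-stenotic maximum / pre-stenotic maximum."""
    if pre_max == 0.0:
        raise ZeroDivisionError("pre-stenotic WSS maximum must be nonzero")
    return post_max / pre_max


def percent_reduction(earlier: float, later: float) -> float:
    """Percent change 100*(earlier - later)/earlier (positive = reduction)."""
    if earlier == 0.0:
        raise ZeroDivisionError("earlier value must be nonzero")
    return 100.0 * (earlier - later) / earlier


def flow_ratio(anterior: float, posterior: float) -> float:
    """Branch flow ratio: right anterior / right posterior."""
    if posterior == 0.0:
        raise ZeroDivisionError("posterior branch flow must be nonzero")
    return anterior / posterior


# ------------------------------------------------------------- field probes

def _plane_column(mesh: VolumeMesh, z: float):
    zg = mesh.z[:, 0]
    if not (zg[0] <= z <= zg[-1]):
        raise ValueError(f"plane z={z:.6g} m lies outside the mesh "
                         f"[{zg[0]:.6g}, {zg[-1]:.6g}] m")
    zc = 0.5 * (zg[:-1] + zg[1:])
    # columns whose centroids straddle the plane; linear extrapolation from
    # the outermost centroid pair when the plane sits in a boundary half-cell
    i1 = int(np.clip(np.searchsorted(zc, z), 1, len(zc) - 1))
    i0 = i1 - 1
    w = (z - zc[i0]) / (zc[i1] - zc[i0])
    return i0, i1, w


def area_averaged_pressure(field: FlowField, plane: ProbePlane) -> float:
    """Cross-sectional area-averaged pressure int p dA / int dA at plane.z.

    The axisymmetric area weighting (2*pi*r factor) is applied per radial
    ring; pressures are interpolated axially between the neighbouring cell
    columns.
    """
    mesh = field.mesh
    i0, i1, w = _plane_column(mesh, plane.z)
    p = (1.0 - w) * field.cell_pressure[i0] + w * field.cell_pressure[i1]
    # radial node line at the plane, interpolated between the stations
    zg = mesh.z[:, 0]
    js = int(np.clip(np.searchsorted(zg, plane.z), 1, len(zg) - 1))
    ws = (plane.z - zg[js - 1]) / (zg[js] - zg[js - 1])
    r_plane = (1.0 - ws) * mesh.r[js - 1] + ws * mesh.r[js]
    ring_area = np.pi * (r_plane[1:] ** 2 - r_plane[:-1] ** 2)
    return float(np.sum(p * ring_area) / np.sum(ring_area))


def _region_mask_columns(mesh: VolumeMesh, z_range) -> np.ndarray:
    zg = mesh.z[:, 0]
    zc = 0.5 * (zg[:-1] + zg[1:])
    z0, z1 = z_range
    return (zc >= z0) & (zc <= z1)


def region_peak_velocity(field: FlowField, z_range) -> float:
    """Maximum velocity magnitude (m/s) over the cross-sections in z_range."""
    cols = _region_mask_columns(field.mesh, z_range)
    if not cols.any():
        raise ValueError("region contains no mesh columns")
    return float(field.speed[cols].max())


def region_max_wss(field: FlowField, z_range) -> float:
    """Maximum wall shear stress (Pa) over wall facets in z_range."""
    cols = _region_mask_columns(field.mesh, z_range)
    if not cols.any():
        raise ValueError("region contains no mesh columns")
    return float(field.wall_shear[cols].max())


# ------------------------------------------------------------- reports

@dataclass
class HemodynamicReport:
    """Per-timepoint clinical metric bundle.

    Invariants hold by construction: pvv_ratio = stenotic/pre-stenotic peak,
    wss_ratio = post-stenotic/pre-stenotic WSS maximum, gradient = pre-plane
    minus post-plane area-averaged pressure.
    """

    timepoint: str
    peak_velocity: dict               # region -> m/s
    pvv_ratio: float
    plane_pressures: dict             # plane label -> Pa
    trans_stenotic_gradient: float    # Pa
    trans_stenotic_gradient_mmhg: float
    wss_max: dict                     # region -> Pa
    wss_ratio: float
    branch_flows: dict                # tag -> m^3/s
    branch_flow_ratio: float | None
    regions: dict = field(default_factory=dict)   # region -> (z0, z1) m
    inlet_flow: float = 0.0           # m^3/s
    converged: bool = True
    mass_error: float = 0.0
    reynolds_max: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def rows(self):
        """Flat (metric, value) rows for CSV output."""
        out = [("pvv_ratio", self.pvv_ratio),
               ("trans_stenotic_gradient_pa", self.trans_stenotic_gradient),
               ("trans_stenotic_gradient_mmhg", self.trans_stenotic_gradient_mmhg),
               ("wss_ratio", self.wss_ratio),
               ("inlet_flow_ml_min", self.inlet_flow * 6e7),
               ("mass_error", self.mass_error),
               ("reynolds_max", self.reynolds_max)]
        for region, v in self.peak_velocity.items():
            out.append((f"peak_velocity_{region}_cm_s", v * 100.0))
        for region, v in self.wss_max.items():
            out.append((f"wss_max_{region}_pa", v))
        for tag, q in self.branch_flows.items():
            out.append((f"branch_flow_{tag}_ml_min", q * 6e7))
        if self.branch_flow_ratio is not None:
            out.append(("branch_flow_ratio", self.branch_flow_ratio))
        return out


def build_report(
    timepoint: str,
    field_: FlowField,
    *,
    branch_flows: dict | None = None,
    branch_ratio_tags: tuple[str, str] = ("RAPV", "RPPV"),
    reynolds_max: float = 0.0,
) -> HemodynamicReport:
    """Assemble the clinical metric bundle from a converged flow field.

    Probe-plane and region placement comes from the mesh profile's recorded
    features (see :mod:`portaflow.geometry`).
    """
    mesh = field_.mesh
    if mesh.profile is None or not mesh.profile.features:
        raise ValueError("mesh carries no profile features for plane placement")
    feats = mesh.profile.features

    regions = {r: tuple(feats[r]) for r in REGIONS}
    peaks = {r: region_peak_velocity(field_, regions[r]) for r in REGIONS}
    wssm = {r: region_max_wss(field_, regions[r]) for r in REGIONS}

    z_pre = feats["max_radius_z"]
    z_post = min(feats["stenosis_exit_z"] + feats["throat_diameter"],
                 float(mesh.z[-1, 0]))
    p_pre = area_averaged_pressure(field_, ProbePlane(z_pre, "pre_stenotic"))
    p_post = area_averaged_pressure(field_, ProbePlane(z_post, "post_stenotic"))
    p_throat = area_averaged_pressure(field_, ProbePlane(feats["throat_z"], "stenotic"))
    gradient = p_pre - p_post

    ratio = None
    if branch_flows and all(t in branch_flows for t in branch_ratio_tags):
        ratio = flow_ratio(branch_flows[branch_ratio_tags[0]],
                           branch_flows[branch_ratio_tags[1]])

    return HemodynamicReport(
        timepoint=timepoint,
        peak_velocity=peaks,
        pvv_ratio=pvv_ratio(peaks["stenotic"], peaks["pre_stenotic"]),
        plane_pressures={"pre_stenotic": p_pre, "stenotic": p_throat,
                         "post_stenotic": p_post},
        trans_stenotic_gradient=gradient,
        trans_stenotic_gradient_mmhg=pa_to_mmhg(gradient),
        wss_max=wssm,
        wss_ratio=wss_ratio(wssm["post_stenotic"], wssm["pre_stenotic"]),
        branch_flows=branch_flows or {},
        branch_flow_ratio=ratio,
        regions=regions,
        inlet_flow=field_.inlet_flux,
        converged=field_.converged,
        mass_error=field_.mass_error,
        reynolds_max=reynolds_max,
    )


@dataclass
class LongitudinalComparison:
    """One metric tracked across timepoints with consecutive percent changes."""

    metric: str
    values: dict                      # timepoint -> value
    percent_changes: dict             # "a->b" -> percent reduction

    @classmethod
    def from_values(cls, metric: str, values: dict) -> "LongitudinalComparison":
        labels = list(values)
        changes = {}
        for a, b in zip(labels[:-1], labels[1:]):
            if values[a] != 0:
                changes[f"{a}->{b}"] = percent_reduction(values[a], values[b])
        return cls(metric=metric, values=dict(values), percent_changes=changes)


def reports_to_frame(reports: dict) -> pd.DataFrame:
    """Stack per-timepoint report rows into a tidy (timepoint, metric, value) frame."""
    rows = []
    for label, rep in reports.items():
        for metric, value in rep.rows():
            rows.append({"timepoint": label, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def write_reports_csv(reports: dict, path) -> None:
    reports_to_frame(reports).to_csv(path, index=False, float_format="%.10g")


# ------------------------------------------------------------- reference data

def load_reference_table() -> pd.DataFrame:
    """Clinical and simulated reference values of the modeled case.

    Columns: timepoint, metric, value, units, source (doppler / catheter /
    simulation_3d).  These are the values the presets encode and the
    comparison tables are measured against; they are informative references,
    never test gates for the idealized-geometry simulation.
    """
    ref = importlib.resources.files("portaflow.data").joinpath("reference_values.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_value(df: pd.DataFrame, timepoint: str, metric: str) -> float:
    sel = df[(df.timepoint == timepoint) & (df.metric == metric)]
    if len(sel) != 1:
        raise KeyError(f"reference ({timepoint}, {metric}) not found or ambiguous")
    return float(sel.value.iloc[0])
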