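"""Parametric stenosed portal-vein geometry and axisymmetric meshing.

The patient lumen is idealized as an axisymmetric profile: an optional cosine
dilation ramp from the inlet bore to the pre-stenotic maximum, a plateau, a
cosine constriction down to the anastomotic throat, a cosine recovery to the
downstream trunk, and a straight trunk run.  Cosine segments make the radius
function C¹ everywhere with the minimum radius attained exactly at the throat.

Three timepoint presets carry the dimensions and Doppler peak velocities of
the modeled clinical case (pre-angioplasty, 1 week and 6 months after):

=======  ========  ============  ======  ===========
label    throat    pre-stenotic  trunk   inlet peak
=======  ========  ============  ======  ===========
preop    5.1 mm    15.2 mm       8.8 mm  13.45 cm/s
week1    8.0 mm    12.0 mm       8.8 mm  13.32 cm/s
month6   8.0 mm    11.0 mm       8.8 mm  15.13 cm/s
=======  ========  ============  ======  ===========

The inlet plane is placed at the pre-stenotic segment (inlet bore equal to the
pre-stenotic maximum), so the Doppler peak velocity is imposed on the section
where it was measured.  Branch maximum diameters are fixed at 5.0 mm (right
anterior) and 7.3 mm (right posterior); branch lengths default to 30 mm (not
clinically measured — placeholders, flagged in config).

The mesh is a structured quadrilateral grid in (r, z): uniform axial stations,
and per-station radial nodes with a geometric-progression boundary layer at
the wall (default first layer 0.065 mm, growth rate 1.2, five layers) and a
near-uniform interior.  Coordinates are SI meters internally; configs accept
millimetres and convert once at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "VesselTimepointSpec",
    "AxisymmetricProfile",
    "BoundaryLayerSpec",
    "VolumeMesh",
    "TIMEPOINT_LABELS",
    "make_timepoint_spec",
    "build_axisymmetric_profile",
    "build_mesh",
    "boundary_layer_total_thickness",
    "estimate_yplus",
]

MM = 1e-3  # metres per millimetre

TIMEPOINT_LABELS = ("preop", "week1", "month6")

BOUNDARY_TAGS = ("inlet", "outlet", "wall", "axis")


@dataclass(frozen=True)
class VesselTimepointSpec:
    """Printed geometric and Doppler parameters for one study timepoint (SI units)."""

    label: str
    inlet_diameter: float
    prestenotic_max_diameter: float
    throat_diameter: float
    stenosis_length: float
    downstream_trunk_diameter: float
    branch_diameters: tuple[float, float]   # (anterior, posterior)
    branch_lengths: tuple[float, float]
    inlet_peak_velocity: float
    total_length: float = 60.0 * MM

    def __post_init__(self) -> None:
        lengths = (
            self.inlet_diameter, self.prestenotic_max_diameter, self.throat_diameter,
            self.stenosis_length, self.downstream_trunk_diameter, self.total_length,
            *self.branch_diameters, *self.branch_lengths,
        )
        if any(x <= 0.0 for x in lengths):
            raise ValueError("all lengths must be > 0")
        if self.throat_diameter > self.prestenotic_max_diameter:
            raise ValueError("throat_diameter must be < prestenotic_max_diameter "
                             "(no stenosis otherwise; use equal diameters for a straight tube)")
        if self.throat_diameter > self.downstream_trunk_diameter:
            raise ValueError("throat_diameter must be <= downstream_trunk_diameter")
        if self.inlet_peak_velocity <= 0.0:
            raise ValueError("inlet_peak_velocity must be > 0")

    @property
    def area_contraction_ratio(self) -> float:
        """(pre-stenotic / throat) area ratio = plug-flow velocity amplification."""
        return (self.prestenotic_max_diameter / self.throat_diameter) ** 2


_PRESETS: dict[str, dict] = {
    # Pre-angioplasty: throat 5.1 mm, pre-stenotic dilatation 15.2 mm,
    # pre-stenotic Doppler peak 13.45 cm/s.
    "preop": dict(prestenotic=15.2 * MM, throat=5.1 * MM, peak_velocity=0.1345),
    # 1 week post: throat dilated to 8 mm, pre-stenotic 12 mm, Doppler 13.32 cm/s.
    "week1": dict(prestenotic=12.0 * MM, throat=8.0 * MM, peak_velocity=0.1332),
    # 6 months: pre-stenotic normalized to 11 mm, Doppler 15.13 cm/s.
    "month6": dict(prestenotic=11.0 * MM, throat=8.0 * MM, peak_velocity=0.1513),
}


def make_timepoint_spec(label: str) -> VesselTimepointSpec:
    """Return the preset :class:`VesselTimepointSpec` for a study timepoint."""
    if label not in _PRESETS:
        raise ValueError(f"unknown timepoint {label!r}; valid labels: {list(TIMEPOINT_LABELS)}")
    p = _PRESETS[label]
    return VesselTimepointSpec(
        label=label,
        inlet_diameter=p["prestenotic"],
        prestenotic_max_diameter=p["prestenotic"],
        throat_diameter=p["throat"],
        stenosis_length=10.0 * MM,
        downstream_trunk_diameter=8.8 * MM,
        branch_diameters=(5.0 * MM, 7.3 * MM),
        branch_lengths=(30.0 * MM, 30.0 * MM),
        inlet_peak_velocity=p["peak_velocity"],
    )


@dataclass(frozen=True)
class AxisymmetricProfile:
    """Sampled lumen radius along the axis, plus the analytic radius function.

    ``features`` records the axial extent of the named regions
    (pre_stenotic / stenotic / post_stenotic) and the throat / maximum-radius
    positions, for metric probe-plane placement.
    """

    z: np.ndarray                      # axial sample positions, m, strictly increasing
    r: np.ndarray                      # lumen radius at each sample, m, > 0
    radius_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False, compare=False)
    features: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        r = np.asarray(self.r, float)
        if z.ndim != 1 or z.size < 2 or not np.all(np.diff(z) > 0):
            raise ValueError("axial samples must be strictly increasing")
        if np.any(r <= 0.0):
            raise ValueError("radius must be > 0 everywhere")

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])

    def radius(self, z):
        """Lumen radius (m) at axial position(s) ``z``."""
        return self.radius_fn(np.asarray(z, float))

    @property
    def area_amplification(self) -> float:
        """(max radius / min radius)^2 — the mass-conservation plug-flow
        velocity amplification across the stenosis; >= 1 whenever a stenosis exists."""
        return float((self.r.max() / self.r.min()) ** 2)


def _cosine_ramp(z, z0, z1, r0, r1):
    """C¹ blend from r0 at z0 to r1 at z1 (zero slope at both ends)."""
    s = (z - z0) / (z1 - z0)
    return r0 + (r1 - r0) * 0.5 * (1.0 - np.cos(np.pi * s))


def build_axisymmetric_profile(
    spec: VesselTimepointSpec,
    n_samples: int = 200,
    *,
    inlet_run: float = 8.0 * MM,
    ramp_length: float = 10.0 * MM,
    plateau_length: float = 6.0 * MM,
) -> AxisymmetricProfile:
    """Construct the idealized lumen profile for one timepoint.

    Segments (z increasing): straight inlet run at the inlet radius; cosine
    ramp to the pre-stenotic maximum (skipped when inlet == pre-stenotic);
    plateau at the maximum; cosine constriction (half the stenosis length)
    down to the throat; cosine recovery (other half) up to the trunk radius;
    straight trunk to the total length.  The sampled points always include the
    segment knots, so the sampled minimum radius equals the throat radius.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50")
    r_in = spec.inlet_diameter / 2.0
    r_pre = spec.prestenotic_max_diameter / 2.0
    r_th = spec.throat_diameter / 2.0
    r_tr = spec.downstream_trunk_diameter / 2.0
    ls = spec.stenosis_length

    same_bore = abs(r_in - r_pre) < 1e-12
    z1 = inlet_run
    z2 = z1 + (0.0 if same_bore else ramp_length)
    z3 = z2 + plateau_length          # constriction starts; last max-radius position
    z4 = z3 + ls / 2.0                # throat
    z5 = z3 + ls                      # stenosis exit
    L = spec.total_length
    if z5 >= L:
        raise ValueError("total_length too short for the requested stenosis layout")

    def radius_fn(z):
        z = np.asarray(z, float)
        out = np.empty_like(z)
        seg1 = z < z2
        out[seg1] = r_in if same_bore else np.where(
            z[seg1] < z1, r_in, _cosine_ramp(z[seg1], z1, z2, r_in, r_pre))
        seg2 = (z >= z2) & (z < z3)
        out[seg2] = r_pre
        seg3 = (z >= z3) & (z < z4)
        out[seg3] = _cosine_ramp(z[seg3], z3, z4, r_pre, r_th)
        seg4 = (z >= z4) & (z < z5)
        out[seg4] = _cosine_ramp(z[seg4], z4, z5, r_th, r_tr)
        out[z >= z5] = r_tr
        return out

    knots = np.array([0.0, z1, z2, z3, z4, z5, L])
    zs = np.unique(np.concatenate([np.linspace(0.0, L, n_samples), knots]))
    rs = radius_fn(zs)

    features = {
        "pre_stenotic": (0.0, z3),
        "stenotic": (z3, z5),
        "post_stenotic": (z5, min(z5 + spec.throat_diameter, L)),
        "throat_z": z4,
        "max_radius_z": z3,           # max-radius position nearest the stenosis
        "stenosis_exit_z": z5,
        "throat_diameter": spec.throat_diameter,
    }
    return AxisymmetricProfile(z=zs, r=rs, radius_fn=radius_fn, features=features)


@dataclass(frozen=True)
class BoundaryLayerSpec:
    """Geometric-progression wall layering: heights h, h*g, ..., h*g^(n-1)."""

    first_layer_height: float = 0.065 * MM
    growth_rate: float = 1.2
    n_layers: int = 5

    def __post_init__(self) -> None:
        if self.first_layer_height <= 0.0:
            raise ValueError("first_layer_height must be > 0")
        if self.growth_rate < 1.0:
            raise ValueError("growth_rate must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")

    @property
    def heights(self) -> np.ndarray:
        """Layer heights from the wall inward (m)."""
        return self.first_layer_height * self.growth_rate ** np.arange(self.n_layers)


def boundary_layer_total_thickness(bl: BoundaryLayerSpec) -> float:
    """Total thickness of the layering: sum h*g^k, k = 0..n-1 (closed form)."""
    h, g, n = bl.first_layer_height, bl.growth_rate, bl.n_layers
    if g == 1.0:
        return h * n
    return h * (g**n - 1.0) / (g - 1.0)


def estimate_yplus(first_layer_height: float, wall_shear: float,
                   density: float, dynamic_viscosity: float) -> float:
    """Dimensionless wall distance y+ of the first cell centroid.

    y+ = y_c * u_tau / nu with friction velocity u_tau = sqrt(tau_w / rho),
    kinematic viscosity nu = mu / rho, and y_c = first_layer_height / 2 (the
    first-cell centroid; the conventional reference point for a cell-centred
    scheme).  Values around 1 indicate a resolved viscous sublayer.
    """
    if min(first_layer_height, wall_shear, density, dynamic_viscosity) <= 0.0:
        raise ValueError("all arguments must be > 0 (zero wall shear gives an "
                         "undefined friction velocity)")
    u_tau = math.sqrt(wall_shear / density)
    nu = dynamic_viscosity / density
    return 0.5 * first_layer_height * u_tau / nu


@dataclass(frozen=True)
class VolumeMesh:
    """Structured axisymmetric quad mesh with tagged boundaries.

    ``nodes`` holds (r, z) in metres; node (i, j) = axial station i, radial
    index j (j = 0 on the axis, j = n_radial on the wall) is row
    ``i * (n_radial + 1) + j``.  ``cells`` are quads (counter-clockwise in the
    (z, r) plane); ``boundary_tags`` maps each tag to an array of facet node
    pairs.  Every boundary facet carries exactly one tag.
    """

    nodes: np.ndarray                       # (N, 2): columns (r, z)
    cells: np.ndarray                       # (M, 4) int
    boundary_tags: dict                     # tag -> (K, 2) int array
    max_cell_size: float
    n_axial: int                            # number of axial cells
    n_radial: int                           # number of radial cells
    boundary_layer: BoundaryLayerSpec | None = None
    profile: AxisymmetricProfile | None = field(default=None, compare=False)

    def node_index(self, i, j):
        return i * (self.n_radial + 1) + j

    @property
    def n_cells(self) -> int:
        return self.n_axial * self.n_radial

    @property
    def r(self) -> np.ndarray:
        """Radial node coordinates as an (n_axial+1, n_radial+1) grid."""
        return self.nodes[:, 0].reshape(self.n_axial + 1, self.n_radial + 1)

    @property
    def z(self) -> np.ndarray:
        return self.nodes[:, 1].reshape(self.n_axial + 1, self.n_radial + 1)

    def cell_volumes(self) -> np.ndarray:
        """Revolved cell volumes (m^3, full 2*pi), shape (n_axial, n_radial)."""
        a, rc = self._planar_area_and_rc()
        return 2.0 * np.pi * a * rc

    def _planar_area_and_rc(self):
        r, z = self.r, self.z
        # quad corners: (i,j), (i+1,j), (i+1,j+1), (i,j+1)
        zs = np.stack([z[:-1, :-1], z[1:, :-1], z[1:, 1:], z[:-1, 1:]])
        rs = np.stack([r[:-1, :-1], r[1:, :-1], r[1:, 1:], r[:-1, 1:]])
        a = np.zeros(zs.shape[1:])
        sr = np.zeros_like(a)
        for k in range(4):
            zk, rk = zs[k], rs[k]
            zk1, rk1 = zs[(k + 1) % 4], rs[(k + 1) % 4]
            cross = zk * rk1 - zk1 * rk
            a += cross
            sr += (rk + rk1) * cross
        a *= 0.5
        with np.errstate(divide="ignore", invalid="ignore"):
            rc = np.where(np.abs(a) > 0, sr / (6.0 * np.where(a == 0, 1, a)), 0.0)
        return np.abs(a), rc

    def total_volume(self) -> float:
        """Total revolved volume (m^3)."""
        return float(self.cell_volumes().sum())

    def wall_layer_heights(self) -> np.ndarray:
        """Radial heights of the wall-adjacent cell layers at each station,
        shape (n_axial+1, n_layers), wall-adjacent layer first."""
        nb = self.boundary_layer.n_layers if self.boundary_layer else 1
        r = self.r
        heights = -np.diff(r[:, ::-1], axis=1)[:, :nb]
        return heights


def build_mesh(
    profile: AxisymmetricProfile,
    max_cell_size: float,
    bl: BoundaryLayerSpec = BoundaryLayerSpec(),
) -> VolumeMesh:
    """Mesh the revolved profile with a wall boundary layer.

    Axial stations are uniform with spacing <= ``max_cell_size``; at each
    station the radial nodes stack the boundary-layer geometric progression on
    the wall (heights exact) and divide the remaining core uniformly with a
    target spacing of ``max_cell_size``.  The number of radial cells is fixed
    across stations (structured grid), so the core spacing contracts where the
    lumen narrows.
    """
    if max_cell_size <= 0.0:
        raise ValueError("max_cell_size must be > 0")
    if max_cell_size < bl.first_layer_height:
        raise ValueError("max_cell_size smaller than the first boundary-layer height "
                         "gives degenerate layering; refine the boundary layer instead")
    t_bl = boundary_layer_total_thickness(bl)
    r_min = float(profile.r.min())
    if t_bl >= 0.7 * r_min:
        raise ValueError("boundary layer too thick for the narrowest lumen section")

    length = profile.length
    n_ax = max(int(math.ceil(length / max_cell_size)), 4)
    z_stations = np.linspace(profile.z[0], profile.z[-1], n_ax + 1)
    r_wall = profile.radius(z_stations)

    r_max = float(profile.r.max())
    n_core = max(int(math.ceil((r_max - t_bl) / max_cell_size)), 4)
    n_rad = n_core + bl.n_layers

    bl_offsets = np.concatenate([[0.0], np.cumsum(bl.heights)])  # from wall inward
    nodes_r = np.empty((n_ax + 1, n_rad + 1))
    for i, rw in enumerate(r_wall):
        outer = rw - bl_offsets              # wall down to core edge
        core = np.linspace(0.0, outer[-1], n_core + 1)
        nodes_r[i] = np.concatenate([core[:-1], outer[::-1]])
    nodes_z = np.repeat(z_stations[:, None], n_rad + 1, axis=1)

    nodes = np.column_stack([nodes_r.ravel(), nodes_z.ravel()])

    njn = n_rad + 1
    ii, jj = np.meshgrid(np.arange(n_ax), np.arange(n_rad), indexing="ij")
    n00 = ii * njn + jj
    cells = np.column_stack([
        n00.ravel(), (n00 + njn).ravel(), (n00 + njn + 1).ravel(), (n00 + 1).ravel()
    ])

    j_idx = np.arange(n_rad)
    inlet = np.column_stack([j_idx, j_idx + 1])
    outlet = np.column_stack([n_ax * njn + j_idx, n_ax * njn + j_idx + 1])
    i_idx = np.arange(n_ax)
    wall = np.column_stack([i_idx * njn + n_rad, (i_idx + 1) * njn + n_rad])
    axis = np.column_stack([i_idx * njn, (i_idx + 1) * njn])

    return VolumeMesh(
        nodes=nodes,
        cells=cells,
        boundary_tags={"inlet": inlet, "outlet": outlet, "wall": wall, "axis": axis},
        max_cell_size=max_cell_size,
        n_axial=n_ax,
        n_radial=n_rad,
        boundary_layer=bl,
        profile=profile,
    )
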