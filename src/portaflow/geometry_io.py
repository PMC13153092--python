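"""Mesh and field writers/readers: VTU (XML), ASCII STL, Gmsh MSH v4.1 dialect.

All formats are plain text.  VTU stores the planar (z, r) mesh as an
unstructured grid of quads plus boundary line cells carrying an integer
``boundary_tag`` cell array (codes in :data:`TAG_CODES`); the reader
round-trips node coordinates exactly (repr-precision ASCII) and restores the
tag map.  STL revolves the lumen surface (wall plus inlet/outlet caps) into a
closed, watertight triangulation.  The MSH writer emits a minimal Gmsh v4.1
file with physical curve groups for the boundary tags and a physical surface
for the fluid domain; the reader parses that same dialect.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np

from .geometry import VolumeMesh

__all__ = ["export_mesh", "read_vtu", "read_msh", "read_stl", "write_vtu_fields",
           "TAG_CODES", "MESH_FORMATS"]

#: Integer codes for boundary tags stored in VTU/MSH files.
TAG_CODES = {"interior": 0, "inlet": 1, "outlet": 2, "wall": 3, "axis": 4}
_CODE_TAGS = {v: k for k, v in TAG_CODES.items()}

MESH_FORMATS = ("vtu", "stl", "msh")

_FMT = "%.17g"  # round-trips float64 exactly


def export_mesh(mesh: VolumeMesh, path: str | os.PathLike, format: str | None = None) -> str:
    """Write ``mesh`` to ``path`` in one of :data:`MESH_FORMATS`.

    The format is inferred from the file suffix when not given.  Returns the
    path written.
    """
    path = os.fspath(path)
    fmt = format or os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; supported: {MESH_FORMATS}")
    if fmt == "vtu":
        _write_vtu(mesh, path)
    elif fmt == "stl":
        _write_stl(mesh, path)
    else:
        _write_msh(mesh, path)
    return path


# ----------------------------------------------------------------- VTU

def _vtu_doc(points_rz: np.ndarray, cells: list[np.ndarray], cell_types: np.ndarray,
             point_data: dict | None = None, cell_data: dict | None = None) -> ET.Element:
    npts = len(points_rz)
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(npts),
                          NumberOfCells=str(len(cells)))
    pts = ET.SubElement(piece, "Points")
    # VTK points are 3D: (x, y, z) = (z_axial, r, 0)
    xyz = np.column_stack([points_rz[:, 1], points_rz[:, 0], np.zeros(npts)])
    da = ET.SubElement(pts, "DataArray", type="Float64", NumberOfComponents="3",
                       format="ascii")
    da.text = "\n".join(" ".join(_FMT % v for v in row) for row in xyz)

    cellsel = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cellsel, "DataArray", type="Int64", Name="connectivity",
                         format="ascii")
    conn.text = "\n".join(" ".join(str(v) for v in c) for c in cells)
    offs = ET.SubElement(cellsel, "DataArray", type="Int64", Name="offsets",
                         format="ascii")
    offs.text = " ".join(str(v) for v in np.cumsum([len(c) for c in cells]))
    types = ET.SubElement(cellsel, "DataArray", type="UInt8", Name="types",
                          format="ascii")
    types.text = " ".join(str(int(t)) for t in cell_types)

    if point_data:
        pd = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.atleast_2d(np.asarray(arr, float).T).T
            d = ET.SubElement(pd, "DataArray", type="Float64", Name=name,
                              NumberOfComponents=str(arr.shape[1]), format="ascii")
            d.text = "\n".join(" ".join(_FMT % v for v in row) for row in arr)
    if cell_data:
        cd = ET.SubElement(piece, "CellData")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            kind = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
            d = ET.SubElement(cd, "DataArray", type=kind, Name=name,
                              NumberOfComponents="1", format="ascii")
            fmt = (lambda v: str(int(v))) if kind == "Int64" else (lambda v: _FMT % v)
            d.text = "\n".join(fmt(v) for v in arr.ravel())
    return root


_VTK_QUAD, _VTK_LINE, _VTK_TRIANGLE = 9, 3, 5


def _write_vtu(mesh: VolumeMesh, path: str) -> None:
    cells = [c for c in mesh.cells]
    types = [_VTK_QUAD] * len(cells)
    tags = [TAG_CODES["interior"]] * len(cells)
    for tag in ("inlet", "outlet", "wall", "axis"):
        for facet in mesh.boundary_tags[tag]:
            cells.append(np.asarray(facet))
            types.append(_VTK_LINE)
            tags.append(TAG_CODES[tag])
    root = _vtu_doc(mesh.nodes, cells, np.array(types),
                    cell_data={"boundary_tag": np.array(tags, dtype=np.int64)})
    _append_mesh_meta(root, mesh)
    ET.ElementTree(root).write(path)


def _append_mesh_meta(root: ET.Element, mesh: VolumeMesh) -> None:
    meta = ET.SubElement(root, "PortaflowMeta")
    meta.set("max_cell_size", _FMT % mesh.max_cell_size)
    meta.set("n_axial", str(mesh.n_axial))
    meta.set("n_radial", str(mesh.n_radial))
    if mesh.boundary_layer is not None:
        b = mesh.boundary_layer
        meta.set("bl", f"{b.first_layer_height!r} {b.growth_rate!r} {b.n_layers}")


def write_vtu_fields(mesh: VolumeMesh, path: str | os.PathLike,
                     point_data: dict | None = None,
                     cell_data: dict | None = None) -> str:
    """Write the quad mesh with solution fields attached (for visualization)."""
    path = os.fspath(path)
    cells = [c for c in mesh.cells]
    root = _vtu_doc(mesh.nodes, cells, np.full(len(cells), _VTK_QUAD),
                    point_data=point_data, cell_data=cell_data)
    ET.ElementTree(root).write(path)
    return path


def read_vtu(path: str | os.PathLike) -> "MeshData":
    """Read a VTU written by :func:`export_mesh` (or :func:`write_vtu_fields`)."""
    root = ET.parse(os.fspath(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    pts = piece.find("./Points/DataArray")
    xyz = np.fromstring(pts.text.replace("\n", " "), sep=" ").reshape(-1, 3)
    nodes = np.column_stack([xyz[:, 1], xyz[:, 0]])  # back to (r, z)

    arrays = {d.get("Name"): d for d in piece.findall("./Cells/DataArray")}
    conn = np.fromstring(arrays["connectivity"].text.replace("\n", " "),
                         sep=" ").astype(int)
    offsets = np.fromstring(arrays["offsets"].text.replace("\n", " "),
                            sep=" ").astype(int)
    types = np.fromstring(arrays["types"].text.replace("\n", " "), sep=" ").astype(int)
    cells, start = [], 0
    for end in offsets:
        cells.append(conn[start:end])
        start = end

    tag_arr = None
    cd = piece.find("CellData")
    if cd is not None:
        for d in cd.findall("DataArray"):
            if d.get("Name") == "boundary_tag":
                tag_arr = np.fromstring(d.text.replace("\n", " "), sep=" ").astype(int)

    quads = np.array([c for c, t in zip(cells, types) if t == _VTK_QUAD])
    boundary: dict[str, list] = {}
    if tag_arr is not None:
        for c, t, code in zip(cells, types, tag_arr):
            if t == _VTK_LINE:
                boundary.setdefault(_CODE_TAGS[code], []).append(c)
    boundary_tags = {k: np.array(v) for k, v in boundary.items()}
    return MeshData(nodes=nodes, cells=quads, boundary_tags=boundary_tags)


@dataclass
class MeshData:
    """Plain mesh container returned by the readers."""

    nodes: np.ndarray
    cells: np.ndarray
    boundary_tags: dict

    @property
    def n_cells(self) -> int:
        return len(self.cells)


# ----------------------------------------------------------------- STL

def _revolved_surface(mesh: VolumeMesh, n_theta: int = 48):
    """Triangulate the revolved lumen surface: wall band + inlet/outlet caps.

    Vertices: for each axial station, a ring of n_theta points at the wall
    radius, plus one axis point at each end.  Closed and orientable.
    """
    rg, zg = mesh.r, mesh.z
    r_wall = rg[:, -1]
    z_wall = zg[:, -1]
    n_st = len(r_wall)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    verts = []
    for rw, zw in zip(r_wall, z_wall):
        for t in theta:
            verts.append((zw, rw * np.cos(t), rw * np.sin(t)))
    i_axis_in = len(verts)
    verts.append((z_wall[0], 0.0, 0.0))
    i_axis_out = len(verts)
    verts.append((z_wall[-1], 0.0, 0.0))
    verts = np.array(verts)

    tris = []
    ring = lambda i, k: i * n_theta + (k % n_theta)
    for i in range(n_st - 1):
        for k in range(n_theta):
            a, b = ring(i, k), ring(i, k + 1)
            c, d = ring(i + 1, k), ring(i + 1, k + 1)
            tris.append((a, b, c))      # outward (+r) winding
            tris.append((b, d, c))
    for k in range(n_theta):  # inlet cap fan (normal -z)
        tris.append((i_axis_in, ring(0, k + 1), ring(0, k)))
    for k in range(n_theta):  # outlet cap fan (normal +z)
        tris.append((i_axis_out, ring(n_st - 1, k), ring(n_st - 1, k + 1)))
    return verts, np.array(tris, dtype=int)


def _write_stl(mesh: VolumeMesh, path: str, n_theta: int = 48) -> None:
    verts, tris = _revolved_surface(mesh, n_theta)
    with open(path, "w") as fh:
        fh.write("solid portaflow\n")
        for tri in tris:
            p0, p1, p2 = verts[tri]
            n = np.cross(p1 - p0, p2 - p0)
            nn = np.linalg.norm(n)
            n = n / nn if nn > 0 else n
            fh.write(f"facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n outer loop\n")
            for p in (p0, p1, p2):
                fh.write(f"  vertex {p[0]:.17e} {p[1]:.17e} {p[2]:.17e}\n")
            fh.write(" endloop\nendfacet\n")
        fh.write("endsolid portaflow\n")


def read_stl(path: str | os.PathLike) -> np.ndarray:
    """Read an ASCII STL; returns the (n_tri, 3, 3) vertex array."""
    tris, cur = [], []
    with open(os.fspath(path)) as fh:
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                cur.append([float(x) for x in parts[1:4]])
                if len(cur) == 3:
                    tris.append(cur)
                    cur = []
    return np.array(tris)


# ----------------------------------------------------------------- MSH v4.1

def _write_msh(mesh: VolumeMesh, path: str) -> None:
    tags = ("inlet", "outlet", "wall", "axis")
    nodes = mesh.nodes
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n%d\n" % (len(tags) + 1))
        for k, t in enumerate(tags, start=1):
            fh.write(f'1 {k} "{t}"\n')
        fh.write('2 5 "fluid"\n')
        fh.write("$EndPhysicalNames\n")
        # entities: 0 points, 4 curves (one per tag), 1 surface, 0 volumes
        rmin, zmin = (float(v) for v in nodes.min(axis=0))
        rmax, zmax = (float(v) for v in nodes.max(axis=0))
        bb = f"{zmin!r} {rmin!r} 0 {zmax!r} {rmax!r} 0"
        fh.write("$Entities\n0 %d 1 0\n" % len(tags))
        for k in range(1, len(tags) + 1):
            fh.write(f"{k} {bb} 1 {k} 0\n")
        fh.write(f"1 {bb} 1 5 4 1 2 3 4\n")
        fh.write("$EndEntities\n")
        # all nodes in one block on the surface entity
        n = len(nodes)
        fh.write("$Nodes\n1 %d 1 %d\n2 1 0 %d\n" % (n, n, n))
        for i in range(1, n + 1):
            fh.write(f"{i}\n")
        for r, z in nodes:
            fh.write(f"{float(z)!r} {float(r)!r} 0\n")
        fh.write("$EndNodes\n")
        # element blocks: one per boundary curve (2-node lines) + quads
        n_elem = sum(len(mesh.boundary_tags[t]) for t in tags) + len(mesh.cells)
        fh.write("$Elements\n%d %d 1 %d\n" % (len(tags) + 1, n_elem, n_elem))
        eid = 1
        for k, t in enumerate(tags, start=1):
            facets = mesh.boundary_tags[t]
            fh.write(f"1 {k} 1 {len(facets)}\n")
            for a, b in facets:
                fh.write(f"{eid} {a + 1} {b + 1}\n")
                eid += 1
        fh.write(f"2 1 3 {len(mesh.cells)}\n")
        for c in mesh.cells:
            fh.write(f"{eid} {c[0] + 1} {c[1] + 1} {c[2] + 1} {c[3] + 1}\n")
            eid += 1
        fh.write("$EndElements\n")


def read_msh(path: str | os.PathLike) -> MeshData:
    """Read a Gmsh v4.1 file written by :func:`export_mesh`."""
    with open(os.fspath(path)) as fh:
        lines = fh.read().splitlines()
    idx = {name: i for i, name in enumerate(lines) if name.startswith("$")}

    names = {}
    i = idx["$PhysicalNames"] + 2
    while not lines[i].startswith("$End"):
        dim, tag, name = lines[i].split(maxsplit=2)
        names[(int(dim), int(tag))] = name.strip('"')
        i += 1

    i = idx["$Nodes"] + 1
    n_total = int(lines[i].split()[1])
    i += 1  # block header
    i += 1 + n_total  # skip node tags
    coords = []
    for k in range(n_total):
        x, y, _ = lines[i + k].split()
        coords.append((float(y), float(x)))  # back to (r, z)
    nodes = np.array(coords)

    i = idx["$Elements"] + 1
    n_blocks = int(lines[i].split()[0])
    i += 1
    quads, boundary = [], {}
    for _ in range(n_blocks):
        dim, ent, etype, count = (int(v) for v in lines[i].split())
        i += 1
        for k in range(count):
            parts = [int(v) for v in lines[i + k].split()]
            conn = [v - 1 for v in parts[1:]]
            if etype == 3:
                quads.append(conn)
            elif etype == 1:
                tag_name = names.get((1, ent), f"curve{ent}")
                boundary.setdefault(tag_name, []).append(conn)
        i += count
    return MeshData(nodes=nodes, cells=np.array(quads),
                    boundary_tags={k: np.array(v) for k, v in boundary.items()})
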