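"""File I/O: TIFF stacks, columnar displacement fields, VTU and Gmsh export.

VTU files are written as ASCII XML UnstructuredGrid (readable by ParaView
and any VTK-based viewer); a minimal reader supports round-tripping the
files this module writes.  Field units are recorded in the array names
(e.g. ``traction_Pa``, ``displacement_um``).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fem import Mesh
from .geometry import ImageStack
from .piv import DisplacementField

__all__ = [
    "read_stack",
    "write_stack",
    "write_displacement_csv",
    "read_displacement_csv",
    "write_vtu",
    "read_vtu",
    "write_msh",
]


def read_stack(
    path: str | Path,
    pixel_size_xy: float,
    z_step: float,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack (z, y, x order)."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return ImageStack(
        data=data, pixel_size_xy=pixel_size_xy, z_step=z_step, origin=origin
    )


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write an ImageStack as a multi-page TIFF (float32)."""
    tifffile.imwrite(str(path), stack.data.astype(np.float32))


def write_displacement_csv(path: str | Path, field: DisplacementField) -> None:
    """Columnar displacement file: x, y, z, ux, uy, uz, valid, quality (µm)."""
    df = pd.DataFrame(
        {
            "x_um": field.points[:, 0],
            "y_um": field.points[:, 1],
            "z_um": field.points[:, 2],
            "ux_um": field.vectors[:, 0],
            "uy_um": field.vectors[:, 1],
            "uz_um": field.vectors[:, 2],
            "valid": field.valid.astype(int),
            "quality": field.quality,
        }
    )
    if field.grid_shape is not None:
        with open(path, "w") as fh:
            fh.write(f"# grid_shape={field.grid_shape}\n")
            df.to_csv(fh, index=False)
    else:
        df.to_csv(path, index=False)


def read_displacement_csv(path: str | Path) -> DisplacementField:
    grid_shape = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# grid_shape="):
            grid_shape = tuple(
                int(t) for t in first.split("=")[1].strip(" ()\n").split(",") if t
            )
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    return DisplacementField(
        points=df[["x_um", "y_um", "z_um"]].to_numpy(),
        vectors=df[["ux_um", "uy_um", "uz_um"]].to_numpy(),
        valid=df["valid"].to_numpy().astype(bool),
        quality=df["quality"].to_numpy(),
        grid_shape=grid_shape,
    )


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    return " ".join(repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v)) for v in flat)


def write_vtu(
    path: str | Path,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh and nodal fields as an ASCII VTU file.

    ``point_data`` values may be (N,) scalars or (N, 3) vectors; include
    units in the name (e.g. ``traction_Pa``).
    """
    point_data = point_data or {}
    n_pts, n_cells = mesh.n_nodes, len(mesh.tets)
    for name, arr in point_data.items():
        if len(arr) != n_pts:
            raise ValueError(f"field '{name}' length {len(arr)} != {n_pts} nodes")
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.nodes.astype(float)),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(mesh.tets),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(4 * np.arange(1, n_cells + 1)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(["10"] * n_cells),  # VTK_TETRA
        "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            _fmt(arr),
            "</DataArray>",
        ]
    lines += ["</PointData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines))


def read_vtu(path: str | Path) -> tuple[Mesh, dict[str, np.ndarray]]:
    """Read a VTU file written by :func:`write_vtu` (ASCII tet meshes)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    pts_el = piece.find("Points/DataArray")
    nodes = np.fromstring(pts_el.text, sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.findall("Cells/DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=np.int64)
    tets = conn.reshape(-1, 4)
    fields: dict[str, np.ndarray] = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el.findall("DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            fields[da.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    return Mesh(nodes=nodes, tets=tets, surface_groups={}), fields


def write_msh(path: str | Path, mesh: Mesh) -> None:
    """Write the mesh in Gmsh MSH 2.2 ASCII format (tets + surface tris)."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(mesh.n_nodes)]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x!r} {y!r} {z!r}")
    lines += ["$EndNodes", "$Elements"]
    group_names = sorted(mesh.surface_groups)
    n_tris = sum(len(mesh.surface_groups[g]) for g in group_names)
    lines.append(str(n_tris + len(mesh.tets)))
    eid = 1
    for tag, g in enumerate(group_names, start=1):
        for tri in mesh.surface_groups[g] + 1:
            lines.append(f"{eid} 2 2 {tag} {tag} {tri[0]} {tri[1]} {tri[2]}")
            eid += 1
    vol_tag = len(group_names) + 1
    for tet in mesh.tets + 1:
        lines.append(
            f"{eid} 4 2 {vol_tag} {vol_tag} {tet[0]} {tet[1]} {tet[2]} {tet[3]}"
        )
        eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines))
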