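"""Mesh and result I/O: VTK XML unstructured grids (.vtu) and Abaqus .inp.

Both dialects use the same mid-edge node ordering as this package
(corners then edges (0,1),(1,2),(2,0),(0,3),(1,3),(2,3)): VTK cell type
24 (quadratic tetra) and Abaqus C3D10 map one-to-one onto the
connectivity rows. Only the ASCII flavours written here are read back.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .mesh import REGION_NAMES, TetMesh10, element_volumes

VTK_QUADRATIC_TETRA = 24


def write_vtu(
    mesh: TetMesh10,
    path,
    point_data: Optional[Dict[str, np.ndarray]] = None,
    cell_data: Optional[Dict[str, np.ndarray]] = None,
) -> None:
    """Write an ASCII .vtu with the region tag and optional data arrays."""
    path = Path(path)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.element_region)
    point_data = dict(point_data or {})

    def da(name, arr):
        arr = np.asarray(arr)
        comps = 1 if arr.ndim == 1 else arr.shape[1]
        typ = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        body = "\n".join(
            " ".join(format(v, ".17g") if typ == "Float64" else str(int(v)) for v in row)
            for row in np.atleast_2d(arr.reshape(arr.shape[0], -1))
        )
        return (
            f'<DataArray type="{typ}" Name="{name}" '
            f'NumberOfComponents="{comps}" format="ascii">\n{body}\n</DataArray>'
        )

    conn = " ".join(str(i) for i in mesh.connectivity.ravel())
    offs = " ".join(str(10 * (i + 1)) for i in range(mesh.n_elements))
    types = " ".join(str(VTK_QUADRATIC_TETRA) for _ in range(mesh.n_elements))
    pd = "\n".join(da(k, v) for k, v in point_data.items())
    cd = "\n".join(da(k, v) for k, v in cell_data.items())
    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elements}">
<Points>
{da("Points", mesh.node_coords)}
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{conn}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{offs}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{types}
</DataArray>
</Cells>
<PointData>
{pd}
</PointData>
<CellData>
{cd}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)


def read_vtu(path) -> TetMesh10:
    """Read an ASCII .vtu written by :func:`write_vtu`."""
    root = ET.parse(Path(path)).getroot()
    piece = root.find(".//Piece")

    def parse(elem, dtype=float):
        return np.fromstring(elem.text.replace("\n", " "), sep=" ", dtype=dtype)

    pts = None
    for daelem in piece.find("Points").iter("DataArray"):
        pts = parse(daelem).reshape(-1, 3)
    cells = {d.get("Name"): d for d in piece.find("Cells").iter("DataArray")}
    types = parse(cells["types"]).astype(int)
    if np.any(types != VTK_QUADRATIC_TETRA):
        raise ValueError("unsupported cell types (only quadratic tetra, type 24)")
    conn = parse(cells["connectivity"]).astype(np.int64).reshape(-1, 10)
    region = np.ones(conn.shape[0], np.int64)
    celldata = piece.find("CellData")
    if celldata is not None:
        for daelem in celldata.iter("DataArray"):
            if daelem.get("Name") == "region":
                region = parse(daelem).astype(np.int64)
    return TetMesh10(pts, conn, region)


def write_inp(mesh: TetMesh10, path, part_name: str = "FEMUR") -> None:
    """Write an Abaqus .inp with C3D10 elements and one elset per region."""
    path = Path(path)
    lines = [f"*HEADING", f"** infantfem mesh export", f"*NODE"]
    for i, (x, y, z) in enumerate(mesh.node_coords, start=1):
        lines.append(f"{i}, {x:.12g}, {y:.12g}, {z:.12g}")
    lines.append(f"*ELEMENT, TYPE=C3D10, ELSET={part_name}")
    for e, row in enumerate(mesh.connectivity, start=1):
        ids = ", ".join(str(i + 1) for i in row)
        lines.append(f"{e}, {ids}")
    for code in np.unique(mesh.element_region):
        name = REGION_NAMES.get(int(code), f"REGION_{code}").upper()
        lines.append(f"*ELSET, ELSET={name}")
        ids = (np.flatnonzero(mesh.element_region == code) + 1).tolist()
        for k in range(0, len(ids), 12):
            lines.append(", ".join(str(i) for i in ids[k : k + 12]))
    path.write_text("\n".join(lines) + "\n")


def read_inp(path) -> TetMesh10:
    """Read the .inp dialect written by :func:`write_inp`."""
    nodes, elems = {}, []
    elsets: Dict[str, list] = {}
    section = None
    current_set = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            up = line.upper()
            if up.startswith("*NODE"):
                section = "node"
            elif up.startswith("*ELEMENT"):
                if "C3D10" not in up:
                    raise ValueError("only C3D10 elements are supported")
                section = "element"
            elif up.startswith("*ELSET"):
                section = "elset"
                current_set = up.split("ELSET=")[-1].split(",")[0].strip()
                elsets[current_set] = []
            else:
                section = None
            continue
        vals = [v.strip() for v in line.split(",") if v.strip()]
        if section == "node":
            nodes[int(vals[0])] = [float(v) for v in vals[1:4]]
        elif section == "element":
            elems.append([int(v) for v in vals[1:11]])
        elif section == "elset" and current_set:
            elsets[current_set].extend(int(v) for v in vals)
    ids = sorted(nodes)
    renum = {nid: k for k, nid in enumerate(ids)}
    coords = np.array([nodes[i] for i in ids])
    conn = np.array([[renum[i] for i in row] for row in elems], np.int64)
    region = np.ones(conn.shape[0], np.int64)
    name_to_code = {v.upper(): k for k, v in REGION_NAMES.items()}
    for name, members in elsets.items():
        if name in name_to_code:
            region[np.asarray(members, int) - 1] = name_to_code[name]
    return TetMesh10(coords, conn, region)


def read_mesh(path) -> TetMesh10:
    """Dispatch on extension: .vtu or .inp."""
    p = Path(path)
    if p.suffix == ".vtu":
        return read_vtu(p)
    if p.suffix == ".inp":
        return read_inp(p)
    raise ValueError(f"unsupported mesh format {p.suffix!r}")


def write_mesh(mesh: TetMesh10, path, **kw) -> None:
    p = Path(path)
    if p.suffix == ".vtu":
        write_vtu(mesh, p, **kw)
    elif p.suffix == ".inp":
        write_inp(mesh, p, **kw)
    else:
        raise ValueError(f"unsupported mesh format {p.suffix!r}")


def mesh_statistics(mesh: TetMesh10) -> dict:
    """Counts plus an element-quality (volume and aspect) summary."""
    vols = element_volumes(mesh)
    edges = mesh.node_coords[mesh.connectivity[:, :4]]
    # longest corner edge per element
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    lmax = np.max(
        [np.linalg.norm(edges[:, a] - edges[:, b], axis=1) for a, b in pairs], axis=0
    )
    # radius ratio proxy: vol / lmax^3, normalised to the regular tet
    q = vols / lmax ** 3 / (1.0 / (6 * np.sqrt(2)))
    hist, bin_edges = np.histogram(q, bins=10, range=(0, 1))
    regions = {
        REGION_NAMES.get(int(c), str(c)): int((mesh.element_region == c).sum())
        for c in np.unique(mesh.element_region)
    }
    return {
        "n_nodes": int(mesh.n_nodes),
        "n_elements": int(mesh.n_elements),
        "regions": regions,
        "total_volume_mm3": float(vols.sum()),
        "quality_histogram": {
            "bin_edges": bin_edges.tolist(),
            "counts": hist.tolist(),
        },
    }


def write_mesh_statistics(mesh: TetMesh10, path) -> None:
    Path(path).write_text(json.dumps(mesh_statistics(mesh), indent=2))
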