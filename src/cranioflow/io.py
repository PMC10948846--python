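"""Mesh and field exchange in plain-text standard formats.

Meshes are written as Gmsh MSH 2.2 ASCII (triangles carry the region id as
their physical tag, boundary/interface lines carry the facet label id) and
field snapshots as legacy ASCII VTK unstructured grids. Both formats are
writable/readable with nothing beyond the standard library and numpy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import FACETS, REGIONS, Mesh


def write_msh(mesh: Mesh, path: str | Path) -> None:
    """Gmsh MSH 2.2 ASCII export with region/facet tags preserved."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(len(mesh.vertices))]
    for i, (x, y) in enumerate(mesh.vertices, start=1):
        lines.append(f"{i} {x:.16g} {y:.16g} 0")
    lines += ["$EndNodes", "$Elements", str(len(mesh.facets) + len(mesh.cells))]
    eid = 1
    for f, lab in zip(mesh.facets, mesh.facet_labels):
        lines.append(f"{eid} 1 2 {lab} {lab} {f[0] + 1} {f[1] + 1}")
        eid += 1
    for c, reg in zip(mesh.cells, mesh.cell_regions):
        lines.append(f"{eid} 2 2 {reg} {reg} {c[0] + 1} {c[1] + 1} {c[2] + 1}")
        eid += 1
    lines += ["$EndElements", ""]
    path.write_text("\n".join(lines))


def read_msh(path: str | Path, axisymmetric: bool = True) -> Mesh:
    """Read a MSH 2.2 ASCII file written by :func:`write_msh`."""
    tokens = Path(path).read_text().splitlines()
    it = iter(tokens)
    verts, cells, regions, facets, labels = [], [], [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                verts.append((float(parts[1]), float(parts[2])))
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                tag = int(parts[3]) if ntags else 0
                conn = [int(v) - 1 for v in parts[3 + ntags :]]
                if etype == 1:
                    facets.append(conn)
                    labels.append(tag)
                elif etype == 2:
                    cells.append(conn)
                    regions.append(tag)
    return Mesh(
        vertices=np.asarray(verts, dtype=float),
        cells=np.asarray(cells, dtype=np.int64),
        cell_regions=np.asarray(regions, dtype=np.int64),
        facets=np.asarray(facets, dtype=np.int64),
        facet_labels=np.asarray(labels, dtype=np.int64),
        axisymmetric=axisymmetric,
        region_names=dict(REGIONS),
        facet_names=dict(FACETS),
    )


def write_vtk(
    path: str | Path,
    vertices: np.ndarray,
    cells: np.ndarray,
    point_data: dict | None = None,
    cell_data: dict | None = None,
    title: str = "cranioflow fields",
) -> None:
    """Legacy ASCII VTK unstructured-grid export (triangles).

    ``point_data``/``cell_data`` map names to scalar (n,) or vector (n, 2)
    arrays; 2-D vectors are padded with a zero z-component.
    """
    path = Path(path)
    n, m = len(vertices), len(cells)
    out = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    out += [f"{x:.10g} {y:.10g} 0" for x, y in vertices]
    out.append(f"CELLS {m} {4 * m}")
    out += [f"3 {a} {b} {c}" for a, b, c in cells]
    out.append(f"CELL_TYPES {m}")
    out += ["5"] * m

    def emit(block: dict, head: str, count: int):
        out.append(f"{head} {count}")
        for name, arr in block.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{v:.10g}" for v in arr)
            else:
                out.append(f"VECTORS {name} double")
                out.extend(f"{v[0]:.10g} {v[1]:.10g} 0" for v in arr)

    if point_data:
        emit(point_data, "POINT_DATA", n)
    if cell_data:
        emit(cell_data, "CELL_DATA", m)
    out.append("")
    path.write_text("\n".join(out))
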