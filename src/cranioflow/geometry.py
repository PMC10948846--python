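"""Idealized head geometry and triangle meshing.

The cranium is idealized as concentric spherical compartments, meshed in the
axisymmetric r-z half-plane (x >= 0 is the cylindrical radius, revolution
about x = 0): a CSF-filled ventricular cavity of radius ``ventricle_radius``,
the brain parenchyma shell out to ``brain_outer_radius``, and a thin
subarachnoid space (SAS) of ``sas_thickness`` bounded by the dura. The
cerebral aqueduct is an optional channel through the parenchyma near the
lower pole; with ``aqueduct_radius = 0`` (default) the ventricles do not
communicate with the SAS, the non-communicating configuration of aqueductal
stenosis.

All mesh coordinates are millimetres. Volumes are reported in ml and areas
in cm^2 by revolving the 2-D measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError, InvalidMeshError, MeshingError

REGIONS = {"ventricle_csf": 0, "brain": 1, "sas_csf": 2}
FACETS = {
    "inlet": 0,
    "spinal_outlet": 1,
    "sinus_outlet": 2,
    "dura": 3,
    "fsi_inner": 4,
    "fsi_outer": 5,
    "axis": 6,
    "shunt": 7,  # ventricular catheter patch (outlet pressure stands in for the valve)
    # generic tags used by benchmark meshes
    "left": 10,
    "right": 11,
    "bottom": 12,
    "top": 13,
}

REFINEMENT_LEVELS = ("coarse", "medium", "fine", "very_fine")
_REFINEMENT_MULT = {"coarse": 1, "medium": 2, "fine": 4, "very_fine": 8}


@dataclass(frozen=True)
class HeadGeometry:
    """Dimensions (mm) of the idealized axisymmetric head model."""

    ventricle_radius: float = 20.0
    aqueduct_radius: float = 0.0
    brain_outer_radius: float = 70.0
    sas_thickness: float = 3.0
    inlet_half_angle_deg: float = 25.0  # polar half-angle of the inflow patch
    outlet_half_angle_deg: float = 20.0  # polar half-angle of each outlet patch
    shunt_half_angle_deg: float = 15.0  # angular width of the ventricular
    # catheter patch adjacent to the inlet; 0 = no shunt (untreated, sealed)
    axisymmetric: bool = True

    def __post_init__(self):
        if not (0 < self.ventricle_radius < self.brain_outer_radius):
            raise InvalidGeometryError(
                "require 0 < ventricle_radius < brain_outer_radius "
                f"(got {self.ventricle_radius}, {self.brain_outer_radius})"
            )
        if self.sas_thickness <= 0:
            raise InvalidGeometryError("sas_thickness must be positive")
        if self.aqueduct_radius < 0:
            raise InvalidGeometryError("aqueduct_radius must be >= 0")
        if self.aqueduct_radius >= self.ventricle_radius:
            raise InvalidGeometryError("aqueduct_radius must be < ventricle_radius")
        if not (0 < self.inlet_half_angle_deg < 90):
            raise InvalidGeometryError("inlet_half_angle_deg must be in (0, 90)")

    @property
    def outer_radius(self) -> float:
        return self.brain_outer_radius + self.sas_thickness

    @property
    def communicating(self) -> bool:
        """True when the aqueduct channel is open (no complete stenosis)."""
        return self.aqueduct_radius > 0


def build_geometry(params: HeadGeometry) -> HeadGeometry:
    """Validate and return the analytic boundary description.

    The dataclass itself is the analytic description (concentric arcs plus
    patch angles); validation happens in its constructor, so this is the
    canonical entry point mirroring mesh generation.
    """
    if not isinstance(params, HeadGeometry):
        params = HeadGeometry(**params)
    return params


@dataclass
class Mesh:
    """Labeled triangle mesh in the r-z half-plane (coordinates in mm)."""

    vertices: np.ndarray  # (n, 2)
    cells: np.ndarray  # (m, 3), CCW
    cell_regions: np.ndarray  # (m,) ints from REGIONS
    facets: np.ndarray  # (F, 2) vertex pairs
    facet_labels: np.ndarray  # (F,) ints from FACETS
    refinement_level: str = "coarse"
    axisymmetric: bool = True
    region_names: dict = field(default_factory=lambda: dict(REGIONS))
    facet_names: dict = field(default_factory=lambda: dict(FACETS))

    def __post_init__(self):
        a = _signed_areas(self.vertices, self.cells)
        neg = a < 0
        if np.any(neg):  # enforce CCW orientation
            self.cells[neg] = self.cells[neg][:, [0, 2, 1]]
            a = np.abs(a)
        if np.any(a <= 0):
            raise InvalidMeshError("mesh contains zero-area cells")

    # ------------------------------------------------------------- queries
    def cells_in(self, *region_names: str) -> np.ndarray:
        ids = [self.region_names[r] for r in region_names]
        return np.nonzero(np.isin(self.cell_regions, ids))[0]

    def facets_named(self, *names: str) -> np.ndarray:
        ids = [self.facet_names[n] for n in names]
        return self.facets[np.isin(self.facet_labels, ids)]

    def has_facets(self, name: str) -> bool:
        return bool(np.any(self.facet_labels == self.facet_names[name]))

    def max_cell_diameter(self) -> float:
        v = self.vertices[self.cells]
        e = np.stack(
            [
                v[:, 1] - v[:, 0],
                v[:, 2] - v[:, 1],
                v[:, 0] - v[:, 2],
            ]
        )
        return float(np.sqrt((e**2).sum(-1)).max())

    def cell_areas(self) -> np.ndarray:
        return np.abs(_signed_areas(self.vertices, self.cells))

    def region_volume_ml(self, *region_names: str) -> float:
        """Revolved volume (axisym) or unit-depth volume of the regions, ml."""
        idx = self.cells_in(*region_names)
        a = self.cell_areas()[idx]
        if self.axisymmetric:
            xc = self.vertices[self.cells[idx]].mean(axis=1)[:, 0]
            vol_mm3 = float((2.0 * np.pi * xc * a).sum())
        else:
            vol_mm3 = float(a.sum())
        return vol_mm3 / 1000.0

    def facet_area_cm2(self, *names: str) -> float:
        """Revolved area of the named facet sets, cm^2."""
        f = self.facets_named(*names)
        if f.size == 0:
            raise InvalidMeshError(f"no facets labeled {names}")
        x0, x1 = self.vertices[f[:, 0]], self.vertices[f[:, 1]]
        length = np.linalg.norm(x1 - x0, axis=1)
        if self.axisymmetric:
            xm = 0.5 * (x0[:, 0] + x1[:, 0])
            area_mm2 = float((2.0 * np.pi * xm * length).sum())
        else:
            area_mm2 = float(length.sum())
        return area_mm2 / 100.0


def _signed_areas(vertices, cells):
    v = vertices[cells]
    return 0.5 * (
        (v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1])
        - (v[:, 2, 0] - v[:, 0, 0]) * (v[:, 1, 1] - v[:, 0, 1])
    )


# ------------------------------------------------------------------ meshing


def generate_mesh(
    geometry: HeadGeometry,
    refinement_level: str = "coarse",
    n_theta_base: int = 12,
    radial_base=(2, 4, 1),
) -> Mesh:
    """Structured polar mesh of the half-disk head section.

    Each refinement level doubles every division count of the previous one,
    halving the maximum cell diameter. ``radial_base`` gives the coarse-level
    radial layer counts in (ventricle, brain, SAS).
    """
    if refinement_level not in _REFINEMENT_MULT:
        raise ValueError(f"unknown refinement level {refinement_level!r}")
    mult = _REFINEMENT_MULT[refinement_level]
    try:
        return _polar_mesh(geometry, mult * n_theta_base, [mult * n for n in radial_base], refinement_level)
    except InvalidMeshError as exc:  # pragma: no cover - defensive
        raise MeshingError(f"meshing failed for geometry {geometry}: {exc}") from exc


def _polar_mesh(geo: HeadGeometry, n_theta: int, radial: list[int], level: str) -> Mesh:
    nv, nb, ns = radial
    rv, rb, ro = geo.ventricle_radius, geo.brain_outer_radius, geo.outer_radius
    radii = np.concatenate(
        [
            np.linspace(0.0, rv, nv + 1)[1:],
            np.linspace(rv, rb, nb + 1)[1:],
            np.linspace(rb, ro, ns + 1)[1:],
        ]
    )
    n_rings = radii.size
    theta = np.linspace(0.0, np.pi, n_theta + 1)
    # vertex 0 = center; ring i vertex j -> 1 + i*(n_theta+1) + j
    pts = [np.zeros((1, 2))]
    for r in radii:
        pts.append(np.column_stack([r * np.sin(theta), r * np.cos(theta)]))
    vertices = np.vstack(pts)

    def vid(i, j):
        return 1 + i * (n_theta + 1) + j

    cells, ring_of_cell = [], []
    for j in range(n_theta):  # center fan
        cells.append([0, vid(0, j), vid(0, j + 1)])
        ring_of_cell.append(0)
    for i in range(n_rings - 1):
        for j in range(n_theta):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            cells.append([a, b, d])
            cells.append([a, d, c])
            ring_of_cell += [i + 1, i + 1]
    cells = np.asarray(cells, dtype=np.int64)
    ring_of_cell = np.asarray(ring_of_cell)

    # region per cell from the outer-ring radius of its band
    outer_r = radii[ring_of_cell]
    regions = np.where(
        outer_r <= rv + 1e-9,
        REGIONS["ventricle_csf"],
        np.where(outer_r <= rb + 1e-9, REGIONS["brain"], REGIONS["sas_csf"]),
    )

    # aqueduct: open a channel through the parenchyma near the lower pole by
    # relabeling brain cells whose centroid lies within the channel radius
    if geo.communicating:
        cent = vertices[cells].mean(axis=1)
        in_channel = (
            (regions == REGIONS["brain"]) & (cent[:, 0] < geo.aqueduct_radius) & (cent[:, 1] < 0)
        )
        regions = np.where(in_channel, REGIONS["ventricle_csf"], regions)

    facets, labels = _label_facets(geo, vertices, cells, regions)
    return Mesh(
        vertices=vertices,
        cells=cells,
        cell_regions=regions,
        facets=facets,
        facet_labels=labels,
        refinement_level=level,
        axisymmetric=geo.axisymmetric,
    )


def _edge_cell_map(cells: np.ndarray):
    """dict sorted-edge-tuple -> list of adjacent cell indices."""
    from collections import defaultdict

    m = defaultdict(list)
    for ci, (a, b, c) in enumerate(cells):
        for e in ((a, b), (b, c), (c, a)):
            m[tuple(sorted(e))].append(ci)
    return m

def _polar_angle(x: np.ndarray) -> np.ndarray:
    """Polar angle from the +z axis (y here), in [0, pi]."""
    return np.arctan2(x[:, 0], x[:, 1])


def _label_facets(geo: HeadGeometry, vertices, cells, regions):
    """Derive facet labels from cell adjacency and patch angles."""
    emap = _edge_cell_map(cells)
    th_in = np.deg2rad(geo.inlet_half_angle_deg)
    th_shunt = th_in + np.deg2rad(geo.shunt_half_angle_deg)
    th_out = np.deg2rad(geo.outlet_half_angle_deg)
    facets, labels = [], []
    vent, brain, sas = REGIONS["ventricle_csf"], REGIONS["brain"], REGIONS["sas_csf"]
    for edge, adj in emap.items():
        v0, v1 = edge
        mid = 0.5 * (vertices[v0] + vertices[v1])
        ang = float(_polar_angle(mid[None, :])[0])
        if len(adj) == 1:  # true boundary
            if abs(mid[0]) < 1e-9:  # on the symmetry axis
                lab = FACETS["axis"]
            elif ang < th_out:
                lab = FACETS["sinus_outlet"]
            elif ang > np.pi - th_out:
                lab = FACETS["spinal_outlet"]
            else:
                lab = FACETS["dura"]
            facets.append(edge)
            labels.append(lab)
        else:
            r0, r1 = regions[adj[0]], regions[adj[1]]
            if r0 == r1:
                continue
            pair = {r0, r1}
            if pair == {vent, brain}:
                if ang < th_in:
                    lab = FACETS["inlet"]
                elif ang < th_shunt:
                    lab = FACETS["shunt"]
                else:
                    lab = FACETS["fsi_inner"]
            elif pair == {brain, sas}:
                lab = FACETS["fsi_outer"]
            else:  # open aqueduct mouth: fluid-fluid, no interface condition
                continue
            facets.append(edge)
            labels.append(lab)
    return np.asarray(facets, dtype=np.int64), np.asarray(labels, dtype=np.int64)


def measure_volume_and_area(mesh: Mesh) -> tuple[float, float]:
    """Intracranial volume (ml) and brain surface area (cm^2).

    Volume integrates all regions inside the dura; area is the measure of the
    brain-CSF interfaces (inner + outer), both revolved about the axis for
    axisymmetric meshes.
    """
    for need in ("fsi_inner", "fsi_outer"):
        if not mesh.has_facets(need):
            raise InvalidMeshError(f"mesh lacks required facet label {need!r}")
    vol = mesh.region_volume_ml("ventricle_csf", "brain", "sas_csf")
    area = mesh.facet_area_cm2("fsi_inner", "fsi_outer")
    return vol, area


# ------------------------------------------------------- benchmark meshes


def rectangle_mesh(
    lx: float,
    ly: float,
    nx: int,
    ny: int,
    region: str = "sas_csf",
    axisymmetric: bool = False,
    x0: float = 0.0,
    y0: float = 0.0,
) -> Mesh:
    """Structured triangle mesh of [x0, x0+lx] x [y0, y0+ly] (mm) with
    left/right/bottom/top boundary tags; used by the solver benchmarks."""
    xs = np.linspace(x0, x0 + lx, nx + 1)
    ys = np.linspace(y0, y0 + ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([X.ravel(), Y.ravel()])

    def vid(i, j):
        return i * (ny + 1) + j

    cells = []
    for i in range(nx):
        for j in range(ny):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            cells.append([a, b, c])
            cells.append([a, c, d])
    cells = np.asarray(cells, dtype=np.int64)
    regions = np.full(len(cells), REGIONS[region], dtype=np.int64)

    facets, labels = [], []
    for j in range(ny):
        facets.append([vid(0, j), vid(0, j + 1)])
        labels.append(FACETS["left"])
        facets.append([vid(nx, j), vid(nx, j + 1)])
        labels.append(FACETS["right"])
    for i in range(nx):
        facets.append([vid(i, 0), vid(i + 1, 0)])
        labels.append(FACETS["bottom"])
        facets.append([vid(i, ny), vid(i + 1, ny)])
        labels.append(FACETS["top"])
    return Mesh(
        vertices=vertices,
        cells=cells,
        cell_regions=regions,
        facets=np.asarray(facets, dtype=np.int64),
        facet_labels=np.asarray(labels, dtype=np.int64),
        axisymmetric=axisymmetric,
    )


def relabel_facets(mesh: Mesh, mapping: dict[str, str]) -> Mesh:
    """Return a mesh with facet labels renamed, e.g. left -> inlet."""
    labels = mesh.facet_labels.copy()
    for src, dst in mapping.items():
        labels[mesh.facet_labels == mesh.facet_names[src]] = mesh.facet_names[dst]
    return Mesh(
        vertices=mesh.vertices.copy(),
        cells=mesh.cells.copy(),
        cell_regions=mesh.cell_regions.copy(),
        facets=mesh.facets.copy(),
        facet_labels=labels,
        refinement_level=mesh.refinement_level,
        axisymmetric=mesh.axisymmetric,
    )


def facet_adjacent_cells(mesh: Mesh, facets: np.ndarray, restrict_regions=None) -> np.ndarray:
    """For each facet, one adjacent cell index (optionally restricted to the
    given region names) — used to orient facet normals."""
    emap = _edge_cell_map(mesh.cells)
    if restrict_regions is not None:
        allowed = set(mesh.region_names[r] for r in restrict_regions)
    out = np.empty(len(facets), dtype=np.int64)
    for i, f in enumerate(facets):
        adj = emap[tuple(sorted(f))]
        if restrict_regions is not None:
            adj = [c for c in adj if mesh.cell_regions[c] in allowed]
        if not adj:
            raise InvalidMeshError("facet has no adjacent cell in requested regions")
        out[i] = adj[0]
    return out
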