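"""Extraction of per-physics subdomains from the labeled global mesh.

The fluid and solid solvers each operate on a region subset of one global
mesh. Because the global mesh is conforming, interface nodes are shared;
cross-solver field transfer is done through stable dof keys (global vertex id
for vertex dofs, the sorted global vertex pair for P2 edge-midpoint dofs).

Subdomain coordinates are converted from mm (mesh units) to meters (solver
units).
"""

from __future__ import annotations

import numpy as np

from .fem import Basis
from .geometry import Mesh, _edge_cell_map

MM_TO_M = 1e-3


class Subdomain:
    def __init__(self, mesh: Mesh, regions: list[str], scale: float = MM_TO_M):
        self.mesh = mesh
        self.regions = list(regions)
        cell_idx = mesh.cells_in(*regions)
        if cell_idx.size == 0:
            raise ValueError(f"no cells in regions {regions}")
        cells_g = mesh.cells[cell_idx]
        vids = np.unique(cells_g)
        g2l = -np.ones(mesh.vertices.shape[0], dtype=np.int64)
        g2l[vids] = np.arange(vids.size)
        self.vertices = mesh.vertices[vids] * scale
        self.cells = g2l[cells_g]
        self.cell_regions = mesh.cell_regions[cell_idx]
        self.vertex_gids = vids
        self.scale = scale
        # local facet sets with a local adjacent cell for normal orientation
        gcell2local = {int(g): i for i, g in enumerate(cell_idx)}
        allowed = {mesh.region_names[r] for r in regions}
        emap = _edge_cell_map(mesh.cells)
        self.facet_sets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, lab in mesh.facet_names.items():
            sel = mesh.facet_labels == lab
            if not np.any(sel):
                continue
            fac, adj = [], []
            for f in mesh.facets[sel]:
                cands = [c for c in emap[tuple(sorted(f))] if mesh.cell_regions[c] in allowed]
                if not cands:
                    continue
                fac.append(g2l[f])
                adj.append(gcell2local[int(cands[0])])
            if fac:
                self.facet_sets[name] = (
                    np.asarray(fac, dtype=np.int64),
                    np.asarray(adj, dtype=np.int64),
                )

    def cells_in(self, *region_names: str) -> np.ndarray:
        ids = [self.mesh.region_names[r] for r in region_names]
        return np.nonzero(np.isin(self.cell_regions, ids))[0]

    def facets(self, *names: str):
        """Concatenated (facets, adj) for the given label names (if present)."""
        fs = [self.facet_sets[n] for n in names if n in self.facet_sets]
        if not fs:
            return np.zeros((0, 2), dtype=np.int64), np.zeros(0, dtype=np.int64)
        return np.vstack([f for f, _ in fs]), np.concatenate([a for _, a in fs])


def dof_keys(basis: Basis, vertex_gids: np.ndarray) -> list:
    """Stable cross-subdomain keys for each scalar dof of a basis."""
    keys = [("v", int(g)) for g in vertex_gids]
    if basis.degree == 2:
        ge = vertex_gids[basis.edges]
        keys += [("e", (int(min(a, b)), int(max(a, b)))) for a, b in ge]
    return keys
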