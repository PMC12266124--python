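"""Labeled hexahedral meshing of MTU designs.

The construct geometry is rectilinear, so meshing is a structured
(tensor-product) grid whose grid lines are placed exactly on every geometric
boundary (bridge edges, gap edges, section boundaries, anchor-hole edges);
each segment is then subdivided into elements of size at most ``h``.
Voxelization is therefore exact: the mesh volume equals the design volume.

Coordinates are mm with the origin at the construct center; z is the long
(contraction) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import MTUDesign

__all__ = ["HexMesh", "hex_mesh", "box_mesh", "write_vtk"]

MUSCLE = 0
TENDON = 1
REGION_NAMES = {MUSCLE: "muscle", TENDON: "tendon"}


@dataclass
class HexMesh:
    """Hexahedral mesh with region labels and actuation bookkeeping.

    vertices : (n_vertices, 3) float array, mm.
    hexahedra : (n_cells, 8) int array, VTK node ordering (bottom z face
        counter-clockwise, then top face).
    region : (n_cells,) int array, ``MUSCLE`` or ``TENDON``.
    contractile : (n_cells,) bool mask, subset of muscle elements.
    constrained_vertices : int array of Dirichlet-fixed vertex ids (empty for
        the free-floating simulations the study analyses).
    """

    vertices: np.ndarray
    hexahedra: np.ndarray
    region: np.ndarray
    contractile: np.ndarray
    constrained_vertices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_cells(self) -> int:
        return int(self.hexahedra.shape[0])

    def cell_sizes(self) -> np.ndarray:
        """(n_cells, 3) edge lengths of every (axis-aligned) element."""
        corner0 = self.vertices[self.hexahedra[:, 0]]
        dx = self.vertices[self.hexahedra[:, 1], 0] - corner0[:, 0]
        dy = self.vertices[self.hexahedra[:, 3], 1] - corner0[:, 1]
        dz = self.vertices[self.hexahedra[:, 4], 2] - corner0[:, 2]
        return np.column_stack([dx, dy, dz])

    def cell_volumes(self) -> np.ndarray:
        return np.prod(self.cell_sizes(), axis=1)

    def validate(self) -> None:
        if self.hexahedra.min() < 0 or self.hexahedra.max() >= self.n_vertices:
            raise ValueError("hexahedron connectivity references invalid vertices")
        if np.any(self.cell_volumes() <= 0):
            raise ValueError("mesh contains degenerate or inverted elements")
        if np.any(self.contractile & (self.region != MUSCLE)):
            raise ValueError("contractile elements must be muscle elements")


def _segment_points(breaks: list[float], h: float) -> np.ndarray:
    """Grid coordinates: each [breaks[i], breaks[i+1]] split into <=h pieces."""
    pts = [breaks[0]]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((hi - lo) / h - 1e-9)))
        pts.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(pts)


def _dedupe(vals: list[float], tol: float = 1e-9) -> list[float]:
    out: list[float] = []
    for v in sorted(vals):
        if not out or v - out[-1] > tol:
            out.append(v)
    return out


def hex_mesh(
    design: MTUDesign, h: float = 0.5, surface_layer_depth: int = 1
) -> HexMesh:
    """Mesh an MTU design into labeled hexahedra of size at most ``h`` mm.

    Muscle elements within ``surface_layer_depth`` face-adjacency steps of
    the exterior surface form the contractile set, emulating the superficial
    tissue shell that actually matures on the construct (cells survive only
    near the surface).  Anchor-hole voxels are removed.

    Raises ``ValueError`` if ``h`` cannot resolve a bridge with at least two
    elements across its width.
    """
    design.validate()
    if surface_layer_depth < 1:
        raise ValueError("surface_layer_depth must be >= 1")
    if int(np.ceil(design.bridge_width / h - 1e-9)) < 2:
        raise ValueError(
            f"element size h={h} mm gives fewer than 2 elements across the "
            f"{design.bridge_width} mm bridge width; use h <= "
            f"{design.bridge_width / 2} mm"
        )

    w, ht, L = design.width, design.height, design.total_length
    Lm = design.muscle_section_length
    Lt = design.tendon_section_length
    hole_x, hole_z = design.anchor_hole

    spans = design.bridge_spans()
    x_breaks = _dedupe(
        [-w / 2, w / 2, -hole_x / 2, hole_x / 2]
        + [s for sp in spans for s in sp]
    )
    y_breaks = [-ht / 2, ht / 2]
    # z boundaries: section limits plus anchor-hole edges centered in each
    # tendon section.
    hole_lo = -L / 2 + (Lt - hole_z) / 2
    z_breaks = _dedupe(
        [
            -L / 2,
            -Lm / 2,
            Lm / 2,
            L / 2,
            hole_lo,
            hole_lo + hole_z,
            -hole_lo - hole_z,
            -hole_lo,
        ]
    )

    xs = _segment_points(x_breaks, h)
    ys = _segment_points(y_breaks, h)
    zs = _segment_points(z_breaks, h)
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1

    xc = 0.5 * (xs[:-1] + xs[1:])
    zc = 0.5 * (zs[:-1] + zs[1:])

    in_muscle_z = np.abs(zc) < Lm / 2
    in_bridge_x = np.zeros(nx, dtype=bool)
    for lo, hi in spans:
        in_bridge_x |= (xc > lo) & (xc < hi)
    in_hole_x = np.abs(xc) < hole_x / 2
    in_hole_z = ((zc > hole_lo) & (zc < hole_lo + hole_z)) | (
        (zc > -hole_lo - hole_z) & (zc < -hole_lo)
    )

    # occupancy (nx, ny, nz): muscle section keeps bridge columns only;
    # tendon sections are full-width minus the through-height anchor holes.
    occ = np.zeros((nx, ny, nz), dtype=bool)
    muscle_col = in_bridge_x[:, None] & in_muscle_z[None, :]
    tendon_col = (~in_muscle_z)[None, :] & ~(
        in_hole_x[:, None] & in_hole_z[None, :]
    )
    occ[:] = (muscle_col | tendon_col)[:, None, :]

    region3 = np.where(in_muscle_z[None, None, :], MUSCLE, TENDON)
    region3 = np.broadcast_to(region3, occ.shape)

    # distance (in face-adjacency steps) from the exterior, computed on the
    # occupancy grid: layer 1 = solid cell with at least one exposed face.
    padded = np.pad(occ, 1, constant_values=False)
    exposed = np.zeros_like(occ)
    for axis in range(3):
        for shift in (-1, 1):
            nb = np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
            exposed |= occ & ~nb
    layer = np.where(exposed, 1, np.iinfo(np.int32).max)
    frontier = exposed.copy()
    depth = 1
    while depth < surface_layer_depth and frontier.any():
        padded_f = np.pad(frontier, 1, constant_values=False)
        grown = np.zeros_like(occ)
        for axis in range(3):
            for shift in (-1, 1):
                grown |= np.roll(padded_f, shift, axis=axis)[1:-1, 1:-1, 1:-1]
        depth += 1
        newly = occ & grown & (layer > depth)
        layer[newly] = depth
        frontier = newly
    contractile3 = occ & (layer <= surface_layer_depth) & (region3 == MUSCLE)

    # build vertices/cells for occupied voxels only
    ii, jj, kk = np.nonzero(occ)
    corners = np.stack(
        [
            np.stack([ii + di, jj + dj, kk + dk], axis=1)
            for di, dj, dk in (
                (0, 0, 0),
                (1, 0, 0),
                (1, 1, 0),
                (0, 1, 0),
                (0, 0, 1),
                (1, 0, 1),
                (1, 1, 1),
                (0, 1, 1),
            )
        ],
        axis=1,
    )  # (n_cells, 8, 3)
    flat = (
        corners[:, :, 0] * (ny + 1) * (nz + 1)
        + corners[:, :, 1] * (nz + 1)
        + corners[:, :, 2]
    )
    used, inverse = np.unique(flat, return_inverse=True)
    hexes = inverse.reshape(flat.shape)
    gi = used // ((ny + 1) * (nz + 1))
    gj = (used // (nz + 1)) % (ny + 1)
    gk = used % (nz + 1)
    verts = np.column_stack([xs[gi], ys[gj], zs[gk]])

    mesh = HexMesh(
        vertices=verts,
        hexahedra=hexes.astype(np.int64),
        region=region3[ii, jj, kk].astype(np.int64),
        contractile=contractile3[ii, jj, kk],
    )
    mesh.validate()
    return mesh


def box_mesh(
    lx: float,
    ly: float,
    lz: float,
    h: float,
    *,
    region: int = MUSCLE,
    contractile: str = "all",
) -> HexMesh:
    """Uniform box mesh centered at the origin (test/benchmark geometry).

    ``contractile`` is ``"all"``, ``"none"`` or ``"surface"`` (depth-1 shell).
    """
    xs = _segment_points([-lx / 2, lx / 2], h)
    ys = _segment_points([-ly / 2, ly / 2], h)
    zs = _segment_points([-lz / 2, lz / 2], h)
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    vid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(
        nx + 1, ny + 1, nz + 1
    )
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    i, j, k = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    hexes = np.stack(
        [
            vid[i, j, k],
            vid[i + 1, j, k],
            vid[i + 1, j + 1, k],
            vid[i, j + 1, k],
            vid[i, j, k + 1],
            vid[i + 1, j, k + 1],
            vid[i + 1, j + 1, k + 1],
            vid[i, j + 1, k + 1],
        ],
        axis=1,
    )
    n_cells = hexes.shape[0]
    if contractile == "all":
        cmask = np.ones(n_cells, dtype=bool)
    elif contractile == "none":
        cmask = np.zeros(n_cells, dtype=bool)
    elif contractile == "surface":
        interior = (
            (i > 0) & (i < nx - 1) & (j > 0) & (j < ny - 1) & (k > 0) & (k < nz - 1)
        )
        cmask = ~interior
    else:
        raise ValueError(f"unknown contractile mode {contractile!r}")
    mesh = HexMesh(
        vertices=verts,
        hexahedra=hexes.astype(np.int64),
        region=np.full(n_cells, region, dtype=np.int64),
        contractile=cmask if region == MUSCLE else np.zeros(n_cells, bool),
    )
    mesh.validate()
    return mesh


def write_vtk(mesh: HexMesh, path: str | Path, point_data: dict | None = None) -> None:
    """Write the mesh as a legacy-ASCII VTK unstructured grid.

    Region and contractile labels are written as cell data; optional
    ``point_data`` arrays (e.g. displacements) as point data.
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "MTU hexahedral mesh (mm; origin at construct center, z = long axis)",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [" ".join(f"{c:.9g}" for c in p) for p in mesh.vertices]
    lines.append(f"CELLS {mesh.n_cells} {mesh.n_cells * 9}")
    lines += ["8 " + " ".join(str(v) for v in cell) for cell in mesh.hexahedra]
    lines.append(f"CELL_TYPES {mesh.n_cells}")
    lines += ["12"] * mesh.n_cells
    lines.append(f"CELL_DATA {mesh.n_cells}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(r)) for r in mesh.region]
    lines.append("SCALARS contractile int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(c)) for c in mesh.contractile]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{c:.9g}" for c in p) for p in arr]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.9g}" for v in arr.ravel()]
    path.write_text("\n".join(lines) + "\n")
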