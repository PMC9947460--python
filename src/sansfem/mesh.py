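"""Structured multi-block quadrilateral meshing of the axisymmetric anatomy.

Each region is a mapped structured block of tensor-product Lagrange elements
(arbitrary order).  The shell block is laid out in (psi, thickness); the fat
block is a transfinite loft between its inner boundary (globe outer surface
+ dural cylinder) and outer boundary (septum + orbital wall).  Blocks are
independent: the sclera-fat interface is non-conforming and coupled by
contact in the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import (AnatomyError, GeometryModel, ellipse_point,
                      fat_inner_curve, fat_wall_curve, _polyline_resample)
from .elements import tabulate

DENSITY_FACTORS = {"coarse": 1.0, "medium": 1.5, "fine": 2.25}


class MeshingError(RuntimeError):
    pass


@dataclass
class Block:
    """Structured lattice of nodes: shape (nt*k+1, ns*k+1, 2)."""

    lattice: np.ndarray
    order: int

    @property
    def ns(self) -> int:
        return (self.lattice.shape[1] - 1) // self.order

    @property
    def nt(self) -> int:
        return (self.lattice.shape[0] - 1) // self.order

    @property
    def nodes(self) -> np.ndarray:
        return self.lattice.reshape(-1, 2)

    def connectivity(self) -> np.ndarray:
        k = self.order
        ncol = self.lattice.shape[1]
        elems = []
        for jt in range(self.nt):
            for js in range(self.ns):
                ids = [(jt * k + b) * ncol + js * k + a
                       for b in range(k + 1) for a in range(k + 1)]
                elems.append(ids)
        return np.asarray(elems, dtype=np.int64)

    def side(self, which: str) -> np.ndarray:
        """Ordered local node ids along a side: t0, t1, s0, s1."""
        ncol = self.lattice.shape[1]
        nrow = self.lattice.shape[0]
        if which == "t0":
            return np.arange(ncol)
        if which == "t1":
            return np.arange(ncol) + (nrow - 1) * ncol
        if which == "s0":
            return np.arange(nrow) * ncol
        if which == "s1":
            return np.arange(nrow) * ncol + (ncol - 1)
        raise KeyError(which)


def path_edges(path: np.ndarray, order: int) -> np.ndarray:
    """Group an ordered node path into (nedge, order+1) boundary edges."""
    m = len(path) - 1
    if m % order:
        raise ValueError("path length incompatible with element order")
    return np.asarray([path[i * order:(i + 1) * order + 1]
                       for i in range(m // order)])


@dataclass
class MeshModel:
    """Multi-block mesh with region tags, named boundaries and landmarks."""

    geom: GeometryModel
    order: int
    density: str | float
    nodes: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    regions: dict = field(default_factory=dict)      # region -> (E, nn) connectivity
    boundaries: dict = field(default_factory=dict)   # name -> ordered global ids
    landmarks: dict = field(default_factory=dict)    # name -> global node id
    shell_psi: np.ndarray = field(default_factory=lambda: np.zeros(0))
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edges(self, boundary: str) -> np.ndarray:
        return path_edges(self.boundaries[boundary], self.order)

    def region_area(self, name: str) -> float:
        """Plane (r, z) area of a region by quadrature."""
        conn = self.regions[name]
        X = self.nodes[conn]
        _, dNx, dNe, w = tabulate(self.order, self.order + 1)
        area = 0.0
        for g in range(len(w)):
            j11 = X[:, :, 0] @ dNx[g]
            j12 = X[:, :, 0] @ dNe[g]
            j21 = X[:, :, 1] @ dNx[g]
            j22 = X[:, :, 1] @ dNe[g]
            area += w[g] * np.sum(j11 * j22 - j12 * j21)
        return float(area)

    def min_jacobian(self) -> float:
        """Minimum det J over all Gauss points; <= 0 means a tangled mesh."""
        worst = np.inf
        for conn in self.regions.values():
            X = self.nodes[conn]
            _, dNx, dNe, w = tabulate(self.order, self.order + 1)
            for g in range(len(w)):
                det = (X[:, :, 0] @ dNx[g]) * (X[:, :, 1] @ dNe[g]) \
                    - (X[:, :, 0] @ dNe[g]) * (X[:, :, 1] @ dNx[g])
                worst = min(worst, det.min())
        return float(worst)


def _density_factor(density) -> float:
    if isinstance(density, str):
        try:
            return DENSITY_FACTORS[density]
        except KeyError:
            raise MeshingError(f"unknown density {density!r}") from None
    # interpret a float as a target edge length in mm relative to 1 mm coarse
    return max(0.5, 1.0 / float(density))


def shell_psi_grid(geom: GeometryModel, d: float) -> np.ndarray:
    """psi cell-boundary positions with knots at every shell landmark."""
    knots = np.unique([0.0, geom.psi_sas[0], geom.psi_sas[1], geom.psi_canal,
                       np.pi / 2, geom.psi_eom, geom.psi_front, np.pi])
    wide = np.pi - geom.psi_canal
    psi = [0.0]
    for a, b in zip(knots[:-1], knots[1:]):
        # one cell for the narrow posterior-pole strips, density-scaled
        # elsewhere in proportion to the angular span
        n = 1 if b <= geom.psi_canal + 1e-12 else \
            max(2, round(25 * d * (b - a) / wide))
        psi.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(psi)


def mesh_shell(geom: GeometryModel, d: float, order: int,
               inner_axes=None, outer_axes=None) -> Block:
    """Shell block; optional semi-axis overrides mesh a zero-stress shell with
    the same angular layout."""
    p = geom.params
    a_i, b_i = inner_axes if inner_axes else (p.R_Eq, p.R_P)
    a_o, b_o = outer_axes if outer_axes else (p.a_out, p.b_out)
    psi_cells = shell_psi_grid(geom, d)
    k = order
    # nodal psi positions: subdivide each cell k times
    psi_nodes = [psi_cells[0]]
    for a, b in zip(psi_cells[:-1], psi_cells[1:]):
        psi_nodes.extend(np.linspace(a, b, k + 1)[1:])
    psi_nodes = np.asarray(psi_nodes)
    n_h = max(2, round(2 * d))
    # t runs outer -> inner so the (psi, t) parametrisation is positively oriented
    t_nodes = np.linspace(1.0, 0.0, n_h * k + 1)
    inner = ellipse_point(a_i, b_i, psi_nodes)
    outer = ellipse_point(a_o, b_o, psi_nodes)
    lattice = ((1.0 - t_nodes[:, None, None]) * inner[None]
               + t_nodes[:, None, None] * outer[None])
    blk = Block(lattice, order)
    blk.psi_nodes = psi_nodes
    blk.psi_cells = psi_cells
    return blk


def _arc_fraction_at(pts: np.ndarray, idx: int) -> float:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return float(s[idx] / s[-1])


def _arc_fraction_at_z(pts: np.ndarray, z: float) -> float:
    """Arc fraction where a monotone-in-z tail of the curve crosses height z."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    idx = int(np.argmin(np.abs(pts[:, 1] - z)))
    return float(s[idx] / s[-1])


def mesh_fat(geom: GeometryModel, d: float, order: int) -> Block:
    """Transfinite loft of the fat block.

    Inner curve: globe outer surface from the septum ring to the canal, then
    the dural cylinder.  Outer curve: orbital wall from the rim to the apex
    truncation.  The s = 0 loft line is then exactly the straight septum
    (ring -> rim); grid lines are anchored at the canal junction and the
    wall point at the same depth to keep the loft untangled.
    """
    inner, n_globe_pts = fat_inner_curve(geom)
    outer = fat_wall_curve(geom)
    k = order
    n_t = max(3, round(4 * d))
    z_j = inner[n_globe_pts - 1, 1]

    fi = [0.0, _arc_fraction_at(inner, n_globe_pts - 1), 1.0]
    # exact-on-ellipse sampling of the globe part: psi as a function of
    # normalized arc length along the dense polyline
    p = geom.params
    psi_dense = np.linspace(geom.psi_front, geom.psi_canal, n_globe_pts)
    seg_i = np.linalg.norm(np.diff(inner[:n_globe_pts], axis=0), axis=1)
    s_i = np.concatenate([[0.0], np.cumsum(seg_i)])
    s_i /= s_i[-1]
    seg_o = np.linalg.norm(np.diff(outer, axis=0), axis=1)
    so = np.concatenate([[0.0], np.cumsum(seg_o)])
    i_bulge = int(np.argmin(np.linalg.norm(outer - geom.wall[1], axis=1)))
    tail = outer[i_bulge:]
    f_j = (so[i_bulge] + _arc_fraction_at_z(tail, z_j)
           * (so[-1] - so[i_bulge])) / so[-1]
    fo = [0.0, f_j, 1.0]

    n_seg = [max(6, round(18 * d)), max(2, round(5 * d))]
    ci_parts, co_parts = [], []
    for i, ((ai, bi), (ao, bo), n) in enumerate(
            zip(zip(fi[:-1], fi[1:]), zip(fo[:-1], fo[1:]), n_seg)):
        fr = np.linspace(0.0, 1.0, n * k + 1)
        if i:
            fr = fr[1:]
        fr_i = ai + fr * (bi - ai)
        if i == 0:
            # globe part: interpolate psi, evaluate on the exact ellipse
            from .anatomy import ellipse_point as _ep
            psi_s = np.interp(fr_i / fi[1], s_i, psi_dense)
            ci_parts.append(_ep(p.a_out, p.b_out, psi_s))
        else:
            ci_parts.append(_polyline_resample(inner, fr_i))
        co_parts.append(_polyline_resample(outer, ao + fr * (bo - ao)))
    ci = np.vstack(ci_parts)
    co = np.vstack(co_parts)
    t_nodes = np.linspace(0.0, 1.0, n_t * k + 1)
    lattice = ((1.0 - t_nodes[:, None, None]) * ci[None]
               + t_nodes[:, None, None] * co[None])
    blk = Block(lattice, order)
    blk.n_globe_cells = n_seg[0]
    blk.n_nerve_cells = n_seg[-1]
    return blk


def _rect_block(r0, r1, z0, z1, n_r, n_z, order) -> Block:
    rr = np.linspace(r0, r1, n_r * order + 1)
    zz = np.linspace(z0, z1, n_z * order + 1)
    lattice = np.stack(np.meshgrid(rr, zz, indexing="xy") , axis=-1)
    return Block(lattice, order)


def mesh_geometry(geom: GeometryModel, density="coarse", order: int = 2,
                  include_passive: bool = False,
                  shell_inner_axes=None, shell_outer_axes=None) -> MeshModel:
    """Mesh the mechanical domains (shell + fat) and optionally the passive
    optic-nerve blocks.  Raises :class:`MeshingError` for degenerate geometry.
    """
    d = _density_factor(density)
    mesh = MeshModel(geom=geom, order=order, density=density)
    blocks: list[tuple[str, Block]] = []

    shell = mesh_shell(geom, d, order, shell_inner_axes, shell_outer_axes)
    blocks.append(("ocular_coats", shell))
    fat = mesh_fat(geom, d, order)
    blocks.append(("orbital_fat", fat))
    if include_passive:
        p = geom.params
        z_j = -p.b_out * np.cos(geom.psi_canal)
        n_z = max(4, round(6 * d))
        blocks.append(("axon_bundle",
                       _rect_block(0.0, p.R_A, geom.z_apex, z_j, 2, n_z, order)))
        blocks.append(("dura",
                       _rect_block(p.R_Di, p.R_Do, geom.z_apex, z_j, 1, n_z, order)))

    nodes, offsets = [], {}
    off = 0
    for name, blk in blocks:
        offsets[name] = off
        nodes.append(blk.nodes)
        mesh.regions[name] = blk.connectivity() + off
        off += len(blk.nodes)
    mesh.nodes = np.vstack(nodes)

    so = offsets["ocular_coats"]
    # shell lattice rows run outer (t0) -> inner (t1)
    mesh.boundaries["shell_inner"] = shell.side("t1") + so
    mesh.boundaries["shell_outer"] = shell.side("t0") + so
    mesh.shell_psi = shell.psi_nodes
    ncol = shell.lattice.shape[1]
    nrow = shell.lattice.shape[0]
    mesh.landmarks["post_pole_outer"] = so + 0
    mesh.landmarks["ant_pole_outer"] = so + ncol - 1
    mesh.landmarks["post_pole_inner"] = so + (nrow - 1) * ncol
    mesh.landmarks["ant_pole_inner"] = so + nrow * ncol - 1
    i_eom = int(np.argmin(np.abs(shell.psi_nodes - geom.psi_eom)))
    mesh.landmarks["eom_ring"] = so + i_eom
    i_eq = int(np.argmin(np.abs(shell.psi_nodes - np.pi / 2)))
    mesh.landmarks["equator_outer"] = so + i_eq
    # ICP band columns on the outer surface
    in_band = (shell.psi_nodes >= geom.psi_sas[0] - 1e-12) \
        & (shell.psi_nodes <= geom.psi_sas[1] + 1e-12)
    mesh.boundaries["sas_band"] = (shell.side("t0") + so)[in_band]
    if len(mesh.boundaries["sas_band"]) < order + 1:
        raise MeshingError("ICP band not resolved by the shell mesh")
    # shell axis columns (r = 0)
    mesh.meta["shell_axis_nodes"] = np.concatenate(
        [so + np.arange(nrow) * ncol, so + np.arange(nrow) * ncol + ncol - 1])

    fo = offsets["orbital_fat"]
    k = order
    t0 = fat.side("t0") + fo
    n_gn = fat.n_globe_cells * k
    mesh.boundaries["fat_inner_globe"] = t0[: n_gn + 1]
    mesh.boundaries["fat_inner_nerve"] = t0[n_gn:]
    mesh.boundaries["fat_outer"] = fat.side("t1") + fo
    mesh.boundaries["fat_front_stub"] = fat.side("s0") + fo
    mesh.boundaries["fat_back"] = fat.side("s1") + fo
    mesh.landmarks["aperture_ring"] = int(t0[0])
    mesh.meta["offsets"] = offsets

    if mesh.min_jacobian() <= 0.0:
        raise MeshingError("degenerate element (non-positive Jacobian) in mesh")
    return mesh


# ---------------------------------------------------------------------------
# plain-text export (legacy VTK and Gmsh 2.2 ASCII), linearised sub-quads
# ---------------------------------------------------------------------------

def _subquads(mesh: MeshModel):
    k = mesh.order
    quads, tags = [], []
    for rid, (name, conn) in enumerate(mesh.regions.items()):
        for row in conn:
            lat = row.reshape(k + 1, k + 1)
            for j in range(k):
                for i in range(k):
                    quads.append([lat[j, i], lat[j, i + 1],
                                  lat[j + 1, i + 1], lat[j + 1, i]])
                    tags.append(rid)
    return np.asarray(quads), np.asarray(tags), list(mesh.regions)


def write_vtk(mesh: MeshModel, path: str, point_data: dict | None = None):
    quads, tags, names = _subquads(mesh)
    lines = ["# vtk DataFile Version 3.0", "sansfem mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    for r, z in mesh.nodes:
        lines.append(f"{r:.9g} {z:.9g} 0")
    lines.append(f"CELLS {len(quads)} {len(quads) * 5}")
    for q in quads:
        lines.append("4 " + " ".join(map(str, q)))
    lines.append(f"CELL_TYPES {len(quads)}")
    lines.extend(["9"] * len(quads))
    lines.append(f"CELL_DATA {len(quads)}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(t) for t in tags)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                for v in arr:
                    lines.append(f"{v[0]:.9g} {v[1]:.9g} 0")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_msh(mesh: MeshModel, path: str):
    quads, tags, names = _subquads(mesh)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(names))]
    for i, n in enumerate(names):
        lines.append(f'2 {i + 1} "{n}"')
    lines += ["$EndPhysicalNames", "$Nodes", str(mesh.n_nodes)]
    for i, (r, z) in enumerate(mesh.nodes, 1):
        lines.append(f"{i} {r:.9g} {z:.9g} 0")
    lines += ["$EndNodes", "$Elements", str(len(quads))]
    for e, (q, t) in enumerate(zip(quads, tags), 1):
        lines.append(f"{e} 3 2 {t + 1} {t + 1} " + " ".join(str(i + 1) for i in q))
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
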