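"""Outcome measures: proptosis, axial length, peripapillary arc, posterior
radius of curvature (Pratt circle fit), and the axial force-balance report.

All changes are reported for the microgravity state relative to the
terrestrial state on the same mesh, so discretisation error largely cancels
in the differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .elements import lagrange_1d
from .mesh import MeshModel, path_edges


class DegenerateCircleError(ValueError):
    pass


def pratt_circle_fit(points) -> tuple[np.ndarray, float]:
    """Algebraic circle fit with the Pratt normalisation.

    Minimises ``sum (A(x^2+y^2) + Bx + Cy + D)^2`` subject to
    ``B^2 + C^2 - 4AD = 1``; exact for points on a circle and nearly
    unbiased for partial arcs.  Returns (center, radius).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    c0 = pts.mean(axis=0)
    scale = max(np.abs(pts - c0).max(), 1e-12)
    xy = (pts - c0) / scale
    x, y = xy[:, 0], xy[:, 1]
    z = x * x + y * y
    A = np.column_stack([z, x, y, np.ones_like(x)])
    M = A.T @ A / len(x)
    B = np.array([[0.0, 0.0, 0.0, -2.0],
                  [0.0, 1.0, 0.0, 0.0],
                  [0.0, 0.0, 1.0, 0.0],
                  [-2.0, 0.0, 0.0, 0.0]])
    w, V = scipy.linalg.eig(M, B)
    best = None
    for wi, vi in zip(w, V.T):
        if abs(wi.imag) > 1e-8 or not np.isfinite(wi.real):
            continue
        v = vi.real
        nb = v @ B @ v
        if nb <= 0:
            continue
        v = v / np.sqrt(nb)
        eta = wi.real
        if eta < -1e-8:
            continue
        if best is None or eta < best[0]:
            best = (eta, v)
    if best is None:
        raise DegenerateCircleError("no admissible Pratt solution")
    a, b, c, d = best[1]
    if abs(a) < 1e-8:
        raise DegenerateCircleError("points are collinear (infinite radius)")
    center = np.array([-b, -c]) / (2.0 * a)
    radius = np.sqrt(max(b * b + c * c - 4.0 * a * d, 0.0)) / (2.0 * abs(a))
    return center * scale + c0, float(radius * scale)


def _edge_samples(mesh: MeshModel, boundary: str, n_per_edge: int = 10):
    """(xi weights are not needed) reference sample operator along a path.

    Returns (node_ids per edge, shape matrix (m, k+1), number of edges) such
    that sampled points are ``N @ X[edge]`` with duplicate edge joints dropped.
    """
    edges = path_edges(mesh.boundaries[boundary], mesh.order)
    xi = np.linspace(-1.0, 1.0, n_per_edge)
    N, _ = lagrange_1d(mesh.order, xi)
    return edges, N


def sample_boundary(mesh: MeshModel, u: np.ndarray, boundary: str,
                    n_per_edge: int = 10) -> np.ndarray:
    """Deformed sample points along a named boundary path."""
    edges, N = _edge_samples(mesh, boundary, n_per_edge)
    X = mesh.nodes + u.reshape(-1, 2)
    out = []
    for i, e in enumerate(edges):
        pts = N @ X[e]
        out.append(pts if i == len(edges) - 1 else pts[:-1])
    return np.vstack(out)


def posterior_roc(mesh: MeshModel, u: np.ndarray, window: float = 4.0,
                  n_per_edge: int = 12) -> float:
    """Radius of a Pratt fit to the deformed outer sclera within ``window`` mm
    of the symmetry axis (posterior pole region).  Points are mirrored across
    the axis so the fitted circle is centred on it."""
    pts = sample_boundary(mesh, u, "shell_outer", n_per_edge)
    post = pts[: len(pts) // 2]                     # posterior half of the path
    sel = post[np.abs(post[:, 0]) <= window]
    if len(sel) < 3:
        raise ValueError("fewer than 3 surface points in the fit window")
    mirrored = np.vstack([sel, sel * np.array([-1.0, 1.0])])
    _, radius = pratt_circle_fit(mirrored)
    return radius


@dataclass
class ArcStations:
    """Material stations along the inner sclera, fixed at the zero-stress
    state, spanning the posterior-most ``fraction`` of the circumference."""

    edges: np.ndarray
    N: np.ndarray            # (m_total, k+1) stacked per-edge shape rows
    rows_per_edge: int
    n_used: int              # whole stations inside the material segment
    end_frac: float          # fractional part of the final station interval
    fraction: float
    ref_length: float

    @classmethod
    def build(cls, mesh: MeshModel, fraction: float = 0.25,
              n_per_edge: int = 24) -> "ArcStations":
        edges, N = _edge_samples(mesh, "shell_inner", n_per_edge)
        X = mesh.nodes
        pts = []
        for i, e in enumerate(edges):
            p = N @ X[e]
            pts.append(p if i == len(edges) - 1 else p[:-1])
        pts = np.vstack(pts)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        L_half = s[-1]
        # posterior-most quarter of the full circumference == the first
        # fraction*L_half of the half-plane arc, measured from the pole
        s_end = fraction * L_half
        i_end = int(np.clip(np.searchsorted(s, s_end), 2, len(s) - 1))
        end_frac = (s_end - s[i_end - 1]) / max(s[i_end] - s[i_end - 1],
                                                1e-30)
        return cls(edges=edges, N=N, rows_per_edge=n_per_edge,
                   n_used=i_end, end_frac=float(np.clip(end_frac, 0.0, 1.0)),
                   fraction=fraction, ref_length=s_end)

    def deformed_length(self, mesh: MeshModel, u: np.ndarray) -> float:
        X = mesh.nodes + u.reshape(-1, 2)
        pts = []
        for i, e in enumerate(self.edges):
            p = self.N @ X[e]
            pts.append(p if i == len(self.edges) - 1 else p[:-1])
        pts = np.vstack(pts)[: self.n_used + 1]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return float(seg[:-1].sum() + self.end_frac * seg[-1])


def peripapillary_arc(mesh: MeshModel, u: np.ndarray,
                      fraction: float = 0.25,
                      stations: ArcStations | None = None) -> float:
    """Deformed arc length (mm) of the posterior material segment."""
    if stations is None or stations.fraction != fraction:
        stations = ArcStations.build(mesh, fraction)
    return stations.deformed_length(mesh, u)


def axial_measures(mesh: MeshModel, u_D: np.ndarray, u_C: np.ndarray):
    """(proptosis mm, delta axial length um), microgravity minus terrestrial.

    Proptosis is the anterior-pole axial displacement; axial length is the
    pole-to-pole extent of the outer shell surface.
    """
    ant = mesh.landmarks["ant_pole_outer"]
    post = mesh.landmarks["post_pole_outer"]
    proptosis = u_D[2 * ant + 1] - u_C[2 * ant + 1]
    al_D = u_D[2 * ant + 1] - u_D[2 * post + 1]
    al_C = u_C[2 * ant + 1] - u_C[2 * post + 1]
    return float(proptosis), float((al_D - al_C) * 1e3)


@dataclass
class BiometricReport:
    eps_H_fat: float
    J_H_fat: float
    proptosis_mm: float
    delta_axial_length_um: float
    delta_arc_um: float
    delta_roc_mm: float
    F_EOM_mN: float
    F_ICP_mN: float
    F_fat_mN: float
    F_ON_mN: float
    IOP_mmHg: float
    balance_residual_mN: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)
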