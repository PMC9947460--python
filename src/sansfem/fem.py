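"""Axisymmetric geometrically nonlinear equilibrium solver.

Total-Lagrangian displacement formulation on the multi-block mesh.  The five
axisymmetric deformation-gradient components are linear in the nodal
displacements, so the exact tangent is B^T A B with A the pointwise material
Hessian.  Elastic incompressibility is enforced by the penalty bulk term
integrated on a reduced Gauss rule (selective reduced integration), which
avoids volumetric locking without a mixed formulation.

Load terms:

* vitreous cavity -- uniform pressure chamber on the shell inner surface,
  either volume-constrained (prescribed hygroscopic volume ratio ``J_Hv``,
  water-like volumetric stiffness) or direct prescribed pressure;
* ICP band -- follower pressure on the subarachnoid annulus of the sclera;
* EOM ring -- nonlinear axial tension law at the insertion ring node;
* sclera-fat interface -- frictionless node-to-segment penalty contact;
* septum / nerve / wall -- slip-plane penalties and fixed boundaries.

Forces are in uN (Pa * mm^2), lengths in mm, pressures in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as law
from .elements import tabulate, tabulate_edge
from .loads import eom_force, eom_force_derivative
from .mesh import MeshModel, path_edges

#: volumetric stiffness of the vitreous chamber (water-like bulk modulus, Pa)
KAPPA_VITREOUS = 2.2e8
#: contact penalty stiffness, Pa/mm of penetration
KAPPA_CONTACT = 2.0e4
#: slip-plane penalty stiffness, Pa/mm
KAPPA_SLIP = 1.0e8
#: augmented-Lagrangian penalty ratio (kappa/mu) for the fat
AUG_RATIO = 1000.0


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, history=None, fraction=None):
        super().__init__(msg)
        self.history = history or []
        self.fraction = fraction


class InversionError(FloatingPointError):
    pass


@dataclass
class StepParams:
    """Load parameters at one equilibrium point."""

    J_Hv: float | None = None   # vitreous volume ratio (swelling IOP mode)
    IOP: float | None = None    # direct vitreous pressure, Pa (fallback mode)
    ICP: float = 0.0            # Pa
    M: float = 0.0              # EOM multiplier
    eps_fat: float = 0.0        # fat hygroscopic strain
    eom_on: bool = False

    def blend(self, other: "StepParams", lam: float) -> "StepParams":
        def mix(a, b):
            if a is None:
                return b
            if b is None:
                return a
            return a + lam * (b - a)
        return StepParams(J_Hv=mix(self.J_Hv, other.J_Hv),
                          IOP=mix(self.IOP, other.IOP),
                          ICP=mix(self.ICP, other.ICP),
                          M=mix(self.M, other.M),
                          eps_fat=mix(self.eps_fat, other.eps_fat),
                          eom_on=other.eom_on)


@dataclass
class SolutionState:
    """Converged equilibrium: displacements plus load bookkeeping."""

    u: np.ndarray
    params: StepParams
    iterations: int = 0
    residual_norm: float = 0.0
    contact_active: int = 0
    forces: dict = field(default_factory=dict)   # axial resultants, mN


def _region_quadrature(nodes, conn, order, npts):
    """Precompute B operators and weights for one region and Gauss rule."""
    N, dNx, dNe, w = tabulate(order, npts)
    X = nodes[conn]                      # (E, nn, 2)
    E, nn = conn.shape
    ngp = len(w)
    B = np.zeros((ngp, E, 2 * nn, 5))
    wdet = np.zeros((ngp, E))
    for g in range(ngp):
        j11 = X[:, :, 0] @ dNx[g]
        j12 = X[:, :, 0] @ dNe[g]
        j21 = X[:, :, 1] @ dNx[g]
        j22 = X[:, :, 1] @ dNe[g]
        det = j11 * j22 - j12 * j21
        if np.any(det <= 0):
            raise InversionError("non-positive reference Jacobian")
        i11, i12 = j22 / det, -j12 / det
        i21, i22 = -j21 / det, j11 / det
        dNdR = dNx[g][None, :] * i11[:, None] + dNe[g][None, :] * i21[:, None]
        dNdZ = dNx[g][None, :] * i12[:, None] + dNe[g][None, :] * i22[:, None]
        R = X[:, :, 0] @ N[g]
        B[g, :, 0::2, 0] = dNdR
        B[g, :, 0::2, 1] = dNdZ
        B[g, :, 1::2, 2] = dNdR
        B[g, :, 1::2, 3] = dNdZ
        B[g, :, 0::2, 4] = N[g][None, :] / R[:, None]
        wdet[g] = w[g] * det * 2.0 * np.pi * R
    dofmap = np.empty((E, 2 * nn), dtype=np.int64)
    dofmap[:, 0::2] = 2 * conn
    dofmap[:, 1::2] = 2 * conn + 1
    return {"B": B, "wdet": wdet, "dofmap": dofmap,
            "rows": np.repeat(dofmap, 2 * nn, axis=1),
            "cols": np.tile(dofmap, (1, 2 * nn))}


class FemModel:
    """Assembled axisymmetric model over the mechanical regions of a mesh."""

    F0 = np.array([1.0, 0.0, 0.0, 1.0, 1.0])

    def __init__(self, mesh: MeshModel, tissues: dict, *,
                 with_fat: bool | None = None,
                 pin_pole: bool = False,
                 kappa_contact: float = KAPPA_CONTACT):
        self.mesh = mesh
        self.tissues = tissues
        self.ndof = 2 * mesh.n_nodes
        self.kappa_contact = kappa_contact
        self.tie_gap_tol = 2e-3   # mm, augmented-tie gap tolerance
        self.tie_margin = 1.5     # mm, untied fat sliver at the septum ring
        self.verbose = False
        self.stiff_band = 0.01  # mm; gap below which contact stiffness engages
        if with_fat is None:
            with_fat = "orbital_fat" in mesh.regions
        self.with_fat = with_fat and "orbital_fat" in mesh.regions

        order = mesh.order
        self.bulk = []
        for name in (["ocular_coats"] + (["orbital_fat"] if self.with_fat else [])):
            conn = mesh.regions[name]
            reg = {
                "name": name,
                "props": tissues[name],
                "dev": _region_quadrature(mesh.nodes, conn, order, order + 1),
                "vol": _region_quadrature(mesh.nodes, conn, order, max(1, order)),
                "swell_mask": None,
                "augmented": name == "orbital_fat",
            }
            if name == "orbital_fat":
                nE = reg["vol"]["B"].shape[1]
                # elementwise pressure multipliers (augmented Lagrangian with
                # mean dilatation: one volumetric constraint per element)
                reg["press"] = np.zeros(nE)
                reg["Vref"] = reg["vol"]["wdet"].sum(axis=0)
                # only retrobulbar fat (behind the orbital-rim plane) swells;
                # the pre-septal compartment in front of the rim does not take
                # part in the cephalad fluid shift
                cz = mesh.nodes[conn, 1].mean(axis=1)
                reg["swell_mask"] = cz <= mesh.geom.z_rim
            self.bulk.append(reg)

        # ---- cavity (shell inner surface) ----
        self.cav_edges = mesh.edges("shell_inner")
        self.Ne, self.dNe_, self.we = tabulate_edge(order, order + 2)

        # ---- ICP band ----
        self.band_edges = path_edges(mesh.boundaries["sas_band"], order)

        # ---- EOM ring ----
        self.eom_node = mesh.landmarks["eom_ring"]
        self.eom_ref = 0.0

        # ---- Dirichlet sets ----
        fixed = np.zeros(self.ndof, dtype=bool)
        axis = mesh.meta["shell_axis_nodes"]
        fixed[2 * axis] = True                        # u_r = 0 on the axis
        if pin_pole:
            fixed[2 * mesh.landmarks["post_pole_outer"] + 1] = True
        active = {r["name"] for r in self.bulk}
        for name, conn in mesh.regions.items():
            if name not in active:     # passive blocks (nerve) or disabled fat
                ids = np.unique(conn)
                fixed[2 * ids] = True
                fixed[2 * ids + 1] = True
        self.slip_nodes = np.zeros((0,), dtype=np.int64)
        self.slip_normals = np.zeros((0, 2))
        self.slip_weights = np.zeros(0)
        self.slaves = np.zeros((0,), dtype=np.int64)
        if self.with_fat:
            for b in ("fat_outer", "fat_back"):
                ids = mesh.boundaries[b]
                fixed[2 * ids] = True
                fixed[2 * ids + 1] = True
            nerve = mesh.boundaries["fat_inner_nerve"]
            fixed[2 * nerve] = True                   # u_r = 0 on the dural cylinder
            # septum face: fat adheres to the fibrous septum (fixed) except
            # for a short frictionless stub next to the ring, where the
            # boundary must slide over the advancing globe
            stub = mesh.boundaries["fat_front_stub"]
            ring, rim = mesh.geom.septum
            d = rim - ring
            n = np.array([d[1], -d[0]]) / np.linalg.norm(d)
            dist = np.linalg.norm(mesh.nodes[stub] - ring, axis=1)
            slip_len = mesh.geom.params.septum_slip_length
            far = stub[dist > slip_len]
            fixed[2 * far] = True
            fixed[2 * far + 1] = True
            free_stub = stub[(dist <= slip_len)
                             & ~(fixed[2 * stub] & fixed[2 * stub + 1])]
            self.slip_nodes = free_stub
            self.slip_normals = np.tile(n, (len(free_stub), 1))
            self.slip_weights = np.full(len(free_stub), 1.0)
            # contact slaves: fat inner boundary along the globe, with
            # lumped tributary areas; a short sliver next to the septum ring
            # is left untied (fornix recess) so the pinched corner can
            # deform freely under the large interface sliding
            path = mesh.boundaries["fat_inner_globe"]
            w_all = self._lumped_boundary_weights(path)
            ring = mesh.geom.septum[0]
            dist = np.linalg.norm(mesh.nodes[path] - ring, axis=1)
            keep = dist > self.tie_margin
            self.slaves = path[keep]
            self.slave_w = w_all[keep]
            # master: outer shell edges, each subdivided through its shape
            # functions so the discrete master follows the curved surface to
            # sub-micron sagitta
            from .elements import lagrange_1d
            self.master_edges = path_edges(mesh.boundaries["shell_outer"],
                                           mesh.order)
            msub = 8
            xi = np.linspace(-1.0, 1.0, msub + 1)
            self.master_S, _ = lagrange_1d(mesh.order, xi)   # (msub+1, k+1)
            self.msub = msub
            # augmented-Lagrangian normal-traction multipliers (Pa)
            self.tie_lambda = np.zeros(len(self.slaves))
        self.fixed = fixed
        self.free = ~fixed
        self.cavity_V0 = self.cavity_volume(np.zeros(self.ndof))

    # ------------------------------------------------------------------
    def _lumped_boundary_weights(self, path):
        edges = path_edges(path, self.mesh.order)
        w = np.zeros(self.mesh.n_nodes)
        X = self.mesh.nodes
        for e in edges:
            xe = X[e]
            for g in range(len(self.we)):
                dx = self.dNe_[g] @ xe
                r = self.Ne[g] @ xe[:, 0]
                ds = np.hypot(*dx)
                w[e] += self.we[g] * self.Ne[g] * 2.0 * np.pi * r * ds
        return w[path]

    # ------------------------------------------------------------------
    # energy / residual / tangent pieces
    # ------------------------------------------------------------------
    def _bulk_terms(self, u, params, want_K):
        rows, cols, vals = [], [], []
        R = np.zeros(self.ndof)
        E = 0.0
        for reg in self.bulk:
            props = reg["props"]
            mu, kappa = props.mu, props.kappa
            J_H = 1.0
            if reg["name"] == "orbital_fat" and params.eps_fat:
                J_full = (1.0 + params.eps_fat) ** 3
                mask = reg["swell_mask"]
                J_H = np.where(mask, J_full, 1.0) if mask is not None else J_full
            for part, fn, coef in (("dev", law.axisym_dev, mu),
                                   ("vol", law.axisym_vol, kappa)):
                q = reg[part]
                B, wdet, dofmap = q["B"], q["wdet"], q["dofmap"]
                ue = u[dofmap]                       # (E, 2nn)
                f = self.F0 + np.einsum("geai,ea->gei", B, ue)
                Jloc = (f[..., 0] * f[..., 3] - f[..., 1] * f[..., 2]) * f[..., 4]
                if np.any(Jloc <= 0):
                    raise InversionError(f"element inversion in {reg['name']}")
                if part == "vol" and reg["augmented"]:
                    # mean dilatation + augmented Lagrangian: a single
                    # volumetric constraint per element avoids both locking
                    # and pressure checkerboarding in the soft fat
                    ka = AUG_RATIO * mu
                    JH_e = np.broadcast_to(
                        np.asarray(J_H, dtype=float), (wdet.shape[1],))
                    Vref = reg["Vref"]
                    Jbar = np.einsum("ge,ge->e", Jloc, wdet) / Vref
                    e_vol = Jbar / JH_e - 1.0
                    pr = reg["press"]
                    coef1 = pr + ka * e_vol                       # (E,)
                    dJ = law._djac(f)
                    dJdu = np.einsum("geai,gei->gea", B, dJ)
                    G = np.einsum("ge,gea->ea", wdet, dJdu)  # Vref dJbar/du
                    E += float(np.sum(Vref * (pr * (Jbar - JH_e)
                               + 0.5 * ka * JH_e * e_vol ** 2)))
                    np.add.at(R, dofmap, coef1[:, None] * G)
                    if want_K:
                        d2J = law._d2jac(f)
                        Kgeo = np.einsum("geai,geij,gebj,ge->eab", B, d2J, B,
                                         wdet, optimize=True)
                        Ke = (ka / (JH_e * Vref))[:, None, None] \
                            * G[:, :, None] * G[:, None, :] \
                            + coef1[:, None, None] * Kgeo
                        rows.append(q["rows"])
                        cols.append(q["cols"])
                        vals.append(Ke.reshape(len(Ke), -1))
                    continue
                W, P, A = fn(f, coef, J_H)
                E += float(np.einsum("ge,ge->", W, wdet))
                re = np.einsum("geai,gei,ge->ea", B, P, wdet)
                np.add.at(R, dofmap, re)
                if want_K:
                    Ke = np.einsum("geai,geij,gebj,ge->eab", B, A, B, wdet,
                                   optimize=True)
                    rows.append(q["rows"])
                    cols.append(q["cols"])
                    vals.append(Ke.reshape(len(Ke), -1))
        return E, R, rows, cols, vals

    def cavity_volume(self, u):
        X = self.mesh.nodes + u.reshape(-1, 2)
        V = 0.0
        for e in self.cav_edges:
            xe = X[e]
            for g in range(len(self.we)):
                r = self.Ne[g] @ xe[:, 0]
                zp = self.dNe_[g] @ xe[:, 1]
                V += self.we[g] * np.pi * r * r * zp
        return V

    def _cavity_terms(self, u, params, want_K):
        """Returns (p, dEdV, d2EdV2, Vp, edge hessian triplets)."""
        X = self.mesh.nodes + u.reshape(-1, 2)
        V = 0.0
        Vp = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        k1 = self.mesh.order + 1
        for e in self.cav_edges:
            xe = X[e]
            dr_dofs = 2 * e
            dz_dofs = 2 * e + 1
            H = np.zeros((2 * k1, 2 * k1))
            for g in range(len(self.we)):
                wg = self.we[g] * np.pi
                r = self.Ne[g] @ xe[:, 0]
                zp = self.dNe_[g] @ xe[:, 1]
                V += wg * r * r * zp
                Vp[dr_dofs] += wg * 2.0 * r * zp * self.Ne[g]
                Vp[dz_dofs] += wg * r * r * self.dNe_[g]
                if want_K:
                    H[:k1, :k1] += wg * 2.0 * zp * np.outer(self.Ne[g], self.Ne[g])
                    blk = wg * 2.0 * r * np.outer(self.Ne[g], self.dNe_[g])
                    H[:k1, k1:] += blk
                    H[k1:, :k1] += blk.T
            if want_K:
                dofs = np.concatenate([dr_dofs, dz_dofs])
                rows.append(np.repeat(dofs, 2 * k1))
                cols.append(np.tile(dofs, 2 * k1))
                vals.append(H.ravel())
        if params.IOP is not None:
            p = params.IOP
            dEdV, d2EdV2 = -p, 0.0
            E = -p * V
        else:
            J_Hv = 1.0 if params.J_Hv is None else params.J_Hv
            Vt = J_Hv * self.cavity_V0
            dEdV = KAPPA_VITREOUS * (V - Vt) / Vt
            d2EdV2 = KAPPA_VITREOUS / Vt
            p = -dEdV
            E = 0.5 * KAPPA_VITREOUS * (V - Vt) ** 2 / Vt
        return E, p, V, dEdV, d2EdV2, Vp, (rows, cols, vals)

    def _band_terms(self, u, p_icp, want_K):
        """Follower external pressure on the SAS band; returns F_ext and
        its (nonsymmetric) load stiffness triplets, plus the axial resultant."""
        X = self.mesh.nodes + u.reshape(-1, 2)
        F = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        k1 = self.mesh.order + 1
        Fz_total = 0.0
        Vband = 0.0
        for e in self.band_edges:
            xe = X[e]
            dr, dz = 2 * e, 2 * e + 1
            dofs = np.concatenate([dr, dz])
            Kl = np.zeros((2 * k1, 2 * k1))
            for g in range(len(self.we)):
                w2 = self.we[g] * 2.0 * np.pi * p_icp
                N, dN = self.Ne[g], self.dNe_[g]
                r = N @ xe[:, 0]
                rp = dN @ xe[:, 0]
                zp = dN @ xe[:, 1]
                F[dr] += -w2 * N * zp * r
                F[dz] += +w2 * N * rp * r
                Fz_total += w2 * rp * r
                Vband += self.we[g] * np.pi * r * r * zp
                if want_K:
                    # dF_r/dr_b, dF_r/dz_b, dF_z/dr_b, dF_z/dz_b
                    Kl[:k1, :k1] += -w2 * zp * np.outer(N, N)
                    Kl[:k1, k1:] += -w2 * r * np.outer(N, dN)
                    Kl[k1:, :k1] += +w2 * (r * np.outer(N, dN)
                                           + rp * np.outer(N, N))
            if want_K:
                rows.append(np.repeat(dofs, 2 * k1))
                cols.append(np.tile(dofs, 2 * k1))
                vals.append(Kl.ravel())
        # approximate potential of the band pressure (end terms neglected);
        # used only by the line search
        return p_icp * Vband, F, (rows, cols, vals), Fz_total

    def _project_contact(self, u):
        """Closest-point projection of every slave onto the curved master
        (outer shell) surface; stores frozen (edge, parameter, normal) data
        used by the tie until the next refresh.  Freezing the projection
        within a Newton iteration keeps the line-search energy smooth while
        sliding remains free across iterations."""
        if not self.with_fat or len(self.slaves) == 0:
            return
        X = self.mesh.nodes + u.reshape(-1, 2)
        xs = X[self.slaves]
        S = self.master_S
        Xe = X[self.master_edges]
        V = np.einsum("sa,eai->esi", S, Xe)
        seg0 = V[:, :-1, :].reshape(-1, 2)
        seg1 = V[:, 1:, :].reshape(-1, 2)
        d = seg1 - seg0
        L2 = np.maximum(np.sum(d * d, axis=1), 1e-30)
        seg_n = np.stack([d[:, 1], -d[:, 0]], axis=1) / np.sqrt(L2)[:, None]
        diff = xs[:, None, :] - seg0[None, :, :]
        t = np.clip(np.einsum("smi,mi->sm", diff, d) / L2[None, :], 0.0, 1.0)
        proj = seg0[None] + t[..., None] * d[None]
        dist2 = np.sum((xs[:, None, :] - proj) ** 2, axis=2)
        jbest = np.argmin(dist2, axis=1)
        msub = self.msub
        ns = len(self.slaves)
        e_idx, sub = np.divmod(jbest, msub)
        tt = t[np.arange(ns), jbest]
        wts = (1.0 - tt)[:, None] * S[sub] + tt[:, None] * S[sub + 1]
        self._ctc = {"e_idx": e_idx, "wts": wts,
                     "n": seg_n[jbest]}

    def _contact_terms(self, u, want_K):
        """Frictionless sclera-fat slip tie (bilateral normal-gap penalty).

        Uses the frozen projection from :meth:`_project_contact`; the gap is
        the frozen-normal component of the offset to the projected master
        point, so tangential sliding is unconstrained and the interface
        carries normal traction only.  The interface stays compressed under
        the swelling protocol (reported for verification).
        """
        R = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        Fz_on_shell = 0.0
        n_active = 0
        E = 0.0
        if not self.with_fat or len(self.slaves) == 0:
            return E, R, (rows, cols, vals), Fz_on_shell, n_active
        if getattr(self, "_ctc", None) is None:
            self._project_contact(u)
        X = self.mesh.nodes + u.reshape(-1, 2)
        ctc = self._ctc
        kc = self.kappa_contact
        for i, s_id in enumerate(self.slaves):
            enodes = self.master_edges[ctc["e_idx"][i]]
            wts = ctc["wts"][i]
            n = ctc["n"][i]
            x0 = wts @ X[enodes]
            g = (X[s_id] - x0) @ n
            if g < 0.0:
                n_active += 1
            w = self.slave_w[i]
            lam_i = self.tie_lambda[i]
            E += w * (lam_i * g + 0.5 * kc * g * g)
            fvec = w * (lam_i + kc * g) * n
            R[2 * s_id: 2 * s_id + 2] += fvec
            R[2 * enodes] += -wts * fvec[0]
            R[2 * enodes + 1] += -wts * fvec[1]
            Fz_on_shell += fvec[1]                 # force on shell: +fvec
            if want_K:
                nn_ = kc * w * np.outer(n, n)
                coef = np.concatenate([[1.0], -wts])
                nds = np.concatenate([[s_id], enodes])
                nblk = len(nds)
                blk = (coef[:, None, None, None] * coef[None, :, None, None]
                       * nn_[None, None, :, :])
                dofs = np.stack([2 * nds, 2 * nds + 1], axis=1).reshape(-1)
                full = np.zeros((2 * nblk, 2 * nblk))
                for a in range(nblk):
                    for b in range(nblk):
                        full[2 * a: 2 * a + 2, 2 * b: 2 * b + 2] = blk[a, b]
                rows.append(np.repeat(dofs, 2 * nblk))
                cols.append(np.tile(dofs, 2 * nblk))
                vals.append(full.ravel())
        return E, R, (rows, cols, vals), Fz_on_shell, n_active

    def _slip_terms(self, u, want_K):
        R = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        E = 0.0
        if len(self.slip_nodes) == 0:
            return E, R, (rows, cols, vals)
        uu = u.reshape(-1, 2)
        for nid, n, w in zip(self.slip_nodes, self.slip_normals,
                             self.slip_weights):
            gn = uu[nid] @ n
            E += 0.5 * KAPPA_SLIP * w * gn * gn
            R[2 * nid: 2 * nid + 2] += KAPPA_SLIP * w * gn * n
            if want_K:
                blk = KAPPA_SLIP * w * np.outer(n, n)
                rows.append(np.repeat([2 * nid, 2 * nid + 1], 2))
                cols.append(np.tile([2 * nid, 2 * nid + 1], 2))
                vals.append(blk.ravel())
        return E, R, (rows, cols, vals)

    # ------------------------------------------------------------------
    def assemble(self, u, params: StepParams, want_K=True,
                 refresh_contact=True):
        if refresh_contact:
            self._project_contact(u)
        E, R, rows, cols, vals = self._bulk_terms(u, params, want_K)
        forces = {}

        Ec, p, V, dEdV, d2EdV2, Vp, cav_tr = self._cavity_terms(
            u, params, want_K)
        E += Ec
        R += dEdV * Vp
        forces["IOP_Pa"] = p
        forces["cavity_V"] = V
        if want_K:
            r2, c2, v2 = cav_tr
            rows += [np.asarray(r) for r in r2]
            cols += [np.asarray(c) for c in c2]
            vals += [dEdV * np.asarray(v) for v in v2]
            if d2EdV2:
                nz = np.nonzero(Vp)[0]
                rows.append(np.repeat(nz, len(nz)))
                cols.append(np.tile(nz, len(nz)))
                vals.append(d2EdV2 * np.outer(Vp[nz], Vp[nz]).ravel())

        if params.ICP:
            Eb, Fb, band_tr, Fz_icp = self._band_terms(u, params.ICP, want_K)
            E += Eb
            R -= Fb
            forces["F_ICP_mN"] = Fz_icp * 1e-3
            if want_K:
                r2, c2, v2 = band_tr
                rows += r2
                cols += c2
                vals += [-np.asarray(v) for v in v2]
        else:
            forces["F_ICP_mN"] = 0.0

        Ect, Rc, con_tr, Fz_fat, n_active = self._contact_terms(u, want_K)
        E += Ect
        R += Rc
        forces["F_fat_mN"] = Fz_fat * 1e-3
        forces["contact_active"] = n_active
        if want_K:
            r2, c2, v2 = con_tr
            rows += r2
            cols += c2
            vals += v2

        Es, Rs, slip_tr = self._slip_terms(u, want_K)
        E += Es
        R += Rs
        if want_K:
            r2, c2, v2 = slip_tr
            rows += r2
            cols += c2
            vals += v2

        if params.eom_on:
            w_ins = u[2 * self.eom_node + 1] - self.eom_ref
            F = eom_force(w_ins, params.M) * 1e3          # uN, posterior
            # potential of the tension law, int F dw
            E += 4.0 * params.M * 1e3 * (
                -0.145 * w_ins ** 2
                + 4.79 * 4.57 * (np.exp(w_ins / 4.57) - 1.0)
                - 3.01 * w_ins)
            R[2 * self.eom_node + 1] += F
            forces["F_EOM_mN"] = F * 1e-3
            forces["eom_w"] = w_ins
            if want_K:
                rows.append(np.array([2 * self.eom_node + 1]))
                cols.append(np.array([2 * self.eom_node + 1]))
                vals.append(np.array(
                    [eom_force_derivative(w_ins, params.M) * 1e3]))
        else:
            forces["F_EOM_mN"] = 0.0
            forces["eom_w"] = 0.0
        forces["energy"] = E

        K = None
        if want_K:
            rows = np.concatenate([np.asarray(r).ravel() for r in rows])
            cols = np.concatenate([np.asarray(c).ravel() for c in cols])
            vals = np.concatenate([np.asarray(v).ravel() for v in vals])
            K = sp.csr_matrix((vals, (rows, cols)),
                              shape=(self.ndof, self.ndof))
        return R, K, forces

    # ------------------------------------------------------------------
    def solve_equilibrium(self, params: StepParams,
                          u0: np.ndarray | None = None,
                          max_iter: int = 60, rtol: float = 1e-8,
                          atol: float = 2.0,
                          step_cap: float | None = None) -> SolutionState:
        """Damped Newton: frozen-projection ties per iteration, energy
        (Armijo) line search, Levenberg-Marquardt fallback."""
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        u[self.fixed] = 0.0
        free = self.free
        history = []
        norm0 = None
        if step_cap is None:
            step_cap = 1.0 if self.with_fat else 10.0
        lam = 0.0
        ident = sp.identity(self.ndof, format="csr")
        # projections are frozen for the whole solve: the tie functional is
        # then smooth and Newton converges quadratically; the ~um error from
        # sliding within one load step is re-projected at the next solve
        self._project_contact(u)
        for it in range(max_iter):
            try:
                R, K, forces = self.assemble(u, params, refresh_contact=False)
            except InversionError as exc:
                if it == 0:
                    # bad initial guess (e.g. an extrapolated predictor)
                    raise NonConvergenceError(str(exc), history) from exc
                raise
            E = forces["energy"]
            rn = np.linalg.norm(R[free])
            history.append(rn)
            if norm0 is None:
                norm0 = max(rn, atol)
            if rn <= max(rtol * norm0, atol):
                return SolutionState(u=u, params=params, iterations=it,
                                     residual_norm=rn,
                                     contact_active=forces["contact_active"],
                                     forces=forces)
            accepted = False
            for _ in range(8):                      # LM escalation
                Ksys = K if lam == 0.0 else K + lam * ident
                Kff = Ksys[free][:, free].tocsc()
                du = np.zeros(self.ndof)
                try:
                    du[free] = spla.spsolve(Kff, -R[free])
                except Exception:
                    du[free] = np.nan
                slope = float(R[free] @ du[free])
                if not np.all(np.isfinite(du)) or slope > 0:
                    lam = max(10.0 * lam, 1.0)
                    continue
                dmax = np.abs(du).max()
                alpha = min(1.0, step_cap / dmax) if dmax > 0 else 1.0
                slack = 1e-8 * abs(E) + 1e-4
                ok = False
                for _bt in range(10):
                    try:
                        u_try = u + alpha * du
                        _, _, f_t = self.assemble(u_try, params, want_K=False,
                                                  refresh_contact=False)
                    except InversionError:
                        alpha *= 0.25
                        continue
                    E_t = f_t["energy"]
                    if np.isfinite(E_t) and \
                            E_t <= E + 1e-4 * alpha * slope + slack:
                        ok = True
                        break
                    alpha *= 0.5
                if ok:
                    u = u_try
                    lam = lam / 3.0 if lam > 1.0 else 0.0
                    accepted = True
                    if self.verbose:
                        print(f"  nt {it:3d} rn={rn:.3e} lam={lam:.1e} "
                              f"alpha={alpha:.3f} E={E_t:.6e}")
                    break
                lam = max(10.0 * lam, 1.0)
            if not accepted:
                raise NonConvergenceError(
                    "line search failed at all damping levels", history)
        raise NonConvergenceError(
            f"Newton did not converge in {max_iter} iterations "
            f"(last residual {history[-1]:.3e})", history)

    # ------------------------------------------------------------------
    def _fat_J_error(self, u, params):
        """Max |J/J_H - 1| over the fat volumetric Gauss points (and the
        pointwise field, for multiplier updates)."""
        out = []
        for reg in self.bulk:
            if not reg["augmented"]:
                continue
            J_H = 1.0
            if params.eps_fat:
                J_full = (1.0 + params.eps_fat) ** 3
                mask = reg["swell_mask"]
                J_H = np.where(mask, J_full, 1.0) if mask is not None \
                    else J_full
            q = reg["vol"]
            ue = u[q["dofmap"]]
            f = self.F0 + np.einsum("geai,ea->gei", q["B"], ue)
            Jloc = (f[..., 0] * f[..., 3] - f[..., 1] * f[..., 2]) * f[..., 4]
            Jbar = np.einsum("ge,ge->e", Jloc, q["wdet"]) / reg["Vref"]
            JH_e = np.broadcast_to(np.asarray(J_H, dtype=float), Jbar.shape)
            out.append((reg, Jbar / JH_e - 1.0))
        if not out:
            return 0.0, []
        return max(float(np.abs(e).max()) for _, e in out), out

    def solve_augmented(self, params: StepParams,
                        u0: np.ndarray | None = None,
                        n_aug: int = 20, tol_J: float = 1e-3,
                        **kw) -> SolutionState:
        """Equilibrium with augmented-Lagrangian incompressibility of the
        fat: moderate volumetric penalty keeps Newton well conditioned;
        outer multiplier updates drive the elastic volume error below
        ``tol_J``."""
        st = self.solve_equilibrium(params, u0, **kw)
        err, fields = self._fat_J_error(st.u, params)
        gerr = self._tie_gap_update(st.u, apply=False)
        stall = 0
        for _ in range(n_aug):
            if (err <= tol_J or not fields) and gerr <= self.tie_gap_tol:
                break
            for reg, e in fields:
                reg["press"] += AUG_RATIO * reg["props"].mu * e
            self._tie_gap_update(st.u, apply=True)
            st = self.solve_equilibrium(params, st.u, **kw)
            err_new, fields = self._fat_J_error(st.u, params)
            gerr = self._tie_gap_update(st.u, apply=False)
            # the multiplier iteration saturates at local corner
            # incompatibilities; stop once progress stalls
            stall = stall + 1 if err_new > 0.9 * err else 0
            err = err_new
            if stall >= 3:
                break
        st.forces["fat_J_error"] = err
        st.forces["tie_gap_max"] = gerr
        return st

    def _tie_gap_update(self, u, apply: bool) -> float:
        """Max |normal gap| over the slip ties; optionally performs the
        augmented-Lagrangian multiplier update."""
        if not self.with_fat or len(self.slaves) == 0:
            return 0.0
        self._project_contact(u)
        X = self.mesh.nodes + u.reshape(-1, 2)
        ctc = self._ctc
        gmax = 0.0
        for i, s_id in enumerate(self.slaves):
            enodes = self.master_edges[ctc["e_idx"][i]]
            x0 = ctc["wts"][i] @ X[enodes]
            g = (X[s_id] - x0) @ ctc["n"][i]
            gmax = max(gmax, abs(g))
            if apply:
                self.tie_lambda[i] += self.kappa_contact * g
        return gmax

    # ------------------------------------------------------------------
    def step_continuation(self, schedule: list[StepParams],
                          u0: np.ndarray | None = None,
                          start: StepParams | None = None,
                          max_bisect: int = 10, **kw) -> list[SolutionState]:
        """Path-following solve; bisects a failing step up to ``max_bisect``.

        ``start`` names the load state of ``u0`` (defaults to the unloaded
        state) so a failing first step can be sub-divided too.
        """
        states: list[SolutionState] = []
        u = np.zeros(self.ndof) if u0 is None else u0.copy()
        u_prev = None
        prev = start if start is not None else StepParams()
        for i, target in enumerate(schedule):
            # secant predictor: extrapolate the previous increment
            guess = u if u_prev is None else u + (u - u_prev)
            u_prev = u
            try:
                st = self.solve_augmented(target, guess, **kw)
            except NonConvergenceError:
                try:
                    st = self.solve_augmented(target, u, **kw)
                except NonConvergenceError:
                    st = self._bisect(prev, target, u, max_bisect, i, **kw)
            states.append(st)
            u = st.u
            prev = target
        return states

    def _bisect(self, base, target, u, max_bisect, idx, **kw):
        lam_done, lam_try, depth = 0.0, 0.5, 0
        st = None
        while lam_done < 1.0:
            try:
                st = self.solve_augmented(
                    base.blend(target, lam_try), u, **kw)
                u = st.u
                lam_done = lam_try
                lam_try = min(1.0, lam_done + 2 * (lam_try - lam_done))
            except NonConvergenceError as exc:
                depth += 1
                if depth > max_bisect:
                    raise NonConvergenceError(
                        f"step {idx}: bisection exhausted at load fraction "
                        f"{lam_done:.3f}", exc.history, lam_done) from exc
                lam_try = lam_done + (lam_try - lam_done) / 2.0
        return st
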