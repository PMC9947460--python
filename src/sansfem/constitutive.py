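"""Tissue material models.

Every soft tissue is an incompressible, isotropic neo-Hookean solid; water
uptake enters through a multiplicative hygroscopic swelling split

    F = F_e * J_H^(1/3) I,    eps_H = beta * (C_W - C_W0),   J_H = (1 + eps_H)^3,

so the stress-free state of a swollen tissue is the isotropically expanded
configuration.  Incompressibility of the *elastic* part (J_e = det F / J_H = 1)
is enforced numerically by a penalty bulk modulus ``kappa = PENALTY_RATIO * mu``
with selective reduced integration in the solver.  The shear modulus follows
from the printed Young's moduli in the incompressible limit, mu = E / 3.

Energy per unit unswollen reference volume:

    W = J_H * [ mu/2 (J_e^{-2/3} tr(C_e) - 3) + kappa/2 (J_e - 1)^2 ]
      = J_H mu/2 (J^{-2/3} I1 - 3)  +  J_H kappa/2 (J/J_H - 1)^2 .
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: penalty bulk-to-shear ratio enforcing elastic incompressibility
PENALTY_RATIO = 1.0e4

#: coefficient of hygroscopic swelling of a fat-water mixture, m^3/kg
BETA_DEFAULT = 1.0e-3


class CollapseError(ValueError):
    """Raised when a swelling state would invert the material (eps_H <= -1)."""


@dataclass(frozen=True)
class TissueProperties:
    """Elastic properties of a single tissue."""

    name: str
    E: float  # Young's modulus, Pa (ignored when rigid)
    incompressible: bool = True
    rigid: bool = False

    def __post_init__(self):
        if not self.rigid and not self.E > 0:
            raise ValueError(f"tissue {self.name!r}: E must be positive, got {self.E}")

    @property
    def mu(self) -> float:
        """Shear modulus in the incompressible limit, mu = E/3 (Pa)."""
        return self.E / 3.0

    @property
    def kappa(self) -> float:
        """Penalty bulk modulus (Pa)."""
        return PENALTY_RATIO * self.mu


def default_tissues() -> dict[str, TissueProperties]:
    """Baseline tissue registry.

    Ocular coats 1.5 MPa, vitreous 6.5 Pa, orbital fat 700 Pa, orbital bone
    rigid.  The optic-nerve entries (axon bundle, dura) carry no load in the
    equilibrium solve (the nerve stays slack); the dura is assigned the
    collagenous scleral modulus and the axon bundle a nominal neural-tissue
    stiffness so exported meshes carry sensible values.
    """
    return {
        "ocular_coats": TissueProperties("ocular_coats", 1.5e6),
        "vitreous": TissueProperties("vitreous", 6.5),
        "orbital_fat": TissueProperties("orbital_fat", 700.0),
        "orbital_bone": TissueProperties("orbital_bone", float("inf"), rigid=True),
        "axon_bundle": TissueProperties("axon_bundle", 3.0e4),
        "dura": TissueProperties("dura", 1.5e6),
    }


def registry_to_dict(reg: dict[str, TissueProperties]) -> dict:
    return {
        k: {"E": v.E, "incompressible": v.incompressible, "rigid": v.rigid}
        for k, v in reg.items()
    }


def registry_from_dict(d: dict) -> dict[str, TissueProperties]:
    return {
        k: TissueProperties(k, v.get("E", float("inf")),
                            v.get("incompressible", True), v.get("rigid", False))
        for k, v in d.items()
    }


def with_modulus(reg: dict[str, TissueProperties], name: str, E: float):
    """Copy of the registry with one tissue's modulus replaced."""
    out = dict(reg)
    out[name] = replace(reg[name], E=E)
    return out


@dataclass(frozen=True)
class SwellingState:
    """Hygroscopic state of one tissue."""

    beta: float = BETA_DEFAULT      # m^3/kg
    C_W0: float = 0.0               # baseline water content, kg/m^3
    C_W: float = 0.0                # current water content, kg/m^3
    eps_H: float = field(init=False, default=0.0)
    J_H: float = field(init=False, default=1.0)

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        eps = self.beta * (self.C_W - self.C_W0)
        if eps <= -1.0:
            raise CollapseError(f"eps_H = {eps} <= -1 collapses the tissue")
        object.__setattr__(self, "eps_H", eps)
        object.__setattr__(self, "J_H", (1.0 + eps) ** 3)


def hygroscopic_state(C_W: float, C_W0: float = 0.0,
                      beta: float = BETA_DEFAULT) -> SwellingState:
    """Swelling state from water contents: eps_H = beta (C_W - C_W0)."""
    return SwellingState(beta=beta, C_W0=C_W0, C_W=C_W)


def swelling_from_strain(eps_H: float) -> SwellingState:
    """Swelling state from the hygroscopic strain directly (beta absorbed)."""
    return hygroscopic_state(C_W=eps_H / BETA_DEFAULT)


# ---------------------------------------------------------------------------
# Pointwise law on axisymmetric deformation-gradient components.
#
# f = (F_rr, F_rz, F_zr, F_zz, F_tt) stacked as (..., 5).  All returns are
# per unit *unswollen* reference volume.
# ---------------------------------------------------------------------------

def _jac(f):
    J2 = f[..., 0] * f[..., 3] - f[..., 1] * f[..., 2]
    return J2 * f[..., 4], J2


def _djac(f):
    """dJ/df, shape (..., 5)."""
    d = np.empty_like(f)
    Fh = f[..., 4]
    d[..., 0] = f[..., 3] * Fh
    d[..., 1] = -f[..., 2] * Fh
    d[..., 2] = -f[..., 1] * Fh
    d[..., 3] = f[..., 0] * Fh
    d[..., 4] = f[..., 0] * f[..., 3] - f[..., 1] * f[..., 2]
    return d


def _d2jac(f):
    """d2J/df2, shape (..., 5, 5)."""
    n = f.shape[:-1]
    H = np.zeros(n + (5, 5))
    Fh = f[..., 4]
    H[..., 0, 3] = H[..., 3, 0] = Fh
    H[..., 1, 2] = H[..., 2, 1] = -Fh
    H[..., 0, 4] = H[..., 4, 0] = f[..., 3]
    H[..., 3, 4] = H[..., 4, 3] = f[..., 0]
    H[..., 1, 4] = H[..., 4, 1] = -f[..., 2]
    H[..., 2, 4] = H[..., 4, 2] = -f[..., 1]
    return H


def axisym_dev(f: np.ndarray, mu: float, J_H=1.0):
    """Deviatoric (isochoric) part: energy, P = dW/df, A = d2W/df2.

    ``J_H`` may be a scalar or an array broadcastable over the point axes
    (heterogeneous swelling fields).
    """
    f = np.asarray(f, dtype=float)
    J, _ = _jac(f)
    if np.any(J <= 0):
        raise FloatingPointError("non-positive Jacobian in deviatoric law")
    I1 = np.sum(f * f, axis=-1)
    c = np.broadcast_to(np.asarray(0.5 * mu * J_H, dtype=float), J.shape)
    Jm23 = J ** (-2.0 / 3.0)
    W = c * (Jm23 * I1 - 3.0)
    dJ = _djac(f)
    dI1 = 2.0 * f
    Jm53 = J ** (-5.0 / 3.0)
    P = c[..., None] * (-(2.0 / 3.0) * (Jm53 * I1)[..., None] * dJ
                        + Jm23[..., None] * dI1)
    d2J = _d2jac(f)
    eye = np.eye(5)
    A = c[..., None, None] * (
        (10.0 / 9.0) * (J ** (-8.0 / 3.0) * I1)[..., None, None] * dJ[..., :, None] * dJ[..., None, :]
        - (2.0 / 3.0) * Jm53[..., None, None]
        * (dI1[..., :, None] * dJ[..., None, :] + dJ[..., :, None] * dI1[..., None, :])
        - (2.0 / 3.0) * (Jm53 * I1)[..., None, None] * d2J
        + 2.0 * Jm23[..., None, None] * eye
    )
    return W, P, A


def axisym_vol(f: np.ndarray, kappa: float, J_H=1.0):
    """Volumetric penalty part: energy, P, A.  ``J_H`` scalar or broadcastable."""
    f = np.asarray(f, dtype=float)
    J, _ = _jac(f)
    J_H = np.broadcast_to(np.asarray(J_H, dtype=float), J.shape)
    b = 0.5 * kappa * J_H
    e = J / J_H - 1.0
    W = b * e * e
    dJ = _djac(f)
    P = (2.0 * b / J_H)[..., None] * e[..., None] * dJ
    A = (2.0 * b / J_H ** 2)[..., None, None] * dJ[..., :, None] * dJ[..., None, :] \
        + (2.0 * b / J_H)[..., None, None] * e[..., None, None] * _d2jac(f)
    return W, P, A


# ---------------------------------------------------------------------------
# General 3x3 interface (verification)
# ---------------------------------------------------------------------------

def strain_energy(F: np.ndarray, props: TissueProperties,
                  swell: SwellingState | None = None):
    """Energy density and first Piola-Kirchhoff stress for a full 3x3 F.

    With ``J_H > 1`` the stress-free state is the isotropically swollen
    configuration ``F = J_H^(1/3) I``.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise FloatingPointError("element inversion: det F <= 0")
    J_H = 1.0 if swell is None else swell.J_H
    mu, kappa = props.mu, props.kappa
    I1 = np.sum(F * F)
    Finv_T = np.linalg.inv(F).T
    c = 0.5 * J_H * mu
    W = c * (J ** (-2.0 / 3.0) * I1 - 3.0)
    P = c * (2.0 * J ** (-2.0 / 3.0) * F
             - (2.0 / 3.0) * J ** (-2.0 / 3.0) * I1 * Finv_T)
    b = 0.5 * J_H * kappa
    e = J / J_H - 1.0
    W += b * e * e
    P += (2.0 * b / J_H) * e * J * Finv_T
    return W, P
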