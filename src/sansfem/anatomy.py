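"""Parametric axisymmetric anatomy of the eye, orbit, fat and optic nerve.

The half-plane (r, z) geometry, z anterior-positive, globe centred at the
origin.  The ocular coats are the shell between two confocal-centre ellipses:
inner semi-axes (R_Eq, R_P), outer (R_Eq + h_Eq, R_P + h_P), so shell
thickness blends smoothly from h_P at the poles to h_Eq at the equator.
The orbital rim is a ring of radius R_OM sitting L_OM anterior of the globe
equator plane; the bony wall runs rim -> equatorial bulge -> apex as straight
segments (the printed anatomy gives only four orbit scalars, so the wall
profile is a reconstruction; see docs/methods.md).  Orbital fat fills the
space between globe, wall, dural sheath and the anterior septum, which spans
from the rim to the palpebral aperture ring on the globe.

Shell surface points are parametrised by the polar angle ``psi`` measured
from the posterior pole (psi = 0 posterior pole, pi/2 equator, pi anterior
pole).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
import hashlib
import math

import numpy as np


class AnatomyError(ValueError):
    """Parameter-validation failure; the message names the violated constraint."""


@dataclass(frozen=True)
class AnatomyParams:
    """Geometric parameters (mm unless noted)."""

    R_Eq: float = 12.36     # equatorial radius (inner sclera)
    R_P: float = 12.36      # polar radius (inner sclera); axial length = 2 R_P
    h_Eq: float = 0.5       # shell thickness at the equator
    h_P: float = 1.0        # shell thickness at the poles
    R_OM: float = 13.95     # orbit margin (rim) radius
    L_OM: float = 9.51      # axial distance of the rim anterior of the equator plane
    L_O: float = 40.26      # total orbit length, rim to apex
    R_A: float = 0.85       # axon-bundle radius
    R_Di: float = 1.0       # inner dura radius
    R_Do: float = 1.515     # outer dura radius
    sas_band: float = 270.0  # ICP band radial extent, um (informational)
    # --- reconstruction parameters (not printed in the source anatomy) ---
    septum_ring_deg: float | None = 80.0  # polar angle (deg from the
    # posterior pole) where the septum/fornix ring meets the globe; the globe
    # surface anterior of this ring is free.  None instead places the ring at
    # the tangency point of a line from the orbital rim (lid wrap limit).
    aperture_radius: float | None = None  # explicit ring radius override (mm)
    wall_bulge_gap: float = 6.0    # lateral fat thickness at the equator plane
    septum_slip_length: float = 1e9  # fat slides freely along the whole septum face
    eom_insertion_deg: float = 115.0  # insertion ring polar angle (deg from post. pole)
    sas_r_inner: float = 0.85   # ICP band projected annulus, inner radius
    sas_r_outer: float = 1.0    # ICP band projected annulus, outer radius
    wall_trunc_width: float = 1.2  # fat wedge width at which the apex is truncated
    front_face_rise: float = 3.0  # axial height where the fat front face meets
    # the orbital wall (sets the wedge angle at the equator ring)
    wall_mid_bulge: float = 1.5   # outward bow of the posterior wall at
    # mid-depth (intraconal fat thickness), mm
    wall_mid_frac: float = 0.25   # axial position of the bow, fraction of apex depth
    g_v: float | None = None    # vitreous-swelling gap (um) -- simulation output

    def validate(self) -> None:
        for f in ("R_Eq", "R_P", "h_Eq", "h_P", "R_OM", "L_OM", "L_O",
                  "R_A", "R_Di", "R_Do", "wall_bulge_gap"):
            if not getattr(self, f) > 0:
                raise AnatomyError(f"{f} must be strictly positive")
        if not self.R_Di > self.R_A:
            raise AnatomyError("R_Di > R_A violated (dura must clear the axon bundle)")
        if not self.R_Do > self.R_Di:
            raise AnatomyError("R_Do > R_Di violated (dura needs finite thickness)")
        if not self.R_OM > self.R_Eq:
            raise AnatomyError("R_OM > R_Eq violated (globe must pass the orbit margin)")
        if not self.L_O > 2.0 * self.R_P:
            raise AnatomyError("L_O > 2 R_P violated (globe does not fit in the orbit)")
        if self.aperture_radius is not None and not (
                0 < self.aperture_radius < self.R_Eq):
            raise AnatomyError("aperture_radius must lie in (0, R_Eq)")
        if not self.sas_r_outer > self.sas_r_inner >= 0:
            raise AnatomyError("ICP band radii must satisfy 0 <= inner < outer")
        if not self.sas_r_outer <= self.R_Do:
            raise AnatomyError("ICP band must lie within the scleral canal (<= R_Do)")

    # outer-surface semi-axes
    @property
    def a_out(self) -> float:
        return self.R_Eq + self.h_Eq

    @property
    def b_out(self) -> float:
        return self.R_P + self.h_P

    @property
    def axial_length(self) -> float:
        """Nominal axial length, 2 R_P (mm)."""
        return 2.0 * self.R_P

    def perturbed(self, **changes) -> "AnatomyParams":
        return replace(self, **changes)

    def hash(self) -> str:
        payload = ",".join(f"{f.name}={getattr(self, f.name)!r}"
                           for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def ellipse_point(a: float, b: float, psi):
    """Point on the ellipse with semi-axes (a, b): (a sin psi, -b cos psi)."""
    psi = np.asarray(psi, dtype=float)
    return np.stack([a * np.sin(psi), -b * np.cos(psi)], axis=-1)


def _polyline_resample(pts: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Sample a dense polyline at normalized arc-length fractions."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s /= s[-1]
    r = np.interp(frac, s, pts[:, 0])
    z = np.interp(frac, s, pts[:, 1])
    return np.stack([r, z], axis=-1)


def _area_of_revolution_volume(poly: np.ndarray) -> float:
    """Volume of revolution of a closed (r, z) polygon about r = 0 (mm^3)."""
    r, z = poly[:, 0], poly[:, 1]
    r2, z2 = np.roll(r, -1), np.roll(z, -1)
    # V = -pi * oint r^2 dz for a counter-clockwise polygon in (r, z)
    return float(abs(np.pi * np.sum((r * r + r * r2 + r2 * r2) / 3.0 * (z2 - z))))


def _polygon_area(poly: np.ndarray) -> float:
    r, z = poly[:, 0], poly[:, 1]
    return float(abs(0.5 * np.sum(r * np.roll(z, -1) - np.roll(r, -1) * z)))


@dataclass
class GeometryModel:
    """Derived axisymmetric geometry: curves, landmarks and region outlines."""

    params: AnatomyParams
    z_rim: float = 0.0
    z_apex: float = 0.0
    z_back: float = 0.0          # axial truncation of the fat wedge near the apex
    psi_canal: float = 0.0       # shell angle where the dural sheath meets the globe
    psi_front: float = 0.0       # shell angle of the palpebral aperture ring
    psi_sas: tuple = (0.0, 0.0)  # shell angles bounding the ICP band (outer surface)
    psi_eom: float = 0.0         # EOM insertion ring angle
    wall: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    septum: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    front_outer: np.ndarray = field(default_factory=lambda: np.zeros(2))
    regions: dict = field(default_factory=dict)   # name -> closed outline polygon

    # -- shell --------------------------------------------------------------
    def shell_point(self, psi, t):
        """Blend between inner (t=0) and outer (t=1) shell ellipses."""
        p = self.params
        inner = ellipse_point(p.R_Eq, p.R_P, psi)
        outer = ellipse_point(p.a_out, p.b_out, psi)
        t = np.asarray(t, dtype=float)[..., None]
        return (1.0 - t) * inner + t * outer

    def fat_volume(self) -> float:
        return _area_of_revolution_volume(self.regions["orbital_fat"])

    def region_areas(self) -> dict:
        return {k: _polygon_area(v) for k, v in self.regions.items()}

    def summary(self) -> dict:
        p = self.params
        return {
            "z_rim": self.z_rim, "z_apex": self.z_apex, "z_back": self.z_back,
            "psi_canal_deg": math.degrees(self.psi_canal),
            "psi_front_deg": math.degrees(self.psi_front),
            "fat_volume_mm3": self.fat_volume(),
            "axial_length": p.axial_length,
            "hash": p.hash(),
        }


def build_anatomy(params: AnatomyParams) -> GeometryModel:
    """Construct the axisymmetric geometry; raises :class:`AnatomyError` on
    invalid parameters or an unbuildable wall."""
    params.validate()
    p = params

    z_rim = p.L_OM
    z_apex = p.L_OM - p.L_O

    psi_canal = math.asin(p.R_Do / p.a_out)
    if p.aperture_radius is not None:
        r_ring = p.aperture_radius
    elif p.septum_ring_deg is not None:
        psi_front = math.radians(p.septum_ring_deg)
        r_ring = p.a_out * math.sin(psi_front)
    else:
        # tangency point of the septum line from the rim onto the outer ellipse:
        # tangent u r + v z = 1 with contact (a^2 u, b^2 v), a^2 u^2 + b^2 v^2 = 1
        a2, b2 = p.a_out ** 2, p.b_out ** 2
        A = a2 * z_rim ** 2 / p.R_OM ** 2 + b2
        B = -2.0 * a2 * z_rim / p.R_OM ** 2
        C = a2 / p.R_OM ** 2 - 1.0
        disc = B * B - 4.0 * A * C
        if disc <= 0:
            raise AnatomyError("orbital rim lies inside the globe; no septum tangent")
        v = (-B + math.sqrt(disc)) / (2.0 * A)     # upper tangency
        u = (1.0 - z_rim * v) / p.R_OM
        r_ring = a2 * u
        if not 0.0 < r_ring < p.a_out:
            raise AnatomyError("septum tangency point degenerate")
    if p.septum_ring_deg is None or p.aperture_radius is not None:
        psi_front = math.pi - math.asin(r_ring / p.a_out)
    psi_sas = (math.asin(p.sas_r_inner / p.a_out) if p.sas_r_inner > 0 else 0.0,
               math.asin(p.sas_r_outer / p.a_out))
    psi_eom = math.radians(p.eom_insertion_deg)
    if not (math.pi / 2 < psi_eom < math.pi):
        raise AnatomyError("EOM insertion ring must sit anterior of the equator")

    # orbit wall: rim -> equatorial bulge -> bowed mid-wall -> apex cone
    # (truncated near the apex)
    r_bulge = p.a_out + p.wall_bulge_gap
    apex = np.array([p.R_Do, z_apex])
    bulge = np.array([r_bulge, 0.0])
    rim = np.array([p.R_OM, z_rim])
    z_mid = p.wall_mid_frac * z_apex
    lam_mid = (0.0 - z_mid) / (0.0 - z_apex)
    mid = bulge + lam_mid * (apex - bulge)
    mid = mid + np.array([p.wall_mid_bulge, 0.0])
    # truncate the cone where the fat wedge narrows to wall_trunc_width
    r_trunc = p.R_Do + p.wall_trunc_width
    frac = (mid[0] - r_trunc) / (mid[0] - p.R_Do)
    if not 0.0 < frac < 1.0:
        raise AnatomyError("orbit wall cone degenerate: cannot truncate at the apex")
    back_outer = mid + frac * (np.array([p.R_Do, z_apex]) - mid)
    z_back = float(back_outer[1])
    wall = np.array([rim, bulge, mid, back_outer])

    # fat front face: from the ring on the globe to the orbital wall,
    # front_face_rise above the ring (sets the wedge angle at the ring)
    ring = ellipse_point(p.a_out, p.b_out, psi_front)
    zf = float(ring[1]) + p.front_face_rise
    zf = min(zf, z_rim - 0.5)
    if zf >= 0.0:
        tau = (z_rim - zf) / (z_rim - 0.0)
        front_outer = rim + tau * (bulge - rim)
    else:
        lam_f = (0.0 - zf) / (0.0 - z_apex)
        front_outer = bulge + lam_f * (np.array([p.R_Do, z_apex]) - bulge)
        front_outer = front_outer + np.array(
            [p.wall_mid_bulge * min(1.0, lam_f / max(p.wall_mid_frac, 1e-6)),
             0.0])
    septum = np.array([ring, front_outer])
    if front_outer[0] <= ring[0] + 0.3:
        raise AnatomyError("fat front face degenerate: wall too close to globe")
    # the wall must clear the globe everywhere
    for seg in (wall[[0, 1]], wall[[1, 2]], wall[[2, 3]]):
        for t in np.linspace(0, 1, 128):
            rr, zz = (1 - t) * seg[0] + t * seg[1]
            if abs(zz) < p.b_out:
                r_globe = p.a_out * math.sqrt(max(0.0, 1.0 - (zz / p.b_out) ** 2))
                if rr < r_globe + 0.2:
                    raise AnatomyError("orbit wall intersects the globe outer surface")

    geom = GeometryModel(params=p, z_rim=z_rim, z_apex=z_apex, z_back=z_back,
                         front_outer=front_outer,
                         psi_canal=psi_canal, psi_front=psi_front,
                         psi_sas=psi_sas, psi_eom=psi_eom,
                         wall=wall, septum=septum)

    # region outline polygons (dense, for tiling/area/volume checks and export)
    psi = np.linspace(0.0, math.pi, 256)
    inner = ellipse_point(p.R_Eq, p.R_P, psi)
    outer = ellipse_point(p.a_out, p.b_out, psi)
    geom.regions["ocular_coats"] = np.vstack([inner, outer[::-1]])
    geom.regions["vitreous"] = np.vstack(
        [inner, [[0.0, -p.R_P]]])  # closed by the axis segment
    geom.regions["orbital_fat"] = _fat_outline(geom)
    z_j = -p.b_out * math.cos(psi_canal)
    geom.regions["axon_bundle"] = np.array(
        [[0.0, z_j], [p.R_A, z_j], [p.R_A, z_apex], [0.0, z_apex]])
    geom.regions["dura"] = np.array(
        [[p.R_Di, z_j], [p.R_Do, z_j], [p.R_Do, z_apex], [p.R_Di, z_apex]])
    return geom


def _fat_outline(geom: GeometryModel) -> np.ndarray:
    """Closed outline of the orbital-fat region (counter-clockwise-ish)."""
    p = geom.params
    psi = np.linspace(geom.psi_front, geom.psi_canal, 200)
    globe = ellipse_point(p.a_out, p.b_out, psi)   # aperture ring -> canal
    z_j = globe[-1, 1]
    nerve = np.array([[p.R_Do, z_j], [p.R_Do, geom.z_back]])
    back = np.array([geom.wall[3]])
    outer = np.array([geom.wall[2], geom.wall[1], geom.front_outer])
    sept = np.array([geom.septum[0]])                   # closes at the ring
    return np.vstack([globe, nerve, back, outer, sept])


def fat_inner_curve(geom: GeometryModel, n: int = 600) -> np.ndarray:
    """Dense polyline of the fat inner boundary: aperture ring -> canal -> apex."""
    p = geom.params
    psi = np.linspace(geom.psi_front, geom.psi_canal, n)
    globe = ellipse_point(p.a_out, p.b_out, psi)
    z_j = globe[-1, 1]
    nz = np.linspace(z_j, geom.z_back, max(8, n // 6))[1:]
    nerve = np.stack([np.full_like(nz, p.R_Do), nz], axis=-1)
    return np.vstack([globe, nerve]), len(globe)  # split index: globe part


def fat_wall_curve(geom: GeometryModel) -> np.ndarray:
    """Dense polyline of the fat outer (orbital wall) boundary:
    front-face corner -> (equatorial bulge) -> mid bow -> apex truncation."""
    pts = [geom.front_outer, geom.wall[1], geom.wall[2], geom.wall[3]]
    if geom.front_outer[1] <= geom.wall[1][1]:
        pts = [geom.front_outer, geom.wall[2], geom.wall[3]]
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linspace(0, 1, 120)[:-1, None] * (b - a) + a
        out.append(seg)
    out.append(np.array([pts[-1]]))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_case(name: str):
    """Named parameter bundle: (AnatomyParams, tissue registry, LoadCase).

    Presets: ``baseline``, ``plus10_RP|REq|LO|ROM|LOM``, ``soft_sclera_<E_MPa>``,
    ``icp_<cmH2O>``, ``active_eom``.
    """
    from .constitutive import default_tissues, with_modulus
    from .loads import LoadCase

    anat = AnatomyParams()
    tissues = default_tissues()
    case = LoadCase()

    if name == "baseline":
        pass
    elif name == "plus10_RP":
        anat = anat.perturbed(R_P=anat.R_P * 1.1)
    elif name == "plus10_REq":
        anat = anat.perturbed(R_Eq=anat.R_Eq * 1.1)
    elif name == "plus10_LO":
        anat = anat.perturbed(L_O=anat.L_O * 1.1)
    elif name == "plus10_ROM":
        anat = anat.perturbed(R_OM=anat.R_OM * 1.1)
    elif name == "plus10_LOM":
        anat = anat.perturbed(L_OM=anat.L_OM * 1.1)
    elif name.startswith("soft_sclera_"):
        E_MPa = float(name.removeprefix("soft_sclera_"))
        tissues = with_modulus(tissues, "ocular_coats", E_MPa * 1e6)
    elif name.startswith("icp_"):
        case = LoadCase(ICP=float(name.removeprefix("icp_")))
    elif name == "active_eom":
        case = LoadCase(M=2.25)
    else:
        known = ("baseline plus10_RP plus10_REq plus10_LO plus10_ROM plus10_LOM "
                 "soft_sclera_<E_MPa> icp_<cmH2O> active_eom").split()
        raise KeyError(f"unknown preset {name!r}; presets: {known}")
    return anat, tissues, case
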