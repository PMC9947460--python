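"""Boundary loads, constraints and unit conversions.

Covers the extraocular-muscle (EOM) tension law, the intracranial-pressure
band on the peripapillary sclera, the optic-nerve slack spring, and the load
case container consumed by the staged protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# The study's rounded pair (10 mmHg = 13.6 cmH2O) is reproduced on purpose.
MMHG_PER_CMH2O = 1.0 / 1.36
PA_PER_CMH2O = 98.0665
PA_PER_MMHG = 1.36 * PA_PER_CMH2O

_UNIT_TO_PA = {"Pa": 1.0, "cmH2O": PA_PER_CMH2O, "mmHg": PA_PER_MMHG}


def pressure_convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure between mmHg, cmH2O and Pa (1 mmHg = 1.36 cmH2O)."""
    try:
        pa = value * _UNIT_TO_PA[from_unit]
        return pa / _UNIT_TO_PA[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown pressure unit {exc.args[0]!r}; known: {sorted(_UNIT_TO_PA)}"
        ) from None


def eom_force(w: float | np.ndarray, M: float = 1.0) -> float | np.ndarray:
    """Total rectus-muscle axial tension in mN.

    ``F = 4 M (-0.29 w + 4.79 exp(w / 4.57) - 3.01)`` with ``w`` the anterior
    displacement of the insertion ring in mm: the passive stretch response of
    one rectus muscle times the four recti, scaled by the multiplier ``M``
    (M = 1 passive, M = 2.25 emulates added active tension).
    """
    w = np.asarray(w, dtype=float)
    out = 4.0 * M * (-0.29 * w + 4.79 * np.exp(w / 4.57) - 3.01)
    return float(out) if out.ndim == 0 else out


def eom_force_derivative(w: float, M: float = 1.0) -> float:
    """dF/dw in mN/mm (needed for the tangent of the floating globe)."""
    return 4.0 * M * (-0.29 + (4.79 / 4.57) * np.exp(w / 4.57))


def eom_displacement(F_mN: float, M: float = 1.0) -> float:
    """Invert the tension law for the insertion displacement (mm), w >= 0."""
    from scipy.optimize import brentq

    if M <= 0:
        raise ValueError("M must be positive to invert the law")
    return brentq(lambda w: eom_force(w, M) - F_mN, 0.0, 50.0)


def on_slack(on_length: float, orbit_length: float, axial_length: float) -> float:
    """Optic-nerve slack: ON length - orbit length - axial length / 2 (mm)."""
    return on_length - orbit_length - 0.5 * axial_length


def on_spring_force(anterior_translation: float, slack: float, k: float = 1.0) -> float:
    """Nerve tether force in mN: zero while slack, then linear with stiffness k (N/m).

    k in N/m times mm of over-travel gives mN directly.
    """
    if k < 0:
        raise ValueError("spring stiffness must be non-negative")
    over = anterior_translation - slack
    return k * over if over > 0 else 0.0


@dataclass
class LoadCase:
    """Load magnitudes and schedules for one protocol run.

    ``eps_H_fat`` is the fat hygroscopic-strain schedule driving the
    microgravity stage; ICP in cmH2O acts on the subarachnoid band of the
    peripapillary sclera; ``M`` multiplies the EOM tension law.
    """

    IOP_target: float = 15.0          # mmHg, target of the zero-stress search
    ICP: float = 13.6                 # cmH2O
    M: float = 1.0
    eps_H_fat: list[float] = field(default_factory=lambda: list(TABLE2_SCHEDULE))
    on_slack_threshold: float = 6.0   # mm
    on_spring_stiffness: float = 1.0  # N/m, engaged only beyond slack
    iop_mode: str = "swelling"        # "swelling" | "direct"

    def __post_init__(self):
        self.validate()

    def validate(self):
        if not (0.0 <= self.ICP <= 40.0):
            raise ValueError(f"ICP {self.ICP} cmH2O outside [0, 40]")
        if not (0.0 <= self.M <= 2.25):
            raise ValueError(f"EOM multiplier {self.M} outside [0, 2.25]")
        eps = np.asarray(self.eps_H_fat, dtype=float)
        if eps.size and (np.any(eps < 0) or np.any(np.diff(eps) < 0)):
            raise ValueError("eps_H_fat schedule must be non-negative, non-decreasing")
        if self.iop_mode not in ("swelling", "direct"):
            raise ValueError("iop_mode must be 'swelling' or 'direct'")

    @property
    def ICP_Pa(self) -> float:
        return pressure_convert(self.ICP, "cmH2O", "Pa")

    def to_dict(self) -> dict:
        return {
            "IOP_target": self.IOP_target, "ICP": self.ICP, "M": self.M,
            "eps_H_fat": list(self.eps_H_fat),
            "on_slack_threshold": self.on_slack_threshold,
            "on_spring_stiffness": self.on_spring_stiffness,
            "iop_mode": self.iop_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoadCase":
        return cls(**d)


#: the baseline fat-swelling schedule (hygroscopic strain of the fat)
TABLE2_SCHEDULE = (0.000, 0.010, 0.015, 0.020, 0.025, 0.030, 0.035,
                   0.040, 0.045, 0.050, 0.055, 0.060, 0.065, 0.070)


def icp_band_resultant(ICP_cmH2O: float, r_inner: float, r_outer: float) -> float:
    """Axial resultant of the ICP band traction in mN.

    Uniform normal pressure on an annular band of the posterior sclera with
    projected annulus [r_inner, r_outer] (mm) gives axial force
    p * pi * (r_outer^2 - r_inner^2); returned in mN (anterior positive).
    """
    p = pressure_convert(ICP_cmH2O, "cmH2O", "Pa")
    area_mm2 = np.pi * (r_outer ** 2 - r_inner ** 2)
    return p * area_mm2 * 1e-3  # Pa * mm^2 = uN -> mN
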