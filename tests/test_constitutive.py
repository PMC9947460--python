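"""Hygroscopic swelling arithmetic and the neo-Hookean law."""

import numpy as np
import pytest
from scipy.optimize import brentq

from sansfem import constitutive as law
from sansfem.constitutive import (CollapseError, SwellingState,
                                  TissueProperties, default_tissues,
                                  hygroscopic_state, registry_from_dict,
                                  registry_to_dict, strain_energy,
                                  swelling_from_strain, with_modulus)


class TestSwellingState:
    def test_volume_ratio_cubic_law(self):
        s = swelling_from_strain(0.070)
        assert s.J_H == pytest.approx((1.07) ** 3, rel=1e-14)
        assert round(s.J_H, 3) == 1.225

    def test_mid_schedule_value(self):
        assert round(swelling_from_strain(0.030).J_H, 3) == 1.093

    def test_no_swelling_identity(self):
        s = hygroscopic_state(C_W=5.0, C_W0=5.0)
        assert s.eps_H == 0.0 and s.J_H == 1.0

    def test_strain_from_water_content(self):
        s = hygroscopic_state(C_W=70.0, C_W0=0.0, beta=1e-3)
        assert s.eps_H == pytest.approx(0.070)

    def test_collapse_rejected(self):
        with pytest.raises(CollapseError):
            swelling_from_strain(-1.0)

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            SwellingState(beta=-1e-3)


class TestRegistry:
    def test_baseline_moduli(self):
        reg = default_tissues()
        assert reg["ocular_coats"].E == 1.5e6
        assert reg["vitreous"].E == 6.5
        assert reg["orbital_fat"].E == 700.0
        assert reg["orbital_bone"].rigid

    def test_incompressible_shear_modulus(self):
        assert default_tissues()["ocular_coats"].mu == pytest.approx(0.5e6)

    def test_round_trip_and_override(self):
        reg = with_modulus(default_tissues(), "ocular_coats", 0.25e6)
        back = registry_from_dict(registry_to_dict(reg))
        assert back["ocular_coats"].E == 0.25e6
        assert back["orbital_bone"].rigid

    def test_nonpositive_modulus_rejected(self):
        with pytest.raises(ValueError):
            TissueProperties("x", 0.0)


class TestStrainEnergy3x3:
    props = TissueProperties("test", 1.5e6)

    def test_reference_state_stress_free(self):
        W, P = strain_energy(np.eye(3), self.props)
        assert W == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(P, 0.0, atol=1e-6)

    def test_swollen_state_stress_free(self):
        s = swelling_from_strain(0.07)
        F = s.J_H ** (1 / 3) * np.eye(3)
        _, P = strain_energy(F, self.props, s)
        assert np.abs(P).max() < 1e-6 * self.props.mu

    def test_uniaxial_closed_form(self):
        # equilibrium transverse stretch from zero transverse nominal stress,
        # then P11 must match mu (lam - lam^-2) of the incompressible law
        lam = 1.1
        mu = self.props.mu

        def p22(s):
            F = np.diag([lam, s, s])
            return strain_energy(F, self.props)[1][1, 1]

        s_eq = brentq(p22, 0.8, 1.1, xtol=1e-14)
        P = strain_energy(np.diag([lam, s_eq, s_eq]), self.props)[1]
        assert P[0, 0] == pytest.approx(mu * (lam - lam ** -2), rel=2e-4)
        assert s_eq == pytest.approx(lam ** -0.5, rel=1e-4)

    def test_frame_indifference(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.2:
            F = np.eye(3)
        W0, _ = strain_energy(F, self.props)
        for _ in range(4):
            A = rng.standard_normal((3, 3))
            Q, _r = np.linalg.qr(A)
            Q *= np.sign(np.linalg.det(Q))
            W, _ = strain_energy(Q @ F, self.props)
            assert W == pytest.approx(W0, rel=1e-9)

    def test_stress_is_energy_gradient(self, rng):
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        _, P = strain_energy(F, self.props)
        h = 1e-7
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                fd = (strain_energy(Fp, self.props)[0]
                      - strain_energy(Fm, self.props)[0]) / (2 * h)
                assert P[i, j] == pytest.approx(fd, rel=5e-5, abs=1e-2)

    def test_inversion_rejected(self):
        with pytest.raises(FloatingPointError):
            strain_energy(-np.eye(3), self.props)


class TestAxisymmetricLaw:
    def test_derivatives_consistent(self, rng):
        f = np.array([1.0, 0.0, 0.0, 1.0, 1.0]) \
            + 0.05 * rng.standard_normal((7, 5))
        for fn, coef in ((law.axisym_dev, 233.0), (law.axisym_vol, 2.33e6)):
            W, P, A = fn(f, coef, 1.02)
            h = 1e-7
            for c in range(5):
                fp, fm = f.copy(), f.copy()
                fp[:, c] += h
                fm[:, c] -= h
                dW = (fn(fp, coef, 1.02)[0] - fn(fm, coef, 1.02)[0]) / (2 * h)
                dP = (fn(fp, coef, 1.02)[1] - fn(fm, coef, 1.02)[1]) / (2 * h)
                assert np.allclose(P[:, c], dW, rtol=1e-4, atol=1e-2)
                assert np.allclose(A[:, c, :], dP, rtol=1e-4, atol=1e-1)

    def test_heterogeneous_swelling_broadcast(self):
        f = np.tile([1.02, 0.0, 0.0, 1.02, 1.02], (4, 1))
        J_H = np.array([1.0, 1.02 ** 3, 1.0, 1.02 ** 3])
        _, P, _ = law.axisym_vol(f, 1e6, J_H)
        # swollen entries are stress-free, unswollen are not
        assert np.abs(P[1]).max() < 1e-6
        assert np.abs(P[0]).max() > 1.0
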