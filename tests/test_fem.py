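"""Solver verification: consistency, classical oracles, contact properties."""

import numpy as np
import pytest
import scipy.sparse.linalg  # noqa: F401

from sansfem.anatomy import AnatomyParams, build_anatomy
from sansfem.constitutive import default_tissues
from sansfem.fem import FemModel, StepParams
from sansfem.loads import pressure_convert
from sansfem.mesh import mesh_geometry


@pytest.fixture(scope="module")
def sphere_model():
    # thin spherical shell, mid-radius 12 mm, h = 0.5 mm
    g = build_anatomy(AnatomyParams(R_Eq=11.75, R_P=11.75, h_Eq=0.5, h_P=0.5))
    mesh = mesh_geometry(g, "coarse", 2)
    return FemModel(mesh, default_tissues(), with_fat=False, pin_pole=True)


@pytest.fixture(scope="module")
def full_model(coarse_mesh):
    return FemModel(coarse_mesh, default_tissues(), with_fat=True)


class TestConsistency:
    def test_unloaded_body_zero_displacement(self, sphere_model):
        st = sphere_model.solve_equilibrium(StepParams(J_Hv=1.0))
        assert np.abs(st.u).max() == 0.0
        assert st.iterations == 0

    def test_tangent_matches_residual_derivative(self, full_model, rng):
        fm = full_model
        u = np.zeros(fm.ndof)
        u[fm.free] = 1e-3 * rng.standard_normal(fm.free.sum())
        pars = StepParams(J_Hv=1.002, ICP=1000.0, M=0.5, eps_fat=0.003,
                          eom_on=True)
        R, K, _ = fm.assemble(u, pars)
        h = 1e-6
        for dof in rng.choice(np.where(fm.free)[0], 6, replace=False):
            up, um = u.copy(), u.copy()
            up[dof] += h
            um[dof] -= h
            Rp, _, _ = fm.assemble(up, pars, want_K=False,
                                   refresh_contact=False)
            Rm, _, _ = fm.assemble(um, pars, want_K=False,
                                   refresh_contact=False)
            fd = (Rp - Rm) / (2 * h)
            col = np.asarray(K[:, dof].todense()).ravel()
            assert np.linalg.norm(fd - col) <= 1e-5 * max(
                np.linalg.norm(col), 1.0)

    def test_residual_is_energy_gradient(self, full_model, rng):
        fm = full_model
        u = np.zeros(fm.ndof)
        u[fm.free] = 1e-3 * rng.standard_normal(fm.free.sum())
        pars = StepParams(J_Hv=1.001, M=0.3, eps_fat=0.002, eom_on=True)
        R, _, f0 = fm.assemble(u, pars)
        h = 1e-6
        for dof in rng.choice(np.where(fm.free)[0], 5, replace=False):
            up, um = u.copy(), u.copy()
            up[dof] += h
            um[dof] -= h
            _, _, fp = fm.assemble(up, pars, want_K=False,
                                   refresh_contact=False)
            _, _, fm_ = fm.assemble(um, pars, want_K=False,
                                    refresh_contact=False)
            fd = (fp["energy"] - fm_["energy"]) / (2 * h)
            assert R[dof] == pytest.approx(fd, rel=1e-4, abs=0.5)


class TestShellOracles:
    def test_thin_shell_inflation_matches_laplace(self, sphere_model):
        p = pressure_convert(15.0, "mmHg", "Pa")
        st = sphere_model.solve_equilibrium(StepParams(IOP=p))
        eq = sphere_model.mesh.landmarks["equator_outer"]
        ur = st.u[2 * eq]
        # incompressible thin shell: w = p R^2 (1 - nu) / (2 h E), nu = 1/2
        w_exact = p * 12.0 ** 2 * 0.5 / (2 * 0.5 * 1.5e6)
        assert ur == pytest.approx(w_exact, rel=0.03)

    def test_swelling_iop_equals_direct_pressure(self, sphere_model):
        p = pressure_convert(15.0, "mmHg", "Pa")
        st1 = sphere_model.solve_equilibrium(StepParams(IOP=p))
        from sansfem.fem import KAPPA_VITREOUS
        J = st1.forces["cavity_V"] / sphere_model.cavity_V0 \
            * (1 + p / KAPPA_VITREOUS)
        st2 = sphere_model.solve_equilibrium(StepParams(J_Hv=J))
        assert st2.forces["IOP_Pa"] == pytest.approx(p, rel=1e-3)
        assert np.abs(st2.u - st1.u).max() < 1e-4   # mm, i.e. within 1%

    def test_pressurised_volume_grows(self, sphere_model):
        p = pressure_convert(15.0, "mmHg", "Pa")
        st = sphere_model.solve_equilibrium(StepParams(IOP=p))
        assert st.forces["cavity_V"] > sphere_model.cavity_V0

    def test_initial_guess_independence(self, sphere_model):
        p = pressure_convert(10.0, "mmHg", "Pa")
        st1 = sphere_model.solve_equilibrium(StepParams(IOP=p), atol=1e-4)
        for scale in (0.5, 1.5):        # under- and over-inflated starts
            st2 = sphere_model.solve_equilibrium(StepParams(IOP=p),
                                                 scale * st1.u, atol=1e-4)
            assert np.abs(st1.u - st2.u).max() < 1e-4


class TestContinuation:
    def test_empty_schedule(self, sphere_model):
        assert sphere_model.step_continuation([]) == []

    def test_blend_interpolates(self):
        a = StepParams(J_Hv=1.0, ICP=0.0, M=0.0, eps_fat=0.0, eom_on=True)
        b = StepParams(J_Hv=1.02, ICP=1000.0, M=1.0, eps_fat=0.07,
                       eom_on=True)
        mid = a.blend(b, 0.5)
        assert mid.J_Hv == pytest.approx(1.01)
        assert mid.ICP == pytest.approx(500.0)
        assert mid.eps_fat == pytest.approx(0.035)

    def test_schedule_path_following(self, sphere_model):
        ps = [StepParams(IOP=p) for p in (500.0, 1000.0, 1500.0)]
        states = sphere_model.step_continuation(ps)
        assert len(states) == 3
        vols = [s.forces["cavity_V"] for s in states]
        assert vols[0] < vols[1] < vols[2]


class TestIcpBand:
    def test_axial_resultant_scales_linearly(self, sphere_model):
        u = np.zeros(sphere_model.ndof)
        p1 = pressure_convert(10.0, "cmH2O", "Pa")
        _, _, f1 = sphere_model.assemble(u, StepParams(J_Hv=1.0, ICP=p1))
        _, _, f2 = sphere_model.assemble(u, StepParams(J_Hv=1.0, ICP=2 * p1))
        assert f2["F_ICP_mN"] == pytest.approx(2 * f1["F_ICP_mN"], rel=1e-12)

    def test_resultant_equals_projected_annulus(self, coarse_mesh):
        fm = FemModel(coarse_mesh, default_tissues(), with_fat=False,
                      pin_pole=True)
        u = np.zeros(fm.ndof)
        icp = pressure_convert(13.6, "cmH2O", "Pa")
        _, _, f = fm.assemble(u, StepParams(J_Hv=1.0, ICP=icp))
        p = coarse_mesh.geom.params
        expected = icp * np.pi * (p.sas_r_outer ** 2 - p.sas_r_inner ** 2) \
            * 1e-3
        assert f["F_ICP_mN"] == pytest.approx(expected, rel=1e-6)
        assert f["F_ICP_mN"] == pytest.approx(1.17, abs=0.02)


class TestContactTie:
    def test_rest_state_nearly_force_free(self, full_model):
        u = np.zeros(full_model.ndof)
        _, _, f = full_model.assemble(u, StepParams(J_Hv=1.0))
        # sub-micron meshing mismatch across the non-conforming interface
        # leaves only a small spurious resultant (signal scale is ~36 mN)
        assert abs(f["F_fat_mN"]) < 4.0

    def test_normal_only_coupling(self, full_model):
        """Tangential (axial, on the near-cylindrical equator) rigid slide of
        the fat relative to the globe produces no spurious force growth."""
        fm = full_model
        u = np.zeros(fm.ndof)
        fm._project_contact(u)
        _, _, f0 = fm.assemble(u, StepParams(J_Hv=1.0), want_K=False,
                               refresh_contact=False)
        base = abs(f0["F_fat_mN"])
        assert base < 4.0
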