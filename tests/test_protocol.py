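"""Staged protocol: zero-stress identification and short end-to-end runs."""

import numpy as np
import pytest

from sansfem.anatomy import AnatomyParams, build_anatomy
from sansfem.constitutive import default_tissues
from sansfem.fem import FemModel, StepParams
from sansfem.loads import LoadCase
from sansfem.mesh import mesh_geometry
from sansfem.protocol import find_zero_stress, run_protocol


@pytest.fixture(scope="module")
def zero_stress(baseline_geom):
    return find_zero_stress(baseline_geom, default_tissues(), 15.0,
                            "coarse", 2)


@pytest.fixture(scope="module")
def short_run():
    lc = LoadCase(eps_H_fat=[0.0, 0.01, 0.02])
    return run_protocol("baseline", load_case=lc, density="coarse", order=2)


class TestZeroStress:
    def test_round_trip_reproduces_targets(self, zero_stress, baseline_geom):
        """Reloading the identified zero-stress eye reproduces the target
        radii within 10 um and the target IOP within 0.1 mmHg."""
        zs, mesh, model, state_B = zero_stress
        assert zs.mismatch_um < 10.0
        assert zs.iop_error_mmHg < 0.1
        # independent reload on a fresh model
        g = baseline_geom
        mesh2 = mesh_geometry(g, "coarse", 2,
                              shell_inner_axes=(zs.rho_Eq, zs.rho_P),
                              shell_outer_axes=(zs.rho_Eq + g.params.h_Eq,
                                                zs.rho_P + g.params.h_P))
        m2 = FemModel(mesh2, default_tissues(), with_fat=False, pin_pole=True)
        st = m2.solve_equilibrium(StepParams(J_Hv=zs.J_Hv))
        X = mesh2.nodes + st.u.reshape(-1, 2)
        a = X[mesh2.landmarks["equator_outer"], 0]
        b = 0.5 * (X[mesh2.landmarks["ant_pole_outer"], 1]
                   - X[mesh2.landmarks["post_pole_outer"], 1])
        assert a == pytest.approx(g.params.a_out, abs=0.010)
        assert b == pytest.approx(g.params.b_out, abs=0.010)

    def test_zero_stress_radii_smaller_than_target(self, zero_stress):
        zs = zero_stress[0]
        assert zs.rho_Eq < 12.36 and zs.rho_P < 12.36
        assert zs.J_Hv > 1.0

    def test_g_v_reported(self, zero_stress):
        zs = zero_stress[0]
        assert zs.g_v_um > 0
        # at the default 15 mmHg target the vitreous-growth gap sits below
        # the printed 133-217 um band; the flag records the deviation
        assert isinstance(zs.in_printed_range, bool)

    def test_robust_to_perturbed_start(self, baseline_geom, zero_stress):
        zs = zero_stress[0]
        zs2 = find_zero_stress(baseline_geom, default_tissues(), 15.0,
                               "coarse", 2,
                               x0=[zs.rho_Eq - 0.05, zs.rho_P + 0.05,
                                   zs.J_Hv * 1.005])[0]
        assert zs2.rho_Eq == pytest.approx(zs.rho_Eq, abs=2e-3)
        assert zs2.rho_P == pytest.approx(zs.rho_P, abs=2e-3)

    def test_zero_iop_target_identity(self, baseline_geom):
        """With no pressure target the zero-stress eye is the target eye."""
        zs = find_zero_stress(baseline_geom, default_tissues(), 0.0,
                              "coarse", 2)[0]
        assert zs.rho_Eq == pytest.approx(12.36, abs=5e-3)
        assert zs.rho_P == pytest.approx(12.36, abs=5e-3)
        assert zs.J_Hv == pytest.approx(1.0, abs=1e-3)


class TestRunProtocol:
    def test_zero_swelling_state_matches_terrestrial(self, short_run):
        b0 = short_run.biometrics[0]
        assert b0.eps_H_fat == 0.0
        assert abs(b0.proptosis_mm) < 1e-4          # 0.1 um
        assert abs(b0.delta_axial_length_um) < 0.1
        assert abs(b0.delta_arc_um) < 0.1
        assert abs(b0.delta_roc_mm) < 1e-4

    def test_terrestrial_force_balance(self, short_run):
        m = short_run.meta
        # terrestrial resultants: EOM ~7 mN balanced by fat + ICP
        assert m["F_EOM_C_mN"] == pytest.approx(7.12, abs=1.0)
        assert m["F_ICP_C_mN"] == pytest.approx(1.17, abs=0.1)
        assert m["F_EOM_C_mN"] == pytest.approx(
            m["F_fat_C_mN"] + m["F_ICP_C_mN"], abs=0.05)

    def test_balance_residual_small(self, short_run):
        for b in short_run.biometrics:
            assert abs(b.balance_residual_mN) < 1e-3 * max(b.F_EOM_mN, 1.0)

    def test_proptosis_grows_with_swelling(self, short_run):
        props = [b.proptosis_mm for b in short_run.biometrics]
        assert props[0] < props[1] < props[2]

    def test_on_slack_never_engaged(self, short_run):
        for b in short_run.biometrics:
            assert b.F_ON_mN == 0.0
            assert b.proptosis_mm < short_run.load_case.on_slack_threshold

    def test_iop_reported_near_target(self, short_run):
        for b in short_run.biometrics:
            assert b.IOP_mmHg == pytest.approx(15.0, abs=0.5)

    def test_fat_incompressibility_enforced(self, short_run):
        st = short_run.states_D[-1]
        assert st.forces["fat_J_error"] <= 1.1e-3

    def test_interface_compressed(self, short_run):
        """The slip-tie interface carries net compression (anterior push)."""
        st = short_run.states_D[-1]
        assert st.forces["F_fat_mN"] > 0
        assert st.forces["tie_gap_max"] < 5e-3      # mm
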