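"""Circle fitting, curvature, arc-length and axial measures."""

import numpy as np
import pytest

from sansfem.biometrics import (ArcStations, DegenerateCircleError,
                                axial_measures, peripapillary_arc,
                                posterior_roc, pratt_circle_fit,
                                sample_boundary)


class TestPrattFit:
    def test_exact_on_noiseless_circle(self, rng):
        th = np.linspace(0, 2 * np.pi, 21)[:-1]
        pts = np.c_[3.0 + 12.36 * np.cos(th), -7.0 + 12.36 * np.sin(th)]
        center, r = pratt_circle_fit(pts)
        assert r == pytest.approx(12.36, abs=1e-9)
        assert center == pytest.approx([3.0, -7.0], abs=1e-9)

    def test_three_points_circumcircle(self):
        pts = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        # closed-form circumcircle of a right triangle: hypotenuse midpoint
        center, r = pratt_circle_fit(pts)
        assert center == pytest.approx([2.0, 1.5], abs=1e-9)
        assert r == pytest.approx(2.5, abs=1e-9)

    def test_collinear_degenerate(self):
        pts = np.c_[np.linspace(0, 5, 8), 2.0 * np.linspace(0, 5, 8)]
        with pytest.raises(DegenerateCircleError):
            pratt_circle_fit(pts)

    def test_translation_invariance_of_radius(self, rng):
        th = np.linspace(0.3, 1.4, 25)
        pts = np.c_[10 * np.cos(th), 10 * np.sin(th)]
        pts += 0.001 * rng.standard_normal(pts.shape)
        _, r1 = pratt_circle_fit(pts)
        _, r2 = pratt_circle_fit(pts + [123.0, -45.0])
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_partial_arc_nearly_unbiased(self, rng):
        # the Pratt normalisation keeps the radius honest on a short arc
        th = np.linspace(-0.3, 0.3, 40)
        pts = np.c_[20 * np.sin(th), 20 * np.cos(th)]
        pts += 0.005 * rng.standard_normal(pts.shape)
        _, r = pratt_circle_fit(pts)
        assert r == pytest.approx(20.0, rel=0.02)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            pratt_circle_fit([[0, 0], [1, 1]])


class TestPosteriorRoc:
    def test_undeformed_matches_ellipse_curvature(self, coarse_mesh):
        # meridional curvature radius of the outer ellipse at the posterior
        # pole is a^2 / b
        p = coarse_mesh.geom.params
        u = np.zeros(2 * coarse_mesh.n_nodes)
        roc = posterior_roc(coarse_mesh, u, window=4.0)
        assert roc == pytest.approx(p.a_out ** 2 / p.b_out, rel=0.02)

    def test_rigid_translation_invariance(self, coarse_mesh):
        u = np.zeros(2 * coarse_mesh.n_nodes)
        roc0 = posterior_roc(coarse_mesh, u)
        u[1::2] += 3.7                       # axial rigid shift
        assert posterior_roc(coarse_mesh, u) == pytest.approx(roc0, abs=1e-9)

    def test_window_too_small(self, coarse_mesh):
        u = np.zeros(2 * coarse_mesh.n_nodes)
        with pytest.raises(ValueError):
            posterior_roc(coarse_mesh, u, window=0.01)


class TestPeripapillaryArc:
    def test_reference_length_is_quarter_circumference(self, coarse_mesh):
        st = ArcStations.build(coarse_mesh, fraction=0.25)
        u = np.zeros(2 * coarse_mesh.n_nodes)
        # half-plane inner boundary length ~ quarter ellipse perimeter * 2
        full = sample_boundary(coarse_mesh, u, "shell_inner", 12)
        L_half = np.sum(np.linalg.norm(np.diff(full, axis=0), axis=1))
        assert st.deformed_length(coarse_mesh, u) == pytest.approx(
            0.25 * L_half, rel=5e-3)

    def test_translation_leaves_length(self, coarse_mesh):
        st = ArcStations.build(coarse_mesh, fraction=0.25)
        u = np.zeros(2 * coarse_mesh.n_nodes)
        L0 = st.deformed_length(coarse_mesh, u)
        u[1::2] -= 1.23
        assert st.deformed_length(coarse_mesh, u) == pytest.approx(L0)

    def test_uniform_scaling_scales_length(self, coarse_mesh):
        st = ArcStations.build(coarse_mesh, fraction=0.25)
        u = np.zeros(2 * coarse_mesh.n_nodes)
        L0 = st.deformed_length(coarse_mesh, u)
        u = 0.01 * np.tile(coarse_mesh.nodes, 1).reshape(-1)  # x -> 1.01 x
        u = 0.01 * coarse_mesh.nodes.reshape(-1)
        assert st.deformed_length(coarse_mesh, u) == pytest.approx(
            1.01 * L0, rel=1e-9)

    def test_fraction_variants(self, coarse_mesh):
        u = np.zeros(2 * coarse_mesh.n_nodes)
        l8 = peripapillary_arc(coarse_mesh, u, fraction=1 / 8)
        l4 = peripapillary_arc(coarse_mesh, u, fraction=1 / 4)
        l2 = peripapillary_arc(coarse_mesh, u, fraction=1 / 2)
        assert l8 < l4 < l2


class TestAxialMeasures:
    def test_identity_state(self, coarse_mesh):
        u = np.zeros(2 * coarse_mesh.n_nodes)
        assert axial_measures(coarse_mesh, u, u) == (0.0, 0.0)

    def test_pure_translation_is_proptosis_only(self, coarse_mesh):
        uC = np.zeros(2 * coarse_mesh.n_nodes)
        uD = uC.copy()
        uD[1::2] += 0.59
        prop, dal = axial_measures(coarse_mesh, uD, uC)
        assert prop == pytest.approx(0.59)
        assert dal == pytest.approx(0.0, abs=1e-9)

    def test_axial_compression_shortens(self, coarse_mesh):
        uC = np.zeros(2 * coarse_mesh.n_nodes)
        uD = uC.copy()
        uD[1::2] = -0.001 * coarse_mesh.nodes[:, 1]   # 0.1% axial squeeze
        prop, dal = axial_measures(coarse_mesh, uD, uC)
        assert dal == pytest.approx(-26.72, rel=1e-6)  # 0.1% of outer AL (um)
        assert prop < 0
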