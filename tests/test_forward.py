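"""FVM solver, reciprocity sensitivity matrix, and linear measurement model."""

import numpy as np
import pytest

from cceit import band, forward
from cceit.phantom import _Ellipse, rasterize, template_scene, GridSpec


@pytest.fixture(scope="module")
def toy():
    """8-electrode circular sensor on a 32x32 grid with 16x16 image pixels."""
    cfg = forward.SensorMeshConfig(solver_n=32, image_n=16,
                                   outline=_Ellipse((0, 0), (0.9, 0.9)))
    layout = band.equidistant_layout(8, coverage=0.5)
    mesh = forward.build_sensor_mesh(layout, cfg)
    ordering = forward.MeasurementOrdering(8)
    eps0 = np.ones((32, 32))
    fields = forward.solve_all_potentials(mesh, eps0)
    S = forward.compute_sensitivity(mesh, fields, ordering=ordering)
    return mesh, ordering, eps0, fields, S


@pytest.fixture(scope="module")
def sensor64():
    """Standard 32-electrode sensor at 64x64 with its sensitivity matrix."""
    layout = band.equidistant_layout()
    S = forward.sensitivity_for_layout(layout)
    return layout, S


class TestMesh:
    def test_electrode_cells_nonempty_disjoint(self):
        mesh = forward.build_sensor_mesh()
        for k in range(32):
            assert mesh.electrode_cells(k).sum() > 0
        ids = mesh.electrode_of[mesh.dirichlet]
        # each Dirichlet cell belongs to at most one electrode by encoding
        assert set(np.unique(ids)) <= set(range(-1, 32))

    def test_degenerate_coverage_errors(self):
        lay = band.ElectrodeLayout(
            32, np.arange(32) * 2 * np.pi / 32, 0.0, np.arange(32) / 31)
        with pytest.raises(ValueError):
            forward.build_sensor_mesh(lay)

    def test_rotated_layout_permutes_electrodes(self):
        """On a circular outline, rotating the layout by a quarter turn
        (8 electrode pitches, a symmetry of the Cartesian grid) permutes the
        electrode cell sets cyclically and exactly."""
        cfg = forward.SensorMeshConfig(outline=_Ellipse((0, 0), (0.9, 0.9)))
        base = band.equidistant_layout()
        rot = band.ElectrodeLayout(
            32, np.mod(base.centers + 8 * 2 * np.pi / 32, 2 * np.pi),
            base.arc_halfwidth, base.normalized_positions)
        m1 = forward.build_sensor_mesh(base, cfg)
        m2 = forward.build_sensor_mesh(rot, cfg)
        for k in range(32):
            np.testing.assert_array_equal(
                m2.electrode_cells(k), m1.electrode_cells((k + 8) % 32))


class TestSolver:
    def test_annulus_matches_analytic_log_potential(self):
        """Uniform permittivity between concentric conductors: the FVM field
        reproduces U*ln(r/r1)/ln(r0/r1) to below 1% of U at 128x128.  The
        conductor radii are the mean radii of the boundary-exposed Dirichlet
        cells (the staircase discretization's effective geometry)."""
        n = 128
        h = 2.0 / n
        c = -1 + (np.arange(n) + 0.5) * h
        x, y = np.meshgrid(c, c)
        r = np.hypot(x, y)
        inside = r < 1.0
        pad = np.pad(inside, 1, constant_values=False)
        ring = inside & (~pad[:-2, 1:-1] | ~pad[2:, 1:-1]
                         | ~pad[1:-1, :-2] | ~pad[1:-1, 2:])
        inner = r < 0.2
        vals = np.zeros((n, n))
        vals[inner] = 1.0
        phi = forward._solve_dirichlet(inside, ring | inner, vals,
                                       np.ones((n, n)))
        pin = np.pad(inner, 1, constant_values=False)
        inner_edge = inner & (~pin[:-2, 1:-1] | ~pin[2:, 1:-1]
                              | ~pin[1:-1, :-2] | ~pin[1:-1, 2:])
        r0e, r1e = r[inner_edge].mean(), r[ring].mean()
        sel = inside & ~(ring | inner) & (r > 0.2 + 3 * h) & (r < 1 - 3 * h)
        exact = np.log(r[sel] / r1e) / np.log(r0e / r1e)
        assert np.max(np.abs(phi[sel] - exact)) < 0.01

    def test_dirichlet_values_exact(self, toy):
        mesh, _, eps0, fields, _ = toy
        for k in range(8):
            cells = mesh.electrode_cells(k)
            assert np.all(fields[k][cells] == 1.0)
            others = mesh.dirichlet & ~cells
            assert np.all(fields[k][others] == 0.0)

    def test_discrete_maximum_principle(self, toy):
        mesh, _, _, fields, _ = toy
        assert np.all(fields[:, mesh.inside] <= 1.0 + 1e-12)
        assert np.all(fields[:, mesh.inside] >= -1e-12)

    def test_uniform_scaling_invariance(self, toy):
        """The field equation is homogeneous in eps: doubling a uniform
        permittivity leaves the potential unchanged."""
        mesh, _, eps0, fields, _ = toy
        phi2 = forward.solve_potential(mesh, 2.0 * eps0, excitation=0)
        assert np.allclose(phi2, fields[0], atol=1e-12)

    def test_complex_permittivity_solve(self, toy):
        mesh, _, _, _, _ = toy
        eps = np.full((32, 32), 10.0 + 100.0j)
        eps[10:15, 10:15] = 1.0 + 0.0j
        phi = forward.solve_potential(mesh, eps, excitation=2)
        assert np.iscomplexobj(phi)
        assert np.all(np.isfinite(phi[mesh.inside]))


class TestSensitivity:
    def test_reciprocity_rows_identical(self, toy):
        _, ordering, _, _, S = toy
        np.testing.assert_array_equal(S, S[ordering.swapped()])

    def test_entries_finite(self, sensor64):
        _, S = sensor64
        assert S.shape == (992, 4096)
        assert np.all(np.isfinite(S))

    def test_matches_finite_difference_jacobian(self, toy):
        """The reciprocity sensitivity agrees with brute-force finite
        differences of the direct (re-solved) capacitances within 10%."""
        mesh, ordering, eps0, fields, S = toy

        def direct_caps(eps):
            f = forward.solve_all_potentials(mesh, eps)
            return forward.capacitance_from_fields(mesh, f, eps,
                                                   ordering=ordering)

        C0 = direct_caps(eps0)
        rng = np.random.default_rng(0)
        pix = [(i, j) for i in range(16) for j in range(16)
               if (mesh.inside[2*i:2*i+2, 2*j:2*j+2]
                   & ~mesh.dirichlet[2*i:2*i+2, 2*j:2*j+2]).all()]
        sel = [pix[k] for k in rng.choice(len(pix), 20, replace=False)]
        delta = 0.01
        for (pi, pj) in sel:
            eps = eps0.copy()
            eps[2*pi:2*pi+2, 2*pj:2*pj+2] += delta
            fd = (direct_caps(eps) - C0) / delta
            s = S[:, pi * 16 + pj]
            assert np.linalg.norm(fd - s) <= 0.10 * np.linalg.norm(s)

    def test_cyclic_symmetry_of_measurements(self):
        """Circular body, uniform eps: advancing excitation and sensing
        electrodes together by a quarter turn (an exact symmetry of the
        staircase-discretized circle) leaves every measurement unchanged.
        Sub-quarter-turn rotations are only approximate on a Cartesian grid
        and are not asserted."""
        cfg = forward.SensorMeshConfig(solver_n=64, image_n=64,
                                       outline=_Ellipse((0, 0), (0.9, 0.9)))
        lay = band.equidistant_layout(8, coverage=0.5)
        mesh = forward.build_sensor_mesh(lay, cfg)
        ordering = forward.MeasurementOrdering(8)
        fields = forward.solve_all_potentials(mesh, np.ones((64, 64)))
        C = forward.capacitance_from_fields(mesh, fields, np.ones((64, 64)),
                                            ordering=ordering)
        for (a, b) in ordering.pairs:
            i = ordering.index[(a, b)]
            j = ordering.index[((a + 2) % 8, (b + 2) % 8)]
            assert C[i] == pytest.approx(C[j], rel=1e-10)


class TestSimulateCapacitance:
    def test_linearization_point_and_length(self, sensor64):
        _, S = sensor64
        eps_ref = np.full(4096, 5.0 + 2.0j)
        C_ref = S @ eps_ref
        C = forward.simulate_capacitance(S, eps_ref, eps_ref, C_ref)
        np.testing.assert_allclose(C, C_ref)
        assert C.shape == (992,)

    def test_linearity(self, sensor64):
        _, S = sensor64
        rng = np.random.default_rng(4)
        ref = np.full(4096, 1.0)
        d = rng.normal(size=4096)
        c1 = forward.simulate_capacitance(S, ref + d) - S @ ref
        c2 = forward.simulate_capacitance(S, ref + 2 * d) - S @ ref
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-10, atol=1e-14)

    def test_length_mismatch_errors(self, sensor64):
        _, S = sensor64
        with pytest.raises(ValueError):
            forward.simulate_capacitance(S, np.ones(100))

    def test_measurement_reciprocity_pre_noise(self, sensor64):
        _, S = sensor64
        _, eps = rasterize(template_scene(), GridSpec(64, 64))
        C = forward.simulate_capacitance(S, eps.ravel())
        assert len(C) == 992
        np.testing.assert_array_equal(C, C[forward.ORDERING.swapped()])


class TestLandweber:
    def test_point_spread_localization(self, toy):
        mesh, ordering, eps0, fields, S = toy
        Sr = np.real(S)
        src = 8 * 16 + 9  # an interior pixel
        C = Sr[:, src] * 1.0
        x = forward.landweber_baseline(C, Sr, iterations=500)
        pk = np.unravel_index(np.argmax(x), x.shape)
        assert abs(pk[0] - 8) <= 2 and abs(pk[1] - 9) <= 2

    def test_zero_measurements_zero_image(self, toy):
        *_, S = toy
        x = forward.landweber_baseline(np.zeros(len(S)), S, iterations=50)
        assert np.all(x == 0.0)

    def test_residual_monotone_decrease(self, toy):
        *_, S = toy
        rng = np.random.default_rng(1)
        C = np.real(S) @ rng.uniform(0, 1, S.shape[1])
        Sr = np.real(S)
        step = 1.0 / np.linalg.norm(Sr, 2) ** 2
        x = np.zeros(Sr.shape[1])
        prev = np.inf
        for _ in range(100):
            r = C - Sr @ x
            rn = np.linalg.norm(r)
            assert rn <= prev + 1e-12
            prev = rn
            x += step * (Sr.T @ r)
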