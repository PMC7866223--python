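"""Physics of the volume-integral (discrete-dipole) forward solver."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import hankel2

import mwtomo as mt
from mwtomo.analytic import cylinder_line_source_field
from mwtomo.forward import (
    DDASolver,
    complex_k2,
    greens_function,
    incident_field,
    self_term,
    wavenumber,
)

BATH = mt.DielectricProperties(20.9, 1.35)
OBJ = mt.DielectricProperties(16.9, 1.15)


class TestMaterialParameters:
    def test_k2_closed_form_value(self):
        # independent arithmetic: w^2 mu0 eps0 eps_r - j w mu0 sigma
        freq = mt.FrequencySpec(1.3e9)
        k2 = complex_k2(mt.DielectricProperties(22.0, 1.0), freq)
        w = 2 * np.pi * 1.3e9
        assert k2.real == pytest.approx((w / 299792458.0) ** 2 * 22.0, rel=1e-9)
        assert k2.imag == pytest.approx(-w * 4e-7 * np.pi * 1.0, rel=1e-9)
        assert k2 == pytest.approx(16331.6 - 10264.4j, rel=1e-4)

    def test_k2_lossless_vacuum_real(self):
        freq = mt.FrequencySpec(1.0e9)
        k2 = complex_k2(mt.DielectricProperties(1.0, 0.0), freq)
        assert k2.imag == 0.0
        assert k2.real == pytest.approx((2 * np.pi * 1e9 / 299792458.0) ** 2, rel=1e-9)

    def test_k2_passive_sign_convention(self):
        k2 = complex_k2(BATH, mt.FrequencySpec(1.5e9))
        assert k2.imag < 0
        k = wavenumber(k2)
        assert k.real > 0 and k.imag < 0

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            mt.DielectricProperties(0.5, 1.0)
        with pytest.raises(ValueError):
            mt.DielectricProperties(2.0, -0.1)


class TestGreensFunction:
    def test_symmetry_and_lossy_decay(self):
        k = wavenumber(complex_k2(BATH, mt.FrequencySpec(1.5e9)))
        assert greens_function(k, 0.03) == greens_function(k, 0.03)  # kernel G(d)
        assert abs(greens_function(k, 0.5)) < 1e-8 * abs(greens_function(k, 0.01))

    def test_lossless_far_field_decay_rate(self):
        # |G| ~ d^(-1/2) for real k
        k = wavenumber(complex_k2(mt.DielectricProperties(1.0, 0.0), mt.FrequencySpec(1e9)))
        d = np.array([5.0, 20.0])
        ratio = abs(greens_function(k, d[0])) / abs(greens_function(k, d[1]))
        assert ratio == pytest.approx(np.sqrt(d[1] / d[0]), rel=1e-3)

    def test_helmholtz_radial_identity(self):
        # (lap + k^2) G = 0 away from the source, via the radial Laplacian
        k = wavenumber(complex_k2(BATH, mt.FrequencySpec(1.0e9)))
        r, dr = 0.04, 1e-6
        g = lambda x: greens_function(k, x)
        lap = (g(r + dr) - 2 * g(r) + g(r - dr)) / dr**2 + (g(r + dr) - g(r - dr)) / (
            2 * dr * r
        )
        assert abs(lap + k**2 * g(r)) < 1e-4 * abs(k**2 * g(r))

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            greens_function(1.0 + 0j, 0.0)


class TestSelfTerm:
    @pytest.mark.parametrize("h", [0.25 / 64, 0.002, 0.001])
    def test_matches_square_cell_quadrature(self, h):
        """Closed form vs adaptive polar quadrature of G over the square cell."""
        k = wavenumber(complex_k2(mt.DielectricProperties(22.0, 1.0), mt.FrequencySpec(1.3e9)))

        def radial(theta, part):
            rmax = (h / 2) / np.cos(theta)
            val, _ = integrate.quad(
                lambda r: getattr(hankel2(0, k * r) / 4j * r, part), 0, rmax, limit=200
            )
            return val

        re, _ = integrate.quad(lambda t: radial(t, "real"), 0, np.pi / 4, limit=200)
        im, _ = integrate.quad(lambda t: radial(t, "imag"), 0, np.pi / 4, limit=200)
        exact = 8 * (re + 1j * im)
        approx = self_term(k, h)
        rel = abs(approx - exact) / abs(exact)
        # equal-area-circle approximation: sub-percent for sub-wavelength cells
        assert rel < (0.01 if abs(k) * h > 0.4 else 0.005)

    def test_small_cell_limit_log_dominated(self):
        # as k a -> 0 the -1/k^2 terms cancel and the log term of H1 survives:
        # C_self ~ area * (log behavior), not the 1/k^2 blow-up
        k = 5.0 - 0.5j
        h = 1e-4
        c = self_term(k, h)
        assert abs(c) < 1e-2 / abs(k) ** 2  # far below the 1/k^2 scale

    def test_translation_invariance_and_warning(self):
        k = wavenumber(complex_k2(BATH, mt.FrequencySpec(1.5e9)))
        assert self_term(k, 0.002) == self_term(k, 0.002)
        with pytest.warns(UserWarning, match="sub-wavelength"):
            self_term(k, 0.01)


class TestIncidentField:
    def test_linearity_and_zero_amplitude(self, small_geometry):
        grid, zone, array, freq, bath = small_geometry
        k = wavenumber(complex_k2(bath, freq))
        pts = zone.node_coords[:10]
        e1 = incident_field(array, 0, pts, k, freq)
        a2 = mt.build_antenna_array(array.n_antennas, array.diameter, 2.0)
        e2 = incident_field(a2, 0, pts, k, freq)
        assert np.allclose(e2, 2 * e1)
        a0 = mt.build_antenna_array(array.n_antennas, array.diameter, 0.0)
        assert np.all(incident_field(a0, 0, pts, k, freq) == 0)

    def test_source_receiver_reciprocity(self, small_geometry):
        _, _, array, freq, bath = small_geometry
        k = wavenumber(complex_k2(bath, freq))
        e_sr = incident_field(array, 0, array.positions[3], k, freq)
        e_rs = incident_field(array, 3, array.positions[0], k, freq)
        assert e_sr == pytest.approx(e_rs)

    def test_point_on_source_rejected(self, small_geometry):
        _, _, array, freq, bath = small_geometry
        k = wavenumber(complex_k2(bath, freq))
        with pytest.raises(ValueError):
            incident_field(array, 0, array.positions[0], k, freq)


class TestSolver:
    def test_zero_contrast_identity(self, small_geometry):
        grid, zone, array, freq, bath = small_geometry
        pmap = mt.PropertyMap.homogeneous(zone, bath, freq)
        sol = mt.solve_total_field(pmap, zone, array, 0, freq)
        assert np.array_equal(sol.E_nodes, sol.E_inc_nodes)
        solver = DDASolver(zone, array, freq, pmap.k2_background)
        assert np.allclose(sol.E_antennas[1:], solver.E_inc_ant[0][1:], rtol=1e-13)

    def test_measurement_reciprocity(self, small_phantom_sweep):
        _, _, _, mset = small_phantom_sweep
        for s, r in mset.pairs:
            a = mset.values[mset.index_of(s, r)]
            b = mset.values[mset.index_of(r, s)]
            assert abs(a - b) <= 1e-10 * abs(a)

    def test_linearity_in_source_amplitude(self, small_geometry):
        grid, zone, array, freq, bath = small_geometry
        spec = mt.PhantomSpec(bath, (((-0.012, 0.018), 0.02, OBJ),), freq.f, 0.0, 1, 0)
        pmap = mt.make_property_map(spec, grid, zone, freq)
        _, m1 = mt.forward_sweep(pmap, zone, array, freq)
        array2 = mt.build_antenna_array(array.n_antennas, array.diameter, 3.0)
        _, m3 = mt.forward_sweep(pmap, zone, array2, freq)
        assert np.allclose(m3.values, 3 * m1.values, rtol=1e-12)

    def test_measurement_count(self, small_phantom_sweep, default_geometry):
        _, _, _, mset = small_phantom_sweep
        assert len(mset) == 8 * 7
        _, _, array16 = default_geometry
        from mwtomo.forward import measurement_pairs

        assert len(measurement_pairs(16)) == 240
        assert len(measurement_pairs(3)) == 6

    def test_iterative_path_agrees_with_lu(self, small_phantom_sweep):
        pmap, solver, fields, _ = small_phantom_sweep
        it = solver.solve_iterative(pmap, 0)
        rel = np.linalg.norm(it.E_nodes - fields[0].E_nodes) / np.linalg.norm(
            fields[0].E_nodes
        )
        assert rel <= 1e-8


class TestCylinderOracle:
    """Scattered field vs the analytic cylindrical-harmonic series."""

    def _scattered_error(self, n_cells, freq_hz=1.5e9, center=(-0.01, 0.015), R=0.02):
        grid = mt.build_grid(0.25, n_cells)
        zone = mt.select_imaging_zone(grid, 0.0698)
        array = mt.build_antenna_array(16, 0.152, 1.0, grid=grid, zone=zone)
        freq = mt.FrequencySpec(freq_hz)
        k2b = complex_k2(BATH, freq)
        kb, kc = wavenumber(k2b), wavenumber(complex_k2(OBJ, freq))
        center = np.asarray(center)
        coords = zone.node_coords
        # exact cell-average of the disk indicator as the node contrast
        sub = (np.arange(16) + 0.5) / 16 - 0.5
        ox, oy = np.meshgrid(sub * grid.h, sub * grid.h, indexing="ij")
        pts = coords[:, None, None, :] + np.stack([ox, oy], axis=-1)[None]
        frac = (
            np.hypot(pts[..., 0] - center[0], pts[..., 1] - center[1]) <= R
        ).mean(axis=(1, 2))
        pmap = mt.PropertyMap(zone, k2b + frac * (complex_k2(OBJ, freq) - k2b), k2b)
        solver = DDASolver(zone, array, freq, k2b)
        fields, _ = solver.sweep(pmap)
        num, ana, inc = [], [], []
        for s in range(16):
            obs = np.delete(array.positions, s, axis=0)
            ana.append(
                cylinder_line_source_field(kb, kc, R, center, array.positions[s], obs, freq.omega)
            )
            num.append(np.delete(fields[s].E_antennas, s))
            inc.append(np.delete(solver.E_inc_ant[s], s))
        num, ana, inc = (np.concatenate(x) for x in (num, ana, inc))
        return np.linalg.norm(num - ana) / np.linalg.norm(ana - inc)

    @pytest.mark.filterwarnings("ignore:cell size")
    def test_accuracy_and_second_order_convergence(self):
        err_coarse = self._scattered_error(64)  # h ~ lambda_b/10
        err_fine = self._scattered_error(128)  # h ~ lambda_b/20
        assert err_coarse < 0.05
        assert err_fine < 0.012
        order = np.log2(err_coarse / err_fine)
        assert order > 1.5  # second-order midpoint radiation quadrature
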