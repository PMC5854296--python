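"""Coupled frequency-domain solver and the transmission-line oracle."""

import numpy as np
import pandas as pd
import pytest

import elemcochlea as ec

OMEGA = 2 * np.pi * 1000.0


def _uniform_pieces(n):
    p = ec.CochleaParams(n_elements=n)
    geo = ec.build_geometry(p, "uniform")
    elts = ec.build_bm_elements(p)
    fd = ec.assemble_fd_matrix(p, geo.effective_height_mean)
    return p, geo, elts, fd


class TestSolveVelocity:
    def test_zero_admittance_returns_excitation(self, elements64, fd64):
        z = ec.zfc_1d_uniform(fd64, OMEGA)
        y = ec.BmAdmittanceMatrix(matrix=np.zeros((64, 64), complex),
                                  omega=OMEGA, structure="diagonal")
        vs = np.zeros(64, complex)
        vs[0] = 1.0
        np.testing.assert_allclose(ec.solve_velocity(y, z, vs), vs)

    def test_zero_fluid_coupling_returns_excitation(self, elements64):
        y = ec.ybm_local(OMEGA, elements64)
        z = ec.FluidCouplingMatrix(matrix=np.zeros((64, 64), complex),
                                   omega=OMEGA, mode="uniform-1d")
        vs = np.zeros(64, complex)
        vs[0] = 1.0
        np.testing.assert_allclose(ec.solve_velocity(y, z, vs), vs)

    def test_coupled_equations_residual(self, elements64, fd64):
        """The solution satisfies p = Z_FC·v and v = v_s − Y_BM·p."""
        z = ec.zfc_1d_uniform(fd64, OMEGA)
        y = ec.ybm_local(OMEGA, elements64)
        vs = np.zeros(64, complex)
        vs[0] = 1.0
        v = ec.solve_velocity(y, z, vs)
        p = z.matrix @ v
        res = v - (vs - y.matrix @ p)
        assert np.abs(res).max() < 1e-10 * np.abs(v).max()

    def test_travelling_wave_peaks_basal_of_cf_place(self):
        """The passive peak lies basal of the tonotopic place, within a few
        mm of it (the well-known basalward shift of the passive response)."""
        p = ec.CochleaParams()
        model = ec.CochlearModel.from_params(p)
        r = model.solve(OMEGA)
        x_peak = p.x[np.argmax(np.abs(r.velocity[1:-1])) + 1]
        x_cf = ec.characteristic_place(1000.0, p)
        assert x_peak < x_cf
        assert x_cf - x_peak < 5e-3


class TestSolvePressure:
    def test_two_pressure_routes_agree(self, elements64, fd64):
        """p = Z_FC[I+Y·Z_FC]⁻¹v_s equals p = [Z_FC⁻¹+Y]⁻¹v_s."""
        z = ec.zfc_1d_uniform(fd64, OMEGA)
        y = ec.ybm_local(OMEGA, elements64)
        vs = np.zeros(64, complex)
        vs[0] = 1.0
        p1 = ec.solve_pressure(y, z, vs)
        p2 = np.linalg.solve(np.linalg.inv(z.matrix) + y.matrix, vs)
        assert np.abs(p1 - p2).max() / np.abs(p1).max() < 1e-8

    def test_helicotrema_pressure_release(self, elements64, fd64):
        z = ec.zfc_1d_uniform(fd64, OMEGA)
        y = ec.ybm_local(OMEGA, elements64)
        vs = np.zeros(64, complex)
        vs[0] = 1.0
        p = ec.solve_pressure(y, z, vs)
        assert abs(p[-1]) / np.abs(p).max() < 1e-8

    def test_zero_admittance_pressure_is_fluid_drive(self, fd64):
        z = ec.zfc_1d_uniform(fd64, OMEGA)
        y = ec.BmAdmittanceMatrix(matrix=np.zeros((64, 64), complex),
                                  omega=OMEGA, structure="diagonal")
        vs = np.zeros(64, complex)
        vs[0] = 1.0
        np.testing.assert_allclose(ec.solve_pressure(y, z, vs), z.matrix @ vs)


class TestTransmissionLine:
    def test_series_inertances(self, params64, geometry64):
        h = geometry64.effective_height_mean
        l1, l = ec.ladder_inertances(params64, h)
        rho, d = params64.fluid_density, params64.delta
        assert l1 == pytest.approx(2 * rho * d)
        assert l == pytest.approx(2 * rho * d**2 / h)

    def test_equivalence_with_elemental_route(self):
        p, geo, elts, fd = _uniform_pieces(128)
        z = ec.zfc_1d_uniform(fd, OMEGA)
        y = ec.ybm_local(OMEGA, elts)
        vs = np.zeros(128, complex)
        vs[0] = 1.0
        v_elem = ec.solve_velocity(y, z, vs)
        tl = ec.transmission_line_solve(p, elts, OMEGA, geo.effective_height_mean)
        assert np.abs(tl.velocity - v_elem).max() / np.abs(v_elem).max() < 1e-8

    def test_equivalence_random_passive_draws(self, rng):
        """Ten random passive parameter sets at N=64: ladder network and
        elemental solutions agree to the solver tolerance."""
        for _ in range(10):
            p = ec.CochleaParams(
                n_elements=64,
                f_base=float(rng.uniform(5e3, 30e3)),
                length_const=float(rng.uniform(4e-3, 10e-3)),
                q_factor=float(rng.uniform(1.5, 6.0)),
                bm_mass=float(rng.uniform(0.05, 0.5)),
            )
            geo = ec.build_geometry(p, "uniform")
            elts = ec.build_bm_elements(p)
            fd = ec.assemble_fd_matrix(p, geo.effective_height_mean)
            omega = 2 * np.pi * float(rng.uniform(200.0, p.f_base / 2))
            z = ec.zfc_1d_uniform(fd, omega)
            y = ec.ybm_local(omega, elts)
            vs = np.zeros(64, complex)
            vs[0] = 1.0
            v_elem = ec.solve_velocity(y, z, vs)
            tl = ec.transmission_line_solve(p, elts, omega, geo.effective_height_mean)
            assert np.abs(tl.velocity - v_elem).max() / np.abs(v_elem).max() < 1e-8

    def test_middle_ear_loading_enters_first_shunt(self):
        p, geo, elts, fd = _uniform_pieces(64)
        me = ec.MiddleEarParams(enabled=True, mass=0.2, stiffness=2e8, damping=5e3)
        tl = ec.transmission_line_solve(p, elts, OMEGA, geo.effective_height_mean, me=me)
        # with loading enabled the element-1 velocity differs from the drive
        assert abs(tl.velocity[0] - 1.0) > 1e-6


class TestModelAndSweep:
    def test_banded_fast_path_matches_dense_route(self, model128):
        r_fast = model128.solve(OMEGA)
        r_dense = model128.solve(OMEGA, dense=True)
        assert (np.abs(r_fast.velocity - r_dense.velocity).max()
                / np.abs(r_dense.velocity).max()) < 1e-10

    def test_sweep_schema_and_shape(self, model128):
        df = model128.sweep([500.0, 1000.0], positions=[10e-3, 20e-3])
        assert list(df.columns) == ["frequency_hz", "position_m",
                                    "magnitude_db", "phase_cycles"]
        assert len(df) == 4

    def test_empty_frequency_grid_rejected(self, model128):
        with pytest.raises(ValueError):
            model128.sweep([])

    def test_positions_outside_bm_rejected(self, model128):
        with pytest.raises(ValueError):
            model128.sweep([1000.0], positions=[40e-3])

    def test_phase_accumulates_to_the_peak(self, model128):
        """Travelling wave: phase decreases monotonically from the stapes to
        the response peak, accumulating more than one cycle."""
        df = model128.profile(2000.0)
        mag = df["magnitude_db"].to_numpy()
        ph = df["phase_cycles"].to_numpy()
        ipk = int(np.argmax(mag))
        assert np.all(np.diff(ph[:ipk]) < 0)
        assert ph[0] - ph[ipk] > 1.0

    def test_3d_and_tapered_modes_solve_with_pressure_release(self):
        for mode in ("nonuniform-1d", "3d"):
            bm_mass = 0.05 if mode == "3d" else 0.28
            p = ec.CochleaParams(n_elements=96, fluid_mode=mode, bm_mass=bm_mass)
            model = ec.CochlearModel.from_params(p)
            r = model.solve(OMEGA)
            assert abs(r.pressure[-1]) / np.abs(r.pressure).max() < 1e-10
            assert r.velocity[-1] == 0

    def test_nonlocal_modes_solve(self):
        for coupling in (ec.CouplingParams.longitudinal_default(),
                         ec.CouplingParams.feedforward_default()):
            p = ec.CochleaParams(n_elements=96)
            model = ec.CochlearModel.from_params(p, coupling=coupling)
            r = model.solve(OMEGA)
            assert np.isfinite(np.abs(r.velocity)).all()
            assert abs(r.pressure[-1]) / np.abs(r.pressure).max() < 1e-8

    def test_default_grid_is_logarithmic(self):
        g = ec.default_frequency_grid(100.0, 20e3, 100)
        ratios = g[1:] / g[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        assert g[0] == pytest.approx(100.0)
        assert g[-1] == pytest.approx(20e3)


class TestReciprocity:
    """The interior block of the coupled pressure kernel [Z_FC⁻¹+Y_BM]⁻¹ is
    symmetric for local and longitudinal micromechanics; feedforward breaks
    the symmetry by construction."""

    @staticmethod
    def _kernel(coupling):
        p, geo, elts, fd = _uniform_pieces(48)
        z = ec.zfc_1d_uniform(fd, OMEGA)
        if coupling is None:
            y = ec.ybm_local(OMEGA, elts).matrix
        elif coupling.mode == "longitudinal":
            y = ec.ybm_from_impedance(
                ec.zbm_longitudinal(OMEGA, elts, coupling), OMEGA).matrix
        else:
            y = ec.ybm_from_impedance(
                ec.zbm_feedforward(OMEGA, elts, coupling), OMEGA,
                structure="inverse-bidiagonal").matrix
        k = np.linalg.inv(np.linalg.inv(z.matrix) + y)
        return k[1:-1, 1:-1]

    def test_local_and_longitudinal_reciprocal(self):
        for coupling in (None, ec.CouplingParams.longitudinal_default()):
            k = self._kernel(coupling)
            assert np.abs(k - k.T).max() / np.abs(k).max() < 1e-10

    def test_feedforward_not_reciprocal(self):
        k = self._kernel(ec.CouplingParams.feedforward_default())
        assert np.abs(k - k.T).max() / np.abs(k).max() > 1e-3
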