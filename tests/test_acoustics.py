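import numpy as np
import pytest

from qrai.grid import Grid, DoseVolume, PressureVolume
from qrai.acoustics import (
    AcousticMedium,
    TimeSeries,
    WaveSolver,
    dose_to_pressure,
    propagate,
    analytic_sphere_signal,
    analytic_smoothed_sphere_signal,
    sphere_pressure,
    smoothed_sphere_pressure,
)
from conftest import gaussian_blob


class TestDoseToPressure:
    def test_hand_value(self, grid2d):
        """Gamma=0.11, eta=1, rho=1000, D=0.0172 Gy -> p0 = 1.892 Pa."""
        med = AcousticMedium(grid2d, c=1500.0, rho=1000.0, grueneisen=0.11, eta_th=1.0)
        dose = DoseVolume(grid2d, np.full(grid2d.shape, 0.0172))
        p0 = dose_to_pressure(dose, med)
        np.testing.assert_allclose(p0.values, 1.892, rtol=1e-12)

    def test_zero_dose_zero_pressure(self, grid2d, water2d):
        p0 = dose_to_pressure(DoseVolume(grid2d, np.zeros(grid2d.shape)), water2d)
        assert np.all(p0.values == 0.0)

    def test_linearity(self, grid2d, water2d, rng):
        d = rng.random(grid2d.shape)
        p1 = dose_to_pressure(DoseVolume(grid2d, d), water2d)
        p2 = dose_to_pressure(DoseVolume(grid2d, 2 * d), water2d)
        np.testing.assert_allclose(p2.values, 2 * p1.values, rtol=1e-12)

    def test_grid_mismatch_raises(self, grid2d, water2d):
        other = Grid((16, 16), (1e-3, 1e-3))
        with pytest.raises(ValueError, match="grid"):
            dose_to_pressure(DoseVolume(other, np.zeros(other.shape)), water2d)


class TestSolverBasics:
    def test_zero_p0_zero_recordings(self, grid2d, water2d):
        p0 = PressureVolume(grid2d, np.zeros(grid2d.shape), role="p0")
        recs = propagate(p0, water2d, [(0.02, 0.02)], duration=1e-5)
        assert all(np.all(r.samples == 0.0) for r in recs)

    def test_causality(self, grid2d, water2d):
        """Signal stays ~0 until the geometric arrival time."""
        p0 = gaussian_blob(grid2d, (8, 16), sigma_vox=1.0)
        sensor = (24e-3, 16e-3)
        recs = propagate(p0, water2d, [sensor], duration=2e-5, pml_width=6)
        r = recs[0]
        dist = (24 - 8) * 1e-3
        arrival = (dist - 4e-3) / 1500.0  # a few voxels early for the blob width
        before = r.samples[r.times < arrival]
        assert np.max(np.abs(before)) < 0.01 * np.max(np.abs(r.samples))

    def test_cfl_violation_reports_max_dt(self, water2d):
        with pytest.raises(ValueError, match="maximum stable dt"):
            WaveSolver(water2d, dt=1e-5)

    def test_sensor_outside_grid_raises(self, grid2d, water2d):
        p0 = gaussian_blob(grid2d, (16, 16))
        with pytest.raises(ValueError, match="outside"):
            propagate(p0, water2d, [(1.0, 1.0)], duration=1e-5)

    def test_linearity_of_propagation(self, grid2d, hetero2d, rng):
        s = WaveSolver(hetero2d, pml_width=4)
        idx = np.array([[5, 20], [25, 10]])
        a = rng.standard_normal(grid2d.shape)
        b = rng.standard_normal(grid2d.shape)
        ra = s.record(a, idx, 40)
        rb = s.record(b, idx, 40)
        rab = s.record(2.0 * a - 0.5 * b, idx, 40)
        np.testing.assert_allclose(rab, 2.0 * ra - 0.5 * rb, atol=1e-10)


class TestAdjoint:
    def test_dot_product_identity_heterogeneous(self, hetero2d, rng):
        s = WaveSolver(hetero2d, pml_width=4)
        idx = np.array([[3, 4], [20, 25], [14, 7]])
        x = rng.standard_normal(hetero2d.grid.shape)
        y = rng.standard_normal((3, 30))
        lhs = float(np.sum(s.record(x, idx, 30) * y))
        rhs = float(np.sum(x * s.record_adjoint(y, idx)))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_adjoint_matches_explicit_matrix(self):
        """On a tiny grid, build A column by column and compare A^T y."""
        g = Grid((7, 6), (1e-3, 1e-3))
        med = AcousticMedium(g, c=1500.0)
        s = WaveSolver(med, pml_width=2)
        idx = np.array([[1, 1], [5, 4]])
        n_steps = 12
        nvox = np.prod(g.shape)
        A = np.zeros((2 * n_steps, nvox))
        for j in range(nvox):
            e = np.zeros(nvox)
            e[j] = 1.0
            A[:, j] = s.record(e.reshape(g.shape), idx, n_steps).ravel()
        rng = np.random.default_rng(0)
        y = rng.standard_normal((2, n_steps))
        expected = (A.T @ y.ravel()).reshape(g.shape)
        np.testing.assert_allclose(s.record_adjoint(y, idx), expected, atol=1e-12)


class TestAnalyticSphere:
    def test_peak_amplitude_and_arrival(self):
        """Peak +p0*a/(2r) at t=(r-a)/c: a=2mm, r=10mm -> +0.1 Pa."""
        c, dt = 1500.0, 1e-9
        ts = analytic_sphere_signal(1.0, 2e-3, 10e-3, c, dt)
        assert ts.samples.max() == pytest.approx(0.1, rel=1e-3)
        t_peak = ts.times[np.argmax(ts.samples)]
        assert t_peak == pytest.approx((10e-3 - 2e-3) / c, abs=2 * dt)

    def test_causal_silence_before_arrival(self):
        c = 1500.0
        ts = analytic_sphere_signal(1.0, 2e-3, 10e-3, c, 1e-8)
        before = ts.samples[ts.times < (10e-3 - 2e-3) / c - 1e-8]
        assert np.all(before == 0.0)

    def test_one_over_r_decay(self):
        a = analytic_sphere_signal(1.0, 2e-3, 10e-3, 1500.0, 1e-9)
        b = analytic_sphere_signal(1.0, 2e-3, 20e-3, 1500.0, 1e-9)
        assert b.samples.max() == pytest.approx(0.5 * a.samples.max(), rel=1e-3)

    def test_detector_inside_sphere_raises(self):
        with pytest.raises(ValueError, match="outside"):
            analytic_sphere_signal(1.0, 5e-3, 4e-3, 1500.0, 1e-8)

    def test_smoothed_reduces_to_n_wave(self):
        """As sigma -> 0 the regularized closed form approaches the N-wave."""
        sharp = analytic_sphere_signal(1.0, 3e-3, 12e-3, 1500.0, 1e-9, duration=1.4e-5)

        def err(sigma):
            smooth = analytic_smoothed_sphere_signal(
                1.0, 3e-3, sigma, 12e-3, 1500.0, 1e-9, duration=1.4e-5
            )
            return np.linalg.norm(sharp.samples - smooth.samples) / np.linalg.norm(
                sharp.samples
            )

        assert err(1e-5) < err(1e-4) < err(1e-3)
        assert err(1e-5) < 0.07


@pytest.fixture(scope="module")
def setup3d():
    n, dx = 64, 1e-3
    g = Grid((n, n, n), (dx, dx, dx))
    med = AcousticMedium(g, c=1500.0)
    center = np.array([n // 2 * dx] * 3)
    det = center + np.array([14 * dx, 0.0, 0.0])
    return g, med, center, det


class TestSolverOracle:
    """Solver vs the closed-form spherical-source solution in 3D."""

    @pytest.mark.parametrize("radius_vox", [2, 4, 6])
    def test_sphere_oracle_within_two_percent(self, setup3d, radius_vox):
        g, med, center, det = setup3d
        dx = g.spacing[0]
        c = 1500.0
        a, sig, r = radius_vox * dx, dx, 14 * dx
        p0 = smoothed_sphere_pressure(g, center, a, sig)
        solver = WaveSolver(med, cfl=0.3, pml_width=8)
        idx = np.array([g.index_of(det)])
        n_steps = int(round((r + 4 * a + 6 * sig) / c / solver.dt))
        rec = solver.record(p0.values, idx, n_steps)[0]
        oracle = analytic_smoothed_sphere_signal(
            1.0, a, sig, r, c, solver.dt, duration=n_steps * solver.dt
        )
        err = np.linalg.norm(rec - oracle.samples) / np.linalg.norm(oracle.samples)
        assert err < 0.02

    def test_boundary_absorption(self, setup3d):
        """Sensor energy decays to near zero after the last arrival."""
        g, med, center, det = setup3d
        dx = g.spacing[0]
        p0 = smoothed_sphere_pressure(g, center, 3 * dx, dx)
        solver = WaveSolver(med, cfl=0.3, pml_width=8)
        idx = np.array([g.index_of(det)])
        # run well past the direct arrival so wrap-around would show up
        n_steps = int(round(2.2 * g.extent[0] / 1500.0 / solver.dt))
        rec = solver.record(p0.values, idx, n_steps)[0]
        peak = np.abs(rec).max()
        tail = np.abs(rec[int(0.7 * n_steps):]).max()
        assert tail < 0.01 * peak


class TestTimeSeries:
    def test_resample_preserves_content(self):
        t = np.arange(400) * 1e-8
        ts = TimeSeries(np.sin(2 * np.pi * 5e5 * t) * np.hanning(400), dt=1e-8)
        down = ts.resample(2e-8)
        assert down.samples.size == 200
        back = down.resample(1e-8)
        err = np.linalg.norm(back.samples - ts.samples) / np.linalg.norm(ts.samples)
        assert err < 0.05

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            TimeSeries(np.array([1.0, np.nan]), dt=1e-8)
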