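import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glecell.correlations import (
    CorrKind,
    binned_conditional,
    conditional_velocity,
    moment_report,
    msd,
    msd_vacf_consistency,
    rescale_velocities,
    second_difference_stencil,
    vacf,
)
from glecell.errors import DegenerateInputError, ParameterError
from glecell.kernel_model import forward_msd
from glecell.trajectory_io import VelocitySeries, velocities

from conftest import make_trajectory

DT = 0.002


def vel_series(*components, dt=DT, cell_id="v"):
    return VelocitySeries(cell_id=cell_id, v=np.array(components, dtype=float), dt=dt)


class TestVacf:
    def test_constant_series(self):
        cf = vacf(vel_series([3.0] * 10, [3.0] * 10), max_lag=4)
        np.testing.assert_allclose(cf.values, 9.0)

    def test_alternating_series(self):
        cf = vacf(vel_series([1, -1, 1, -1]), max_lag=2)
        np.testing.assert_allclose(cf.values, [1, -1, 1])
        np.testing.assert_array_equal(cf.counts, [4, 3, 2])

    def test_matches_direct_sum(self):
        # FFT estimator against the naive double loop
        rng = np.random.default_rng(3)
        v = rng.normal(size=50)
        cf = vacf(vel_series(v), max_lag=10)
        for i in range(11):
            direct = np.mean(v[: 50 - i] * v[i:])
            assert cf.values[i] == pytest.approx(direct, rel=1e-12)

    def test_iid_series_decorrelates(self):
        rng = np.random.default_rng(4)
        n, s = 200_000, 2.5
        cf = vacf(vel_series(rng.normal(0, s, n)), max_lag=5)
        bound = 4 * s**2 / np.sqrt(n)
        assert cf.values[0] == pytest.approx(s**2, abs=bound)
        assert np.all(np.abs(cf.values[1:]) < bound)

    def test_lag_zero_is_mean_squared_velocity(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 3, (2, 1000))
        cf = vacf(VelocitySeries("c", v, DT), max_lag=3)
        assert cf.values[0] == pytest.approx(np.mean(v**2), rel=1e-12)

    def test_max_lag_validation(self):
        with pytest.raises(ParameterError):
            vacf(vel_series([1, 2, 3]), max_lag=3)


class TestMsd:
    def test_ballistic_law(self):
        v, n = 7.0, 50
        traj = make_trajectory(v * np.arange(n) * DT)
        cf = msd(traj, max_lag=10)
        # y is flat, so the component average halves the ballistic law
        np.testing.assert_allclose(cf.values, 0.5 * (v * cf.lags) ** 2, atol=1e-12)
        assert cf.values[0] == 0.0

    def test_oscillating_positions(self):
        traj = make_trajectory([0, 1, 0, 1, 0])
        cf = msd(traj, max_lag=2)
        assert 2 * cf.values[1] == pytest.approx(1.0)  # undo flat-y averaging
        assert 2 * cf.values[2] == pytest.approx(0.0)

    def test_matches_markovian_closed_form(self, p_std):
        from glecell import KernelParams, kernel_to_embedding, simulate

        p = KernelParams(a=5.0, b=1e-9, tau=0.5, omega=120.0)  # near-Markovian
        e = kernel_to_embedding(p, 1000.0)
        traj = simulate(e, 200_000, DT, seed=9)
        cf = msd(traj, max_lag=50)
        a, B = 5.0, 1000.0
        t = cf.lags
        closed = 2 * B * (t / a - (1 - np.exp(-a * t)) / a**2)
        np.testing.assert_allclose(cf.values[1:], closed[1:], rtol=0.06)


class TestConsistency:
    def test_exact_ballistic_identity(self):
        v = 3.0
        lags = np.arange(20) * DT
        msd_cf = type("M", (), {})()
        from glecell.correlations import CorrelationFunction

        msd_cf = CorrelationFunction(CorrKind.MSD, lags, (v * lags) ** 2, np.ones(20), dt=DT)
        vacf_cf = CorrelationFunction(CorrKind.VACF, lags[:-1], np.full(19, v**2), np.ones(19), dt=DT)
        rep = msd_vacf_consistency(msd_cf, vacf_cf)
        assert rep["max_abs_residual"] == pytest.approx(0.0, abs=1e-9)

    def test_corruption_is_localized(self):
        from glecell.correlations import CorrelationFunction

        v = 3.0
        lags = np.arange(20) * DT
        vals = (v * lags) ** 2
        vals[10] += 1.0
        msd_cf = CorrelationFunction(CorrKind.MSD, lags, vals, np.ones(20), dt=DT)
        vacf_cf = CorrelationFunction(CorrKind.VACF, lags[:-1], np.full(19, v**2), np.ones(19), dt=DT)
        rep = msd_vacf_consistency(msd_cf, vacf_cf)
        hit = np.nonzero(np.abs(rep["residuals"]) > 1e-9)[0]
        assert set(hit) == {9, 10, 11}

    def test_mismatched_dt_rejected(self):
        from glecell.correlations import CorrelationFunction

        a = CorrelationFunction(CorrKind.MSD, np.arange(5) * 0.002, np.zeros(5), np.ones(5))
        b = CorrelationFunction(CorrKind.VACF, np.arange(5) * 0.001, np.ones(5), np.ones(5))
        with pytest.raises(ParameterError):
            msd_vacf_consistency(a, b)

    def test_stencil_inverts_forward_model(self, p_std):
        # curvature of the exact model MSD reproduces the model VACF to O(Δ²)
        from glecell.kernel_model import forward_vacf

        m = forward_msd(p_std, 1000.0, 0.05, DT)
        c = forward_vacf(p_std, 1000.0, 0.05, DT)
        stencil = second_difference_stencil(m.values, DT)
        np.testing.assert_allclose(stencil[1:], c.values[1 : len(stencil)], rtol=0.01)


class TestRescaling:
    def test_single_cell_standardized(self):
        out = rescale_velocities([vel_series([1, 2, 3])], mode="per_cell")
        assert np.mean(out["samples"]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(out["samples"]) == pytest.approx(1.0)

    def test_per_cell_collapses_heterogeneous_gaussians(self):
        rng = np.random.default_rng(6)
        cells = [
            vel_series(rng.normal(10, 1, 20_000), cell_id="fast"),
            vel_series(rng.normal(-10, 1, 20_000), cell_id="slow"),
        ]
        rep = moment_report(rescale_velocities(cells, mode="per_cell")["samples"])
        assert abs(rep["mean"]) < rep["clt_bound"]
        assert abs(rep["std"] - 1) < rep["clt_bound"]
        assert abs(rep["excess_kurtosis"]) < 0.1

    def test_ensemble_rescaling_reveals_mixture(self):
        rng = np.random.default_rng(7)
        cells = [
            vel_series(rng.normal(10, 1, 20_000), cell_id="fast"),
            vel_series(rng.normal(-10, 1, 20_000), cell_id="slow"),
        ]
        rep = moment_report(rescale_velocities(cells, mode="ensemble")["samples"])
        # symmetric two-point mixture: excess kurtosis -> -2, far from Gaussian
        assert rep["excess_kurtosis"] < -1.5

    def test_degenerate_cell_rejected(self):
        with pytest.raises(DegenerateInputError):
            rescale_velocities([vel_series([2.0, 2.0, 2.0])], mode="per_cell")


class TestConditional:
    def test_lag_zero_deterministic(self):
        from glecell.correlations import CorrelationFunction

        cf = CorrelationFunction(CorrKind.VACF, np.arange(3) * DT, [4.0, 2.0, 1.0], np.ones(3))
        cond = conditional_velocity(cf, v1=1.5, lag=0)
        assert cond.mean == pytest.approx(1.5)
        assert cond.variance == pytest.approx(0.0)

    def test_independence_limit(self):
        from glecell.correlations import CorrelationFunction

        cf = CorrelationFunction(CorrKind.VACF, np.arange(3) * DT, [4.0, 0.0, 0.0], np.ones(3))
        cond = conditional_velocity(cf, v1=9.0, lag=1)
        assert cond.mean == 0.0
        assert cond.variance == pytest.approx(4.0)

    def test_non_psd_rejected(self):
        from glecell.correlations import CorrelationFunction

        cf = CorrelationFunction(CorrKind.VACF, np.arange(2) * DT, [1.0, 1.5], np.ones(2))
        with pytest.raises(ParameterError):
            conditional_velocity(cf, v1=0.0, lag=1)

    @settings(deadline=None, max_examples=50)
    @given(
        c0=st.floats(0.1, 1e4),
        rho=st.floats(-1.0, 1.0),
        v1=st.floats(-100, 100),
    )
    def test_two_point_covariance_psd(self, c0, rho, v1):
        # any stored pair with |C_lag| <= C_0 gives a valid (PSD) conditional
        from glecell.correlations import CorrelationFunction

        cl = rho * c0
        cf = CorrelationFunction(CorrKind.VACF, np.arange(2) * DT, [c0, cl], np.ones(2))
        cond = conditional_velocity(cf, v1=v1, lag=1)
        assert cond.variance >= -1e-9
        sigma = np.array([[c0, cl], [cl, c0]])
        assert np.linalg.eigvalsh(sigma).min() >= -1e-9 * c0

    def test_binned_conditional_on_gaussian_pairs(self):
        # AR(1) Gaussian series: empirical conditional law matches the VACF law
        rng = np.random.default_rng(8)
        rho, n = 0.6, 400_000
        v = np.empty(n)
        v[0] = rng.normal()
        eps = rng.normal(0, np.sqrt(1 - rho**2), n)
        for i in range(1, n):
            v[i] = rho * v[i - 1] + eps[i]
        vel = vel_series(v)
        cf = vacf(vel, max_lag=2)
        emp = binned_conditional(vel, lag=1, bin_edges=np.linspace(-2, 2, 9))
        for center, m, var, cnt in zip(emp["centers"], emp["means"], emp["variances"], emp["counts"]):
            if cnt < 1000 or abs(center) < 0.4:
                continue
            pred = conditional_velocity(cf, v1=center, lag=1)
            assert m == pytest.approx(pred.mean, rel=0.08)
            assert var == pytest.approx(pred.variance, rel=0.05)
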