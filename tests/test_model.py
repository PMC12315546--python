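"""Laplace location-scale spline model: likelihood, fitting, bands."""

import warnings

import numpy as np
import pytest
from scipy import stats

from icvnorm.model import (
    EXACT_95_MULTIPLE,
    FitWarning,
    LaplaceTrajectoryFit,
    fit,
    log_likelihood,
)
from icvnorm.splines import build_basis


@pytest.fixture(scope="module")
def basis():
    return build_basis()


def simulate(theta_mu, theta_b, n, seed, basis):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(18, 90, n)
    B = basis.design_matrix(ages)
    v = B @ np.asarray(theta_mu) + rng.laplace(0, np.exp(B @ np.asarray(theta_b)))
    return ages, v


class TestLogLikelihood:
    def test_single_datum_at_location_with_half_scale_is_zero(self, basis):
        """v = mu, b = 0.5: log p = -ln(2*0.5) - 0 = 0."""
        theta_mu = np.full(4, 7.0)
        theta_b = np.full(4, np.log(0.5))
        ll = log_likelihood(theta_mu, theta_b, [50.0], [7.0], basis)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_identical_points(self, basis):
        theta_mu, theta_b = np.full(4, 7.0), np.full(4, np.log(0.3))
        one = log_likelihood(theta_mu, theta_b, [40.0], [7.5], basis)
        many = log_likelihood(theta_mu, theta_b, [40.0] * 8, [7.5] * 8, basis)
        assert many == pytest.approx(8 * one, rel=1e-12)

    def test_matches_textbook_density_oracle(self, basis, rng):
        """Equals an independent sum of scipy Laplace log-densities to 1e-10."""
        theta_mu = rng.normal(8, 1, 4)
        theta_b = rng.normal(np.log(0.4), 0.2, 4)
        ages = rng.uniform(18, 90, 200)
        v = rng.normal(8, 1, 200)
        B = basis.design_matrix(ages)
        mu, b = B @ theta_mu, np.exp(B @ theta_b)
        oracle = float(np.sum(stats.laplace.logpdf(v, loc=mu, scale=b)))
        ours = log_likelihood(theta_mu, theta_b, ages, v, basis)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_empty_data_rejected(self, basis):
        with pytest.raises(ValueError, match="nonempty"):
            log_likelihood(np.zeros(4), np.zeros(4), [], [], basis)


class TestFit:
    def test_degree0_recovers_median_and_mad(self, rng):
        """Single-segment constant fit = sample median and MAD-about-median."""
        v = rng.normal(100, 10, 1001)  # odd n: unique median
        ages = rng.uniform(18, 90, 1001)
        b0 = build_basis((54.0,), degree=0)
        f = fit(ages, v, b0)
        med = np.median(v)
        mad = np.mean(np.abs(v - med))
        assert f.converged
        assert f.theta_mu[0] == pytest.approx(med, rel=1e-6)
        assert np.exp(f.theta_b[0]) == pytest.approx(mad, rel=1e-6)

    def test_parameter_recovery_on_simulated_trajectories(self, basis):
        theta_mu = np.array([1100.0, 1080.0, 1030.0, 950.0])
        theta_b = np.log([45.0, 50.0, 55.0, 60.0])
        ages, v = simulate(theta_mu, theta_b, 4000, 42, basis)
        f = fit(ages, v, basis)
        assert f.converged
        for age in (30.0, 50.0, 70.0):
            mu_true = basis.evaluate(theta_mu, [age])[0]
            b_true = np.exp(basis.evaluate(theta_b, [age]))[0]
            assert f.location([age])[0] == pytest.approx(mu_true, rel=0.02)
            assert f.scale([age])[0] == pytest.approx(b_true, rel=0.10)

    def test_duplicated_dataset_gives_identical_fit(self, basis):
        ages, v = simulate(np.full(4, 8.0), np.full(4, np.log(0.4)), 500, 7, basis)
        f1 = fit(ages, v, basis)
        f2 = fit(np.r_[ages, ages], np.r_[v, v], basis)
        assert np.allclose(f1.theta_mu, f2.theta_mu, atol=1e-6)
        assert np.allclose(f1.theta_b, f2.theta_b, atol=1e-6)

    def test_shift_and_scale_equivariance(self, basis):
        ages, v = simulate(np.full(4, 8.0), np.full(4, np.log(0.4)), 800, 8, basis)
        f = fit(ages, v, basis)
        f_shift = fit(ages, v + 55.0, basis)
        assert np.allclose(f_shift.theta_mu, f.theta_mu + 55.0, atol=1e-6)
        assert np.allclose(f_shift.theta_b, f.theta_b, atol=1e-6)
        f_scaled = fit(ages, 2.5 * v, basis)
        assert np.allclose(f_scaled.theta_mu, 2.5 * f.theta_mu, atol=1e-5)
        assert np.allclose(np.exp(f_scaled.theta_b), 2.5 * np.exp(f.theta_b), rtol=1e-5)

    def test_objective_never_below_initialization(self, basis):
        """Accepted ascent steps only increase the objective, so the final
        exact log-likelihood is at least the L2-initialization's."""
        ages, v = simulate(np.full(4, 8.0), np.full(4, np.log(0.4)), 600, 9, basis)
        f = fit(ages, v, basis)
        B = basis.design_matrix(ages)
        beta0, *_ = np.linalg.lstsq(B, v, rcond=None)
        mad0 = np.mean(np.abs(v - B @ beta0))
        ll0 = log_likelihood(beta0, np.full(4, np.log(mad0)), ages, v, basis)
        assert f.log_likelihood >= ll0

    def test_robust_to_symmetric_outlier_contamination(self, basis, rng):
        """5% contamination at +/-10 scales moves the L1 location less than
        the least-squares spline location at mid-ages."""
        theta_mu = np.array([1100.0, 1080.0, 1030.0, 950.0])
        theta_b = np.full(4, np.log(40.0))
        ages, v = simulate(theta_mu, theta_b, 3000, 11, basis)
        v_cont = v.copy()
        idx = rng.choice(3000, 150, replace=False)
        v_cont[idx] += rng.choice([-1, 1], 150) * 10 * 40.0 * rng.uniform(1, 2, 150)
        B = basis.design_matrix(ages)
        mid = basis.design_matrix([40.0, 50.0, 60.0])

        def l2_curve(vol):
            beta, *_ = np.linalg.lstsq(B, vol, rcond=None)
            return mid @ beta

        l1_shift = np.abs(
            fit(ages, v_cont, basis).location([40.0, 50.0, 60.0])
            - fit(ages, v, basis).location([40.0, 50.0, 60.0])
        )
        l2_shift = np.abs(l2_curve(v_cont) - l2_curve(v))
        assert np.mean(l1_shift) < np.mean(l2_shift)

    def test_thin_data_warns(self, basis):
        with pytest.warns(FitWarning, match="unstable"):
            fit([30.0, 50.0, 70.0] * 3, [8.0, 8.1, 7.9] * 3, basis)

    def test_non_convergence_warns_and_flags(self, basis):
        ages, v = simulate(np.full(4, 8.0), np.full(4, np.log(0.4)), 500, 13, basis)
        with pytest.warns(FitWarning, match="did not converge"):
            f = fit(ages, v, basis, max_iter=2)
        assert not f.converged

    def test_json_round_trip(self, basis, tmp_path):
        ages, v = simulate(np.full(4, 8.0), np.full(4, np.log(0.4)), 400, 15, basis)
        f = fit(ages, v, basis, roi="hippocampus", group=("Asian", "Female"))
        path = tmp_path / "fit.json"
        f.to_json(path)
        back = LaplaceTrajectoryFit.from_json(path)
        assert np.allclose(back.theta_mu, f.theta_mu)
        assert np.allclose(back.theta_b, f.theta_b)
        assert back.roi == "hippocampus" and back.group == ("Asian", "Female")


class TestPredict:
    def make_fit(self, theta_mu, theta_b, basis, **kw):
        return LaplaceTrajectoryFit(
            basis=basis,
            theta_mu=np.asarray(theta_mu, dtype=float),
            theta_b=np.asarray(theta_b, dtype=float),
            log_likelihood=0.0,
            converged=True,
            n_iterations=0,
            n_subjects=0,
            **kw,
        )

    def test_unit_scale_gives_halfwidth_three(self, basis):
        f = self.make_fit(np.full(4, 10.0), np.zeros(4), basis)
        mu, b, lo, hi = f.predict([25.0, 50.0, 75.0])
        assert np.allclose(hi - mu, 3.0)
        assert np.allclose(mu - lo, 3.0)

    def test_exact_95_multiple_is_almost_three(self):
        """-ln(0.05) = 2.9957...: the 95% interval is almost exactly mu+/-3b."""
        assert EXACT_95_MULTIPLE == pytest.approx(2.9957, abs=1e-4)
        assert round(EXACT_95_MULTIPLE) == 3

    def test_band_coverage_on_simulated_draws(self, basis, rng):
        """Empirical coverage of mu+/-3b is ~1 - e^-3 = 0.9502 (1e5 draws)."""
        f = self.make_fit(np.full(4, 8.0), np.full(4, np.log(0.4)), basis)
        ages = rng.uniform(18, 90, 100_000)
        mu, b, lo, hi = f.predict(ages)
        draws = rng.laplace(mu, b)
        coverage = np.mean((draws >= lo) & (draws <= hi))
        assert 0.944 <= coverage <= 0.956

    def test_extrapolation_requires_flag(self, basis):
        f = self.make_fit(np.full(4, 8.0), np.zeros(4), basis)
        with pytest.raises(ValueError):
            f.predict([95.0])
        mu, *_ = f.predict([95.0], allow_extrapolation=True)
        assert np.isfinite(mu).all()

    def test_exponentiate_maps_band_back_to_volume_units(self, basis):
        f = self.make_fit(np.full(4, np.log(20.0)), np.full(4, np.log(0.3)), basis,
                          log_transformed=True)
        mu, b, lo, hi = f.predict([50.0], exponentiate=True)
        assert mu[0] == pytest.approx(20.0)
        assert lo[0] == pytest.approx(20.0 * np.exp(-0.9))
        assert hi[0] == pytest.approx(20.0 * np.exp(0.9))
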