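"""ICV-correction schemes: division, residual, covariate, matching, log."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from icvnorm.cohort import (
    ALL_GROUPS,
    ICV_COLUMN,
    CohortSpec,
    GroupLabel,
    RoiModel,
    generate_cohort,
)
from icvnorm.model import fit as fit_model
from icvnorm.normalization import (
    COVARIATE_ICV,
    covariate_adjust_flag,
    divide_normalize,
    invert_log_transform,
    log_transform,
    match_groups,
    residual_normalize,
)
from icvnorm.qc import aggregate_subjects
from icvnorm.splines import build_basis

AF, BF = GroupLabel("Asian", "Female"), GroupLabel("Black", "Female")


def subjects_frame(icv, roi, sid0=0, race="Asian", sex="Female"):
    icv = np.asarray(icv, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": [f"x{sid0 + i:05d}" for i in range(len(icv))],
            "sex": sex,
            "race": race,
            "age": 50.0,
            "roi": np.asarray(roi, dtype=float),
            ICV_COLUMN: icv,
        }
    )


def icv_proportional_cohort(n=5000, scale_frac=0.05, seed=17):
    spec = CohortSpec(
        group_sizes={AF: n},
        roi_models={"roi": RoiModel((0.05,) * 4, scale_frac)},
        log_normal_rois=frozenset(),
        visits_per_subject_range=(1, 1),
        scans_per_visit_range=(1, 1),
        all_fail_fraction=0.0,
        seed=seed,
    )
    subjects, _ = aggregate_subjects(generate_cohort(spec))
    return subjects


class TestDivideNormalize:
    def test_equal_icvs_are_identity(self):
        df = subjects_frame([1400.0] * 4, [3.9, 4.0, 4.1, 4.2])
        out = divide_normalize(df).records
        assert np.allclose(out["roi"], df["roi"])

    def test_exact_proportionality_collapses_to_mean(self):
        df = subjects_frame([1000.0, 1100.0], [1.0, 1.1])
        out = divide_normalize(df).records
        assert np.allclose(out["roi"], [1.05, 1.05])

    def test_removes_icv_correlation(self):
        """Volumes proportional to ICV plus Laplace noise: |r| < 0.05 after."""
        subjects = icv_proportional_cohort()
        out = divide_normalize(subjects).records
        r = np.corrcoef(out["roi"], subjects[ICV_COLUMN])[0, 1]
        assert abs(r) < 0.05

    def test_mean_volume_approximately_preserved(self):
        subjects = icv_proportional_cohort(n=2000, seed=3)
        out = divide_normalize(subjects)
        assert out.records["roi"].mean() == pytest.approx(
            subjects["roi"].mean(), rel=0.02
        )
        assert out.reference_mean_icv == pytest.approx(
            subjects[ICV_COLUMN].mean()
        )

    def test_division_is_idempotent(self):
        subjects = icv_proportional_cohort(n=500, seed=4)
        once = divide_normalize(subjects).records
        twice = divide_normalize(once).records
        pd.testing.assert_frame_equal(once, twice)

    def test_positivity_preserved(self):
        subjects = icv_proportional_cohort(n=500, seed=5)
        out = divide_normalize(subjects).records
        assert (out["roi"] > 0).all()

    def test_nonpositive_icv_names_subject(self):
        df = subjects_frame([1400.0, 0.0], [4.0, 4.0])
        with pytest.raises(ValueError, match="x00001"):
            divide_normalize(df)


class TestResidualNormalize:
    def test_exact_line_removed(self):
        icv = np.linspace(1200, 1700, 40)
        df = subjects_frame(icv, 2.0 + 0.003 * icv)
        out = residual_normalize(df).records
        assert np.allclose(out["roi"], 2.0 + 0.003 * icv.mean(), atol=1e-8)

    def test_icv_independent_data_nearly_identity(self, rng):
        icv = rng.normal(1450, 110, 800)
        roi = rng.laplace(4.0, 0.2, 800)
        df = subjects_frame(icv, roi)
        out = residual_normalize(df)
        # slope ~ O(noise scale / (icv sd * sqrt(n))): far below 1e-3 roi/mL
        assert abs(out.residual_slopes["roi"]) < 1e-3
        assert np.allclose(out.records["roi"], roi, atol=0.5)

    def test_slope_matches_grid_search_oracle(self, rng):
        """LAD slope within 1% of a brute-force absolute-error grid search."""
        icv = rng.normal(1450, 110, 600)
        roi = 1.0 + 0.004 * icv + rng.laplace(0, 0.3, 600)
        df = subjects_frame(icv, roi)
        slope = residual_normalize(df).residual_slopes["roi"]

        def sad(beta):  # sum of absolute deviations at the optimal intercept
            r = roi - beta * icv
            return np.sum(np.abs(r - np.median(r)))

        grid = np.linspace(0.002, 0.006, 4001)
        oracle = grid[np.argmin([sad(b) for b in grid])]
        assert slope == pytest.approx(oracle, rel=0.01)

    def test_constant_icv_reference_rejected(self):
        df = subjects_frame([1400.0] * 10, np.linspace(3, 4, 10))
        with pytest.raises(ValueError, match="constant"):
            residual_normalize(df)


class TestCovariateAdjust:
    def test_flag_token(self):
        assert covariate_adjust_flag() == COVARIATE_ICV

    def test_no_token_means_base_model(self, rng):
        ages = rng.uniform(18, 90, 400)
        v = rng.laplace(4.0, 0.2, 400)
        basis = build_basis()
        f1 = fit_model(ages, v, basis)
        f2 = fit_model(ages, v, basis)
        assert f1.covariate_coef is None
        assert np.allclose(f1.theta_mu, f2.theta_mu)

    def test_icv_driven_data_gets_positive_coefficient(self, rng):
        ages = rng.uniform(18, 90, 1500)
        icv = rng.normal(1450, 110, 1500)
        v = icv * 0.005 + rng.laplace(0, 0.3, 1500)
        f = fit_model(ages, v, build_basis(), covariate=icv)
        assert f.covariate_coef > 0

    def test_icv_independent_coefficient_near_zero(self, rng):
        """Coefficient within 3 bootstrap SEs of 0 for ICV-independent data."""
        ages = rng.uniform(18, 90, 600)
        icv = rng.normal(1450, 110, 600)
        v = rng.laplace(4.0, 0.2, 600)
        basis = build_basis()
        f = fit_model(ages, v, basis, covariate=icv)
        coefs = []
        for _ in range(25):
            idx = rng.integers(0, 600, 600)
            coefs.append(
                fit_model(ages[idx], v[idx], basis, covariate=icv[idx]).covariate_coef
            )
        se = np.std(coefs, ddof=1)
        assert abs(f.covariate_coef) < 3 * se


class TestMatchGroups:
    def make_two_groups(self, rng, n=200):
        a = subjects_frame(rng.normal(1407.8, 107.69, n), 4.0, sid0=0)
        b = subjects_frame(
            rng.normal(1364.1, 108.57, n), 4.0, sid0=n, race="Black"
        )
        return pd.concat([a, b], ignore_index=True)

    def test_identical_groups_fully_matched(self):
        icv = np.linspace(1300, 1500, 30)
        a = subjects_frame(icv, 4.0, sid0=0)
        b = subjects_frame(icv, 4.0, sid0=30, race="Black")
        out = match_groups(pd.concat([a, b], ignore_index=True), AF, BF, caliper=1.0)
        assert len(out.records) == 60
        assert out.matching_report.attrs["standardized_mean_difference"] == pytest.approx(0.0, abs=1e-12)

    def test_tiny_caliper_gives_empty_set_with_warning(self, rng):
        df = self.make_two_groups(rng, n=20)
        with pytest.warns(UserWarning, match="caliper"):
            out = match_groups(df, AF, BF, caliper=1e-12)
        assert len(out.records) == 0

    def test_balance_against_hungarian_oracle(self, rng):
        """Greedy matching on the two printed female ICV laws, caliper 50 mL.

        Post-matching |standardized ICV difference| < 0.1, and the greedy
        pairing is close to the optimal (Hungarian) assignment's cost.
        """
        df = self.make_two_groups(rng, n=200)
        out = match_groups(df, AF, BF, caliper=50.0)
        smd = out.matching_report.attrs["standardized_mean_difference"]
        assert abs(smd) < 0.1
        icv_a = df[df.race == "Asian"][ICV_COLUMN].to_numpy()
        icv_b = df[df.race == "Black"][ICV_COLUMN].to_numpy()
        cost = np.abs(icv_a[:, None] - icv_b[None, :])
        big = 1e9
        cost_cap = np.where(cost <= 50.0, cost, big)
        ri, ci = linear_sum_assignment(cost_cap)
        valid = cost_cap[ri, ci] < big
        optimal_pairs = int(valid.sum())
        # the optimal assignment bounds how many pairs any 1:1 caliper
        # matching can form; greedy must stay in its vicinity
        assert len(out.matching_report) <= optimal_pairs
        assert len(out.matching_report) >= 0.8 * optimal_pairs
        assert (out.matching_report["icv_distance"] <= 50.0).all()

    def test_volumes_unchanged_and_subset(self, rng):
        df = self.make_two_groups(rng, n=50)
        out = match_groups(df, AF, BF, caliper=100.0)
        merged = out.records.merge(df, on="subject_id", suffixes=("", "_orig"))
        assert np.allclose(merged["roi"], merged["roi_orig"])

    def test_empty_group_rejected(self, rng):
        df = subjects_frame(rng.normal(1400, 100, 10), 4.0)
        with pytest.raises(ValueError, match="nonempty"):
            match_groups(df, AF, BF, caliper=10.0)


class TestLogTransform:
    def test_empty_set_is_identity(self, small_subjects):
        out = log_transform(small_subjects, [])
        pd.testing.assert_frame_equal(out, small_subjects)

    def test_unit_volume_maps_to_zero(self):
        df = subjects_frame([1400.0], [1.0])
        assert log_transform(df, ["roi"])["roi"].iloc[0] == 0.0

    def test_exp_round_trip(self, small_subjects):
        logged = log_transform(small_subjects, ["ventricles", "hippocampus"])
        back = invert_log_transform(logged)
        assert np.allclose(back["ventricles"], small_subjects["ventricles"])
        assert np.allclose(back["hippocampus"], small_subjects["hippocampus"])
        assert logged.attrs["log_rois"] == ("hippocampus", "ventricles")

    def test_nonpositive_volume_rejected(self):
        df = subjects_frame([1400.0], [-1.0])
        with pytest.raises(ValueError, match="log-transform"):
            log_transform(df, ["roi"])

    def test_unknown_column_rejected(self):
        df = subjects_frame([1400.0], [1.0])
        with pytest.raises(KeyError):
            log_transform(df, ["nope"])
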