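"""Spline mixed-model growth trajectories and anchor predictions."""

import numpy as np
import pandas as pd
import pytest

from twingrowth.config import ANCHOR_GAS
from twingrowth.trajectory import (
    SplineSpec,
    fit_growth_lmm,
    natural_spline_basis,
    predict_anchor_dataset,
    predict_at_anchor,
)

SPEC = SplineSpec()


def _lstsq_fit(x, y):
    return np.linalg.lstsq(x, y, rcond=None)[0]


class TestNaturalSplineBasis:
    def test_dimension(self):
        b = natural_spline_basis(np.array([15.0, 25.0]), SPEC)
        assert b.shape == (2, len(SPEC.interior_knots) + 1)

    def test_deterministic(self):
        ga = np.linspace(11, 41, 50)
        np.testing.assert_array_equal(
            natural_spline_basis(ga, SPEC), natural_spline_basis(ga, SPEC)
        )

    def test_linear_function_in_span(self):
        """Natural splines span linear functions exactly."""
        ga = np.linspace(11.0, 41.0, 60)
        x = np.column_stack([np.ones(ga.size), natural_spline_basis(ga, SPEC)])
        coef = _lstsq_fit(x, ga)
        anchors = np.asarray(ANCHOR_GAS)
        xa = np.column_stack([np.ones(4), natural_spline_basis(anchors, SPEC)])
        np.testing.assert_allclose(xa @ coef, anchors, atol=1e-8)

    def test_linear_beyond_boundary_knots(self):
        ga = np.linspace(41.0, 42.0, 20)
        b = natural_spline_basis(ga, SPEC)
        # second differences vanish where the spline is linear
        for j in range(b.shape[1]):
            assert np.all(np.abs(np.diff(b[:, j], 2)) < 1e-8)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            natural_spline_basis(np.array([9.0]), SPEC)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SplineSpec(interior_knots=(22.0, 16.0))
        with pytest.raises(ValueError):
            SplineSpec(interior_knots=(10.0, 22.0))


def _model_generated_measurements(rng, n_pairs=30, residual_sd=0.0,
                                  pair_intercept_sd=0.0):
    """Visit data generated exactly from the spline + covariate model."""
    gamma = rng.normal(0, 2.0, len(SPEC.interior_knots) + 1)
    beta_sex = 1.5
    rows, covs = [], []
    for i in range(n_pairs):
        pid = f"P{i:03d}"
        visits = np.array([12.5, 16.0, 20.0, 24.0, 28.0, 32.0, 35.0])
        b0 = rng.normal(0, pair_intercept_sd)
        for fid in (1, 2):
            sex = int(rng.random() < 0.5)
            basis = natural_spline_basis(visits, SPEC)
            y = 150.0 + basis @ gamma + beta_sex * sex + b0
            y = y + rng.normal(0, residual_sd, visits.size)
            for ga, v in zip(visits, y):
                rows.append((pid, fid, "DZ", ga, "AC", v))
            covs.append(dict(pair_id=pid, fetus_id=fid, zygosity="DZ", sex=sex,
                             maternal_age=30.0, pre_pregnancy_bmi=25.0, smoking=0,
                             alcohol=0, race=1, parity=0, gravidity=1, employment=1,
                             education=1, marital=1, delivery_ga=38.0))
    m = pd.DataFrame(rows, columns=["pair_id", "fetus_id", "zygosity", "ga_weeks",
                                    "trait", "value"])
    return m, pd.DataFrame(covs), gamma, beta_sex


class TestFitGrowthLMM:
    def test_noise_free_data_refit_exactly(self, rng):
        m, c, gamma, beta_sex = _model_generated_measurements(rng)
        fit = fit_growth_lmm(m, c, "AC", SPEC)
        assert fit.converged
        assert fit.residual_var < 1e-10
        np.testing.assert_allclose(
            fit.fixed_effects[[f"ns{j + 1}" for j in range(len(gamma))]], gamma, atol=1e-6
        )
        assert fit.fixed_effects["sex"] == pytest.approx(beta_sex, abs=1e-6)

    def test_prediction_interpolates_noiseless_observation(self, rng):
        m, c, *_ = _model_generated_measurements(rng)
        fit = fit_growth_lmm(m, c, "AC", SPEC)
        obs = m[(m.pair_id == "P000") & (m.fetus_id == 1) & (m.ga_weeks == 20.0)]
        pred, extrap = predict_at_anchor(fit, "P000", 1, 20.0)
        assert pred == pytest.approx(float(obs["value"].iloc[0]), abs=1e-8)
        assert not extrap

    def test_pair_intercept_variance_recovery(self, rng):
        m, c, *_ = _model_generated_measurements(
            rng, n_pairs=500, residual_sd=0.1, pair_intercept_sd=0.5
        )
        fit = fit_growth_lmm(m, c, "AC", SPEC)
        assert fit.converged
        assert fit.pair_re_cov[0, 0] == pytest.approx(0.25, rel=0.15)

    def test_row_order_invariance(self, small_cohort):
        _, m, c, _ = small_cohort
        fit1 = fit_growth_lmm(m, c, "FL", SPEC)
        shuffled = m.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_growth_lmm(shuffled, c, "FL", SPEC)
        for key in fit1.pair_blups:
            np.testing.assert_allclose(fit1.pair_blups[key], fit2.pair_blups[key],
                                       atol=1e-8)
        p1, _ = predict_at_anchor(fit1, "P0001", 1, 20.0)
        p2, _ = predict_at_anchor(fit2, "P0001", 1, 20.0)
        assert p1 == pytest.approx(p2, abs=1e-8)

    def test_constant_covariate_dropped(self, rng):
        m, c, *_ = _model_generated_measurements(rng, n_pairs=10)
        c["smoking"] = 0  # constant: no information
        fit = fit_growth_lmm(m, c, "AC", SPEC)
        assert "smoking" in fit.dropped_columns
        assert "smoking" not in fit.covariate_names

    def test_unknown_fetus_raises(self, rng):
        m, c, *_ = _model_generated_measurements(rng, n_pairs=5)
        fit = fit_growth_lmm(m, c, "AC", SPEC)
        with pytest.raises(KeyError):
            predict_at_anchor(fit, "NOPE", 1, 20.0)


class TestAnchorDataset:
    def test_one_row_per_fetus_anchor_trait(self, small_cohort):
        _, m, c, _ = small_cohort
        fit = fit_growth_lmm(m, c, "EFW", SPEC)
        ad = predict_anchor_dataset({"EFW": fit}, ANCHOR_GAS)
        n_fetus = len(fit.fetus_info)
        assert len(ad) == n_fetus * len(ANCHOR_GAS)
        assert not ad.duplicated(["pair_id", "fetus_id", "anchor_ga", "trait"]).any()

    def test_extrapolation_flag_matches_last_visit(self, small_cohort):
        _, m, c, _ = small_cohort
        fit = fit_growth_lmm(m, c, "EFW", SPEC)
        ad = predict_anchor_dataset({"EFW": fit}, ANCHOR_GAS)
        last = m[m.trait == "EFW"].groupby(["pair_id", "fetus_id"])["ga_weeks"].max()
        for _, row in ad.iterrows():
            expected = row["anchor_ga"] > last.loc[(row["pair_id"], row["fetus_id"])]
            assert bool(row["extrapolated"]) == expected

    def test_anchor_predictions_beat_measurement_sd(self, default_cohort):
        """Mid-gestation anchor RMSE against latent truth is below the
        cross-sectional anchor SD (the prediction is informative)."""
        _, m, c, tr = default_cohort
        fit = fit_growth_lmm(m, c, "AC", SPEC)
        ad = predict_anchor_dataset({"AC": fit}, [20.0])
        ad = ad.sort_values(["pair_id", "fetus_id"])
        ti = tr.traits.index("AC")
        truth_vals = tr.anchor_values[:, 1, ti]
        rmse = np.sqrt(np.mean((ad["predicted_value"].to_numpy() - truth_vals) ** 2))
        assert rmse < 7.3  # anchor SD of AC at mid-gestation, mm
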