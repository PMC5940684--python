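"""Synthetic-cohort generator: calibration, twin structure, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twingrowth.cohort import (
    HC_ANCHOR_MEANS,
    assign_visit_schedule,
    hadlock_efw,
    hc_from_hadlock,
    mean_growth_curve,
    simulate_cohort,
)
from twingrowth.config import (
    ANCHOR_GAS,
    ANCHOR_MEANS,
    TRAITS,
    CohortConfig,
    ConfigError,
    ga_from_weeks_days,
)

SCHED_A = (16.0, 20.0, 24.0, 28.0, 32.0, 35.0)
SCHED_B = (18.0, 22.0, 26.0, 30.0, 34.0, 36.0)


class TestMeanGrowthCurve:
    @pytest.mark.parametrize(
        "trait, ga, expected",
        [
            ("AC", 20.0, 150.5),
            ("AC", ga_from_weeks_days(13, 6), 77.0),
            ("FL", ga_from_weeks_days(27, 6), 51.3),
            ("HL", 20.0, 31.0),
            ("EFW", ga_from_weeks_days(38, 6), 3046.8),
        ],
    )
    def test_reproduces_anchor_means(self, trait, ga, expected):
        assert mean_growth_curve(trait, ga) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("trait", [*TRAITS, "HC"])
    def test_strictly_increasing_and_positive(self, trait):
        ga = np.linspace(10.0, 42.0, 400)
        v = mean_growth_curve(trait, ga)
        assert np.all(v > 0)
        assert np.all(np.diff(v) > 0)

    def test_humerus_grows_between_anchors(self):
        assert mean_growth_curve("HL", ga_from_weeks_days(27, 6)) > mean_growth_curve("HL", 20.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mean_growth_curve("AC", 9.0)
        with pytest.raises(ValueError):
            mean_growth_curve("AC", 43.0)
        with pytest.raises(ValueError):
            mean_growth_curve("XYZ", 20.0)


class TestHadlock:
    def test_reference_value(self):
        assert hadlock_efw(175.0, 150.0, 32.0) == pytest.approx(330.7, rel=2e-3)

    def test_small_biometry_limit(self):
        # all inputs -> 0 gives 10^1.326
        assert hadlock_efw(1e-9, 1e-9, 1e-9) == pytest.approx(10**1.326, rel=1e-6)

    def test_monotone_in_ac_over_physiologic_range(self):
        base = hadlock_efw(175.0, 150.0, 32.0)
        assert hadlock_efw(175.0, 160.0, 32.0) > base

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hadlock_efw(-1.0, 150.0, 32.0)

    @settings(max_examples=50, deadline=None)
    @given(
        efw=st.floats(20.0, 5000.0),
        ac=st.floats(40.0, 400.0),
        fl=st.floats(5.0, 90.0),
    )
    def test_hc_inversion_roundtrip(self, efw, ac, fl):
        hc = hc_from_hadlock(efw, ac, fl)
        if hc > 0:
            assert hadlock_efw(hc, ac, fl) == pytest.approx(efw, rel=1e-10)

    def test_hc_anchor_means_close_the_identity(self):
        for k in range(4):
            efw = hadlock_efw(HC_ANCHOR_MEANS[k], ANCHOR_MEANS["AC"][k], ANCHOR_MEANS["FL"][k])
            assert efw == pytest.approx(ANCHOR_MEANS["EFW"][k], rel=1e-10)


class TestVisitSchedule:
    def test_structure(self):
        for seed in range(50):
            visits = assign_visit_schedule(seed)
            assert len(visits) == 7
            assert 11.0 <= visits[0] <= ga_from_weeks_days(13, 6)
            assert tuple(visits[1:]) in (SCHED_A, SCHED_B)

    def test_fair_randomization(self):
        frac_a = np.mean(
            [tuple(assign_visit_schedule(s)[1:]) == SCHED_A for s in range(10_000)]
        )
        assert frac_a == pytest.approx(0.5, abs=0.02)


class TestSimulateCohort:
    def test_default_cohort_shape(self, default_cohort):
        cfg, m, c, tr = default_cohort
        assert m["pair_id"].nunique() == 148
        assert len(c) == 296
        visits = m.groupby(["pair_id", "fetus_id"])["ga_weeks"].nunique()
        assert visits.max() <= 7
        # both fetuses share zygosity and visit schedule
        for pid, g in m.groupby("pair_id"):
            assert g["zygosity"].nunique() == 1
            gas = g.groupby("fetus_id")["ga_weeks"].apply(lambda s: tuple(sorted(s.unique())))
            assert len(set(gas)) == 1
        assert (m["value"] > 0).all()
        key = m[["pair_id", "fetus_id", "ga_weeks", "trait"]]
        assert not key.duplicated().any()

    def test_seeded_determinism(self):
        cfg = CohortConfig(n_mz=3, n_dz=7, seed=99)
        a = simulate_cohort(cfg)
        b = simulate_cohort(CohortConfig(n_mz=3, n_dz=7, seed=99))
        assert a[0].to_csv() == b[0].to_csv()
        assert a[1].to_csv() == b[1].to_csv()

    def test_adding_pairs_preserves_existing(self):
        small = simulate_cohort(CohortConfig(n_mz=3, n_dz=4, seed=42))[0]
        large = simulate_cohort(CohortConfig(n_mz=3, n_dz=24, seed=42))[0]
        shared = large[large["pair_id"].isin(small["pair_id"].unique())]
        pd.testing.assert_frame_equal(
            small.reset_index(drop=True), shared.reset_index(drop=True)
        )

    def test_efw_rows_satisfy_hadlock_identity(self, small_cohort):
        _, m, _, _ = small_cohort
        piv = m.pivot_table(index=["pair_id", "fetus_id", "ga_weeks"], columns="trait",
                            values="value")
        np.testing.assert_allclose(
            hadlock_efw(piv["HC"], piv["AC"], piv["FL"]), piv["EFW"], rtol=1e-12
        )

    def test_pure_genetic_mz_twins_identical(self):
        plan = {t: [(1.0, 0.0, 0.0)] * 4 for t in TRAITS}
        cfg = CohortConfig(
            n_mz=5, n_dz=5, seed=3, variance_plan=plan,
            covariate_effects={}, measurement_cv={t: 0.0 for t in TRAITS},
        )
        m, _, _ = simulate_cohort(cfg)
        mz = m[m["zygosity"] == "MZ"]
        piv = mz.pivot_table(index=["pair_id", "ga_weeks", "trait"], columns="fetus_id",
                             values="value")
        np.testing.assert_allclose(piv[1], piv[2], rtol=1e-10)

    def test_anchor_calibration_within_one_percent(self):
        _, _, tr = simulate_cohort(CohortConfig(n_mz=0, n_dz=4000, seed=21))
        for ti, t in enumerate(TRAITS):
            emp = tr.anchor_values[:, :, ti].mean(axis=0)
            np.testing.assert_allclose(emp, ANCHOR_MEANS[t], rtol=0.01)

    def test_truth_record_twin_structure(self):
        _, _, tr = simulate_cohort(CohortConfig(n_mz=500, n_dz=1500, seed=8))
        a = tr.a_components  # (fetus, anchor, trait)
        zyg = tr.fetus_index["zygosity"].to_numpy()
        a1, a2 = a[::2], a[1::2]
        z = zyg[::2]
        # MZ co-twins share A exactly; DZ co-twins correlate 0.5
        np.testing.assert_allclose(a1[z == "MZ"], a2[z == "MZ"], atol=1e-12)
        dz_corr = np.corrcoef(a1[z == "DZ"].ravel(), a2[z == "DZ"].ravel())[0, 1]
        assert dz_corr == pytest.approx(0.5, abs=0.05)

    def test_cross_trait_genetic_correlation_matches_plan(self):
        cfg = CohortConfig(n_mz=1000, n_dz=1000, seed=12)
        _, _, tr = simulate_cohort(cfg)
        a = tr.a_components
        for k in range(4):
            emp = np.corrcoef(a[:, k, :].T)
            np.testing.assert_allclose(emp, np.asarray(cfg.rho_g_plan[k]), atol=0.05)

    def test_intraclass_correlations_match_plan(self):
        """rMZ = h2 + c2 and rDZ = h2/2 + c2 on latent anchor values."""
        rmz, rdz = [], []
        for seed in range(10):
            cfg = CohortConfig(n_mz=500, n_dz=1500, seed=100 + seed,
                               covariate_effects={})
            _, _, tr = simulate_cohort(cfg)
            ti = tr.traits.index("EFW")
            lv = np.log(tr.anchor_values[:, 2, ti]).reshape(-1, 2)
            zyg = tr.fetus_index["zygosity"].to_numpy()[::2]
            rmz.append(np.corrcoef(lv[zyg == "MZ", 0], lv[zyg == "MZ", 1])[0, 1])
            rdz.append(np.corrcoef(lv[zyg == "DZ", 0], lv[zyg == "DZ", 1])[0, 1])
        # EFW late-second-trimester plan: h2=0.71, c2=0.11
        assert np.mean(rmz) == pytest.approx(0.82, abs=0.04)
        assert np.mean(rdz) == pytest.approx(0.465, abs=0.04)


class TestConfigValidation:
    def test_rejects_non_psd_rho_plan(self):
        bad = np.array([[1.0, 0.9, -0.9, 0.0], [0.9, 1.0, 0.9, 0.0],
                        [-0.9, 0.9, 1.0, 0.0], [0.0, 0.0, 0.0, 1.0]])
        with pytest.raises(ConfigError):
            CohortConfig(rho_g_plan=[bad] * 4)

    def test_rejects_too_few_pairs(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_mz=1, n_dz=0)

    def test_rejects_bad_variance_triple(self):
        plan = {t: [(0.5, 0.4, 0.2)] * 4 for t in TRAITS}  # sums to 1.1
        with pytest.raises(ConfigError):
            CohortConfig(variance_plan=plan)

    def test_yaml_roundtrip(self):
        cfg = CohortConfig(n_mz=4, n_dz=9, seed=77)
        back = CohortConfig.from_yaml(cfg.to_yaml())
        assert back.to_dict() == cfg.to_dict()
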