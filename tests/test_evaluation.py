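import numpy as np
import pytest
from statsmodels.stats.proportion import proportion_confint

from btksim.evaluation import (
    DOSE_GROUP_BOUNDS,
    ObservedDoseRecord,
    RuvModel,
    add_ruv,
    clopper_pearson,
    generate_synthetic_study,
    load_observed_fixture,
    observed_frame,
    pool_dose_groups,
    predicted_vs_observed,
)


class TestObservedFixture:
    def test_totals(self):
        recs = load_observed_fixture()
        assert len(recs) == 21
        assert sum(r.n_obs for r in recs) == 320

    def test_reference_dose_row(self):
        rec = {r.dose_mg: r for r in load_observed_fixture()}[420.0]
        assert rec.n_obs == 119
        assert rec.pct_gt90 == 77.0
        assert rec.responders == 92

    def test_reconstructed_counts_are_valid(self):
        for r in load_observed_fixture():
            assert 0 <= r.responders <= r.n_obs

    def test_overall_response_rate_consistent(self):
        df = observed_frame()
        overall = 100.0 * df["responders"].sum() / df["n_obs"].sum()
        assert overall == pytest.approx(82.0, abs=0.5)


class TestPooling:
    def test_counts_conserved(self):
        pooled = pool_dose_groups()
        assert pooled["n"].sum() == 320
        assert len(pooled) == 5

    def test_lowest_group_composition(self):
        g = pool_dose_groups().iloc[0]
        # 80 mg (n=8) and 120 mg (n=12); responders 4 + 8
        assert g["n"] == 20
        assert g["responders"] == 12
        assert g["pct_gt90"] == pytest.approx(60.0)

    def test_single_record_group_passes_through(self):
        recs = [ObservedDoseRecord(100.0, 10, 70.0)]
        pooled = pool_dose_groups(recs, bounds=((80.0, 140.0),))
        assert pooled["pct_gt90"].iloc[0] == pytest.approx(70.0)

    def test_record_outside_groups_rejected(self):
        with pytest.raises(ValueError):
            pool_dose_groups([ObservedDoseRecord(2000.0, 5, 50.0)])

    def test_boundary_doses_land_in_lower_group(self):
        pooled = pool_dose_groups()
        # 140 would close group 1, 300 closes group 2 (upper-inclusive)
        assert DOSE_GROUP_BOUNDS[1] == (140.0, 300.0)
        assert pooled["n"].tolist() == [20, 30, 130, 82, 58]


class TestClopperPearson:
    def test_zero_successes_has_zero_lower_bound(self):
        lo, hi = clopper_pearson(0, 5)
        assert lo == 0.0
        assert 0 < hi < 1

    def test_full_successes_has_unit_upper_bound(self):
        lo, hi = clopper_pearson(5, 5)
        assert hi == 1.0

    @pytest.mark.parametrize("k,n", [(3, 10), (92, 119), (44, 49)])
    def test_matches_statsmodels_beta_interval(self, k, n):
        lo, hi = clopper_pearson(k, n)
        sm_lo, sm_hi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(sm_lo, abs=1e-10)
        assert hi == pytest.approx(sm_hi, abs=1e-10)


class TestRuv:
    def test_zero_variance_is_identity(self):
        occ = np.array([10.0, 50.0, 95.0])
        assert np.array_equal(add_ruv(occ, RuvModel(0.0), 0), occ)

    def test_noise_is_centered(self):
        occ = np.full(200_000, 50.0)
        noisy = add_ruv(occ, RuvModel(), np.random.default_rng(1))
        assert noisy.mean() == pytest.approx(50.0, abs=0.05)
        assert noisy.std() == pytest.approx(np.sqrt(27.1), rel=0.02)

    def test_clipping_keeps_physical_range(self):
        noisy = add_ruv(np.full(10_000, 99.0), RuvModel(), 2)
        assert noisy.max() <= 100.0 and noisy.min() >= 0.0

    def test_clipping_bias_sign_near_boundary(self):
        """Near 100% the noise can only push values down, so the mean drops;
        in mid-range it stays centered."""
        rng = np.random.default_rng(3)
        hi = add_ruv(np.full(50_000, 99.5), RuvModel(), rng)
        assert hi.mean() < 99.5 - 0.5
        lo = add_ruv(np.full(50_000, 0.5), RuvModel(), rng)
        assert lo.mean() > 0.5

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            RuvModel(-1.0)


class TestSyntheticStudy:
    def test_zero_dose_zero_noise_gives_zero_occupancy(self):
        df = generate_synthetic_study({0.0: 5}, (2, 8), ruv=RuvModel(0.0), seed=0)
        assert np.allclose(df["occupancy_pct"], 0.0, atol=1e-10)

    def test_observed_study_bookkeeping(self):
        """Allocating the observed per-dose sample sizes yields 320 records
        per sampling day."""
        alloc = {r.dose_mg: r.n_obs for r in load_observed_fixture()}
        df = generate_synthetic_study(alloc, (2, 8), seed=1, dt=0.25)
        assert (df["day"] == 8).sum() == 320
        assert (df["day"] == 2).sum() == 320
        assert df["subject_id"].nunique() == 320

    def test_round_trip_consistency_with_trial_engine(self):
        """Proportions measured from generated records agree with the
        generating model's intrinsic proportion within binomial error."""
        from btksim.trials import TrialDesign, run_virtual_trial

        n = 400
        df = generate_synthetic_study({420.0: n}, (8,), ruv=RuvModel(0.0), seed=2)
        prop_study = 100.0 * df["gt90"].mean()
        occ = run_virtual_trial(
            TrialDesign(doses=(420.0,), n_subjects=n, days=7, seed=2)
        )[420.0].occupancies
        prop_trial = 100.0 * np.mean(occ > 90.0)
        # three binomial standard errors at n=400
        se = 100.0 * np.sqrt(0.95 * 0.05 / n)
        assert abs(prop_study - prop_trial) < 3 * se + 1e-9

    def test_sampling_day_validation(self):
        with pytest.raises(ValueError):
            generate_synthetic_study({140.0: 2}, (1,), seed=0)


@pytest.fixture(scope="module")
def sweep():
    from btksim.trials import dose_response_sweep

    doses = [80, 140, 200, 300, 420, 560, 700, 900, 1100, 1400]
    return dose_response_sweep(doses, n_subjects=300, seed=10,
                               ruv_variance=27.1)


class TestPredictedVsObserved:

    def test_comparison_table_shape(self, sweep):
        table = predicted_vs_observed(sweep)
        assert len(table) == 5
        assert {"observed_pct", "pred_median_pct", "covered"} <= set(table.columns)

    def test_exact_match_is_covered(self):
        import pandas as pd

        doses = np.array([r.dose_mg for r in load_observed_fixture()])
        rows = []
        pooled = pool_dose_groups()
        for pct in (5, 50, 95):
            for d in np.unique(doses):
                # flat predictions equal to each group's observed value
                grp = pooled[(pooled["low_mg"] <= d) & (d <= pooled["high_mg"])]
                # boundary doses close the lower group (upper-inclusive rule)
                rows.append({"dose_mg": d, "percentile": pct,
                             "prop_gt90_ruv": grp["pct_gt90"].iloc[0]})
        synthetic = pd.DataFrame(rows)
        table = predicted_vs_observed(synthetic)
        assert table["covered"].all()

    def test_missing_doses_rejected(self, sweep):
        truncated = sweep[sweep["dose_mg"] <= 560]
        with pytest.raises(ValueError):
            predicted_vs_observed(truncated)
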