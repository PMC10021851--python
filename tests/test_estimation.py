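import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmrcal import (
    DegenerateCalibrationError,
    UndefinedRateError,
    ValidationError,
    estimation,
)


class TestRates:
    def test_national_counts_give_published_rate(self):
        assert estimation.compute_mmr(61_169, 61_982_623) == pytest.approx(98.69, abs=0.005)

    def test_reference_sample_counts(self):
        assert estimation.compute_mmr(525, 429_173) == pytest.approx(122.33, abs=0.005)

    def test_zero_numerator_is_zero_not_undefined(self):
        assert estimation.compute_mmr(0, 1000) == 0.0
        assert estimation.compute_imr(0, 500) == 0.0

    def test_imr_definitional(self):
        assert estimation.compute_imr(32, 1000) == 32.0

    def test_zero_births_is_undefined_rate(self):
        with pytest.raises(UndefinedRateError):
            estimation.compute_mmr(0, 0)

    def test_deaths_exceeding_births_rejected(self):
        with pytest.raises(ValidationError):
            estimation.compute_mmr(11, 10)


def _districts(rows):
    base = {
        "infant_deaths": 0,
        "female_pop_15_49": 10_000,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestStateRate:
    def test_pooled_counts_not_mean_of_rates(self):
        d = _districts(
            [
                {"district_id": "a", "state_id": "s", "maternal_deaths": 10, "live_births": 10_000},
                {"district_id": "b", "state_id": "s", "maternal_deaths": 30, "live_births": 10_000},
            ]
        )
        assert estimation.state_hmis_rate(d, "mmr").loc["s"] == pytest.approx(200.0)

    def test_pooled_differs_from_unweighted_mean_with_unequal_denominators(self):
        d = _districts(
            [
                {"district_id": "a", "state_id": "s", "maternal_deaths": 10, "live_births": 1_000},
                {"district_id": "b", "state_id": "s", "maternal_deaths": 10, "live_births": 100_000},
            ]
        )
        pooled = estimation.state_hmis_rate(d, "mmr").loc["s"]
        unweighted = np.mean([10 / 1_000 * 1e5, 10 / 100_000 * 1e5])
        assert pooled == pytest.approx(20 / 101_000 * 1e5)
        assert pooled != pytest.approx(unweighted)

    def test_single_district_state_equals_its_rate(self):
        d = _districts(
            [{"district_id": "a", "state_id": "s", "maternal_deaths": 7, "live_births": 3_500}]
        )
        assert estimation.state_hmis_rate(d, "mmr").loc["s"] == pytest.approx(200.0)

    def test_zero_birth_state_errors_with_state_name(self):
        d = _districts(
            [{"district_id": "a", "state_id": "empty", "maternal_deaths": 0, "live_births": 0}]
        )
        with pytest.raises(UndefinedRateError, match="empty"):
            estimation.state_hmis_rate(d, "mmr")


class TestCalibrationFactor:
    def test_identity_when_reference_equals_facility_rate(self):
        cf = estimation.calibration_factor("s", 150.0, None, 150.0, 25.0)
        assert cf.cf == pytest.approx(1.0)
        assert cf.source == "mmr_based"

    def test_imr_proxy_path_when_reference_mmr_missing(self):
        cf = estimation.calibration_factor("s", None, 32.0, 120.0, 26.2)
        assert cf.cf == pytest.approx(1.221, abs=5e-4)
        assert cf.source == "imr_proxy"

    def test_reference_mmr_wins_over_proxy(self):
        cf = estimation.calibration_factor("s", 130.0, 32.0, 98.69, 26.2)
        assert cf.cf == pytest.approx(1.317, abs=5e-4)
        assert cf.source == "mmr_based"

    def test_both_references_missing_errors(self):
        with pytest.raises(ValidationError):
            estimation.calibration_factor("s", np.nan, np.nan, 100.0, 25.0)

    def test_degenerate_facility_rate_errors_by_default(self):
        with pytest.raises(DegenerateCalibrationError):
            estimation.calibration_factor("s", 130.0, 32.0, 0.0, 26.2)

    def test_degenerate_facility_rate_falls_back_when_allowed(self):
        cf = estimation.calibration_factor(
            "s", 130.0, 32.0, 0.0, 26.2, allow_imr_fallback_on_degenerate=True
        )
        assert cf.source == "imr_proxy"


class TestAdjustAndAggregate:
    def test_adjustment_is_elementwise_multiplication(self):
        d = _districts(
            [{"district_id": "a", "state_id": "s", "maternal_deaths": 20, "live_births": 10_000}]
        )
        cf = pd.DataFrame({"cf": [1.3]}, index=pd.Index(["s"], name="state_id"))
        out = estimation.adjust_districts(d, cf)
        assert out["mmr_unadjusted"].iloc[0] == pytest.approx(200.0)
        assert out["mmr_adjusted"].iloc[0] == pytest.approx(260.0)

    def test_unit_cf_is_identity(self):
        d = _districts(
            [
                {"district_id": "a", "state_id": "s", "maternal_deaths": 5, "live_births": 9_000},
                {"district_id": "b", "state_id": "s", "maternal_deaths": 0, "live_births": 4_000},
            ]
        )
        cf = pd.DataFrame({"cf": [1.0]}, index=pd.Index(["s"], name="state_id"))
        out = estimation.adjust_districts(d, cf)
        np.testing.assert_allclose(out["mmr_adjusted"], out["mmr_unadjusted"])
        assert out["mmr_adjusted"].iloc[1] == 0.0

    def test_missing_state_cf_errors(self):
        d = _districts(
            [{"district_id": "a", "state_id": "s2", "maternal_deaths": 1, "live_births": 100}]
        )
        cf = pd.DataFrame({"cf": [1.0]}, index=pd.Index(["s1"], name="state_id"))
        with pytest.raises(ValidationError, match="s2"):
            estimation.adjust_districts(d, cf)

    def test_population_weights_are_state_shares(self):
        d = _districts(
            [
                {"district_id": "a", "state_id": "s", "maternal_deaths": 0,
                 "live_births": 100, "female_pop_15_49": 30_000},
                {"district_id": "b", "state_id": "s", "maternal_deaths": 0,
                 "live_births": 100, "female_pop_15_49": 70_000},
                {"district_id": "c", "state_id": "t", "maternal_deaths": 0,
                 "live_births": 100, "female_pop_15_49": 123},
            ]
        )
        pw = estimation.population_weights(d)
        assert pw.loc["a"] == pytest.approx(0.3)
        assert pw.loc["b"] == pytest.approx(0.7)
        assert pw.loc["c"] == pytest.approx(1.0)

    def test_weighted_state_aggregation(self):
        adjusted = pd.DataFrame(
            {
                "district_id": ["a", "b"],
                "state_id": ["s", "s"],
                "mmr_adjusted": [100.0, 300.0],
            }
        )
        even = pd.Series([0.5, 0.5], index=["a", "b"])
        skew = pd.Series([0.25, 0.75], index=["a", "b"])
        assert estimation.aggregate_states(adjusted, even).loc["s"] == pytest.approx(200.0)
        assert estimation.aggregate_states(adjusted, skew).loc["s"] == pytest.approx(250.0)
        # invariant to district ordering
        flipped = adjusted.iloc[::-1].reset_index(drop=True)
        assert estimation.aggregate_states(flipped, skew).loc["s"] == pytest.approx(250.0)

    def test_constant_districts_aggregate_to_same_value(self):
        adjusted = pd.DataFrame(
            {"district_id": list("abc"), "state_id": ["s"] * 3, "mmr_adjusted": [140.0] * 3}
        )
        w = pd.Series([0.2, 0.3, 0.5], index=list("abc"))
        assert estimation.aggregate_states(adjusted, w).loc["s"] == pytest.approx(140.0)


class TestClassification:
    @pytest.mark.parametrize(
        "mmr, label",
        [
            (0.0, "below_70"),
            (69.99, "below_70"),
            (70.0, "70_139"),
            (139.999, "70_139"),
            (140.0, "140_209"),
            (209.999, "140_209"),
            (210.0, "ge_210"),
            (1671.0, "ge_210"),
        ],
    )
    def test_half_open_bins(self, mmr, label):
        assert estimation.classify_sdg(mmr) == label

    def test_negative_and_nan_rejected(self):
        with pytest.raises(ValidationError):
            estimation.classify_sdg(-1.0)
        with pytest.raises(ValidationError):
            estimation.classify_sdg(float("nan"))

    @given(st.lists(st.floats(min_value=0, max_value=5000, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_categories_partition_defined_values(self, values):
        cats = estimation.classify_sdg_series(pd.Series(values))
        assert cats.notna().sum() == len(values)
        assert set(cats) <= set(estimation.SDG_LABELS)


class TestCompleteness:
    def test_published_worked_number(self):
        pct = estimation.completeness(62_000_000, 81_000_000)
        assert pct == pytest.approx(76.54, abs=0.01)
        assert round(pct) == 77

    def test_full_and_empty_registration(self):
        assert estimation.completeness(5, 5) == 100.0
        assert estimation.completeness(0, 5) == 0.0

    def test_zero_estimate_rejected(self):
        with pytest.raises(ValidationError):
            estimation.completeness(10, 0)


class TestEndToEnd:
    def test_unit_cf_pipeline_is_identity_on_district_mmr(self, small_system):
        """Setting the reference to the facility-system state rate gives cf=1."""
        _, districts, _, _, _ = small_system
        hmis_mmr = estimation.state_hmis_rate(districts, "mmr")
        states = pd.DataFrame(
            {"state_id": hmis_mmr.index, "ref_mmr": hmis_mmr.to_numpy(), "ref_imr": np.nan}
        )
        adjusted, adjusted_states, _ = estimation.estimate(districts, states)
        np.testing.assert_allclose(adjusted["mmr_adjusted"], adjusted["mmr_unadjusted"])
        np.testing.assert_allclose(adjusted_states["cf"], 1.0)

    def test_population_weights_sum_to_one_within_states(self, small_system):
        _, districts, _, _, _ = small_system
        pw = estimation.population_weights(districts)
        sums = pw.groupby(districts.set_index("district_id")["state_id"]).sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_zero_birth_district_flagged_and_excluded(self, small_system):
        _, districts, states, _, _ = small_system
        districts = districts.copy()
        districts.loc[districts.index[0], ["live_births", "maternal_deaths", "infant_deaths"]] = 0
        adjusted, _, drops = estimation.estimate(districts, states)
        assert np.isnan(adjusted["mmr_adjusted"].iloc[0])
        assert pd.isna(adjusted["sdg_category"].iloc[0])
        assert drops[0]["district_id"] == adjusted["district_id"].iloc[0]

    def test_calibration_recovers_truth_under_underreporting(self):
        """Adjusted district MMR tracks truth when the reference is exact."""
        from mmrcal import synthetic

        cfg = synthetic.SyntheticConfig(
            n_states=4, districts_per_state=5, lattice_rows=4, lattice_cols=5,
            births_per_district_range=(2_000_000, 2_000_000),
            reporting_fraction_range=(0.5, 1.0),
            missing_reference_fraction=0.0,
            seed=21,
        )
        districts, states, _, truth = synthetic.generate_system(cfg)
        adjusted, _, _ = estimation.estimate(districts, states)
        est = adjusted.set_index("district_id")["mmr_adjusted"]
        rel = np.abs(est - truth.district_true_mmr) / truth.district_true_mmr
        assert rel.mean() < 0.03
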