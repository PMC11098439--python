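"""The NNT benefit chain: gains -> lives saved -> events averted -> aggregates."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qualimpact._util import round_half_up
from qualimpact.benchmarks import PERCENTILES, BenchmarkTable, PercentileBin, make_bins
from qualimpact.errors import ValidationError
from qualimpact.impact import (
    BenefitModel,
    ImpactResult,
    Scenario,
    aggregate_national,
    compute_impact,
    events_averted,
    lives_saved,
    nnt_from_deaths_per_1000,
    numerator_gain,
    percent_annual_death_reduction,
)

CRC_MODEL = BenefitModel("crc_screening", nnt_death=37, annualization="lifetime", lifetime_years=22)
BP_MODEL = BenefitModel(
    "bp_control", nnt_death=101, annualization="trial", trial_followup_years=4, nnt_event=80.72
)


def _result(measure="m", segment="s", scenario="p66", gain=0.0, lives=0.0, events=None):
    return ImpactResult(measure, segment, scenario, gain, lives, lives / 10.0, events)


class TestNumeratorGain:
    def test_all_bins_at_target_gain_zero(self, medicare_crc):
        bins = make_bins(medicare_crc)
        assert numerator_gain(bins, 60.0, 5e6) == 0.0

    def test_ca_marketplace_bp_gain(self, ca_bp):
        """Bins at {57,65,...} vs the 66 benchmark: 2.5 pp of the denominator."""
        bins = make_bins(ca_bp)
        assert numerator_gain(bins, 66.0, 555_200) == pytest.approx(13_880)

    def test_two_bin_hand_computation(self):
        bins = [
            PercentileBin(0, 50, assumed_score=40, population_weight=0.5),
            PercentileBin(50, 100, assumed_score=60, population_weight=0.5),
        ]
        assert numerator_gain(bins, 60.0, 1000) == pytest.approx(100.0)


class TestNNT:
    @pytest.mark.parametrize("deaths, expected", [(27, 37), (1000, 1), (2, 500)])
    def test_reported_nnt(self, deaths, expected):
        assert round_half_up(nnt_from_deaths_per_1000(deaths)) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            nnt_from_deaths_per_1000(0)

    @given(st.floats(0.1, 1000, allow_nan=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_exact_inverse_of_deaths_per_1000(self, d):
        assert 1000.0 / nnt_from_deaths_per_1000(d) == pytest.approx(d, rel=1e-12)


class TestLivesSaved:
    def test_lifetime_annualization_ca_screening(self):
        """20,865 extra screened / NNT 37, spread over 22 remaining years x 10."""
        assert lives_saved(20_865, CRC_MODEL, 10) == pytest.approx(257, rel=0.01)

    def test_zero_gain(self):
        assert lives_saved(0, CRC_MODEL, 10) == 0.0

    def test_trial_annualization_medicare_bp(self):
        assert lives_saved(1_168_105, BP_MODEL, 10) == pytest.approx(28_913.5, rel=1e-4)

    def test_annualization_modes_are_not_interchangeable(self):
        gain = 1e6
        lifetime = lives_saved(gain, CRC_MODEL, 10)
        as_trial = BenefitModel("crc_screening", 37, "trial", trial_followup_years=22)
        assert lives_saved(gain, as_trial, 10) == pytest.approx(lifetime)
        # same constants under the wrong period give a very different answer
        wrong = BenefitModel("crc_screening", 37, "trial", trial_followup_years=4)
        assert lives_saved(gain, wrong, 10) > 5 * lifetime


class TestEventsAverted:
    def test_calibrated_national_mace(self):
        from qualimpact import refdata

        model = refdata.benefit_models()["bp_control"]
        assert events_averted(4_428_717, model, 10) == pytest.approx(137_164, rel=1e-6)

    def test_zero_gain(self):
        assert events_averted(0, BP_MODEL, 10) == 0.0

    def test_absent_without_event_nnt(self):
        assert events_averted(1e6, CRC_MODEL, 10) is None


class TestAggregation:
    def test_published_screening_national_total(self):
        parts = [
            _result(segment="Medicare", lives=15_127),
            _result(segment="Marketplace", lives=2_680),
            _result(segment="Commercial", lives=15_695),
            _result(segment="CA-Marketplace", lives=257),  # excluded from national
        ]
        agg = aggregate_national(parts)
        assert agg.lives_saved_per_horizon == pytest.approx(33_502)
        assert agg.segment == "National"

    def test_single_segment_identity(self):
        only = _result(segment="Medicare", gain=5.0, lives=1.0)
        agg = aggregate_national([only])
        assert agg.lives_saved_per_horizon == only.lives_saved_per_horizon

    def test_bp_p90_segment_sum_exceeds_published_total(self):
        """The published segment values sum to 284,160, not the published 280,487."""
        parts = [
            _result(segment=s, lives=v)
            for s, v in [
                ("Medicare", 80_080),
                ("Medicaid", 51_760),
                ("Marketplace", 12_260),
                ("Commercial", 140_060),
            ]
        ]
        assert aggregate_national(parts).lives_saved_per_horizon == pytest.approx(284_160)

    def test_mixed_measures_rejected(self):
        with pytest.raises(ValidationError, match="mixed"):
            aggregate_national(
                [_result(measure="a", segment="Medicare"), _result(measure="b", segment="Medicaid")]
            )


class TestPercentReduction:
    @pytest.mark.parametrize(
        "lives, deaths, expected, tol",
        [
            (110_067, 691_095, 1.6, 0.05),
            (280_487, 691_095, 4.1, 0.1),
            (0, 691_095, 0.0, 1e-12),
        ],
    )
    def test_examples(self, lives, deaths, expected, tol):
        assert percent_annual_death_reduction(lives, 10, deaths) == pytest.approx(expected, abs=tol)

    def test_zero_deaths_rejected(self):
        with pytest.raises(ValidationError):
            percent_annual_death_reduction(100, 10, 0)


class TestScenarioChain:
    def test_p90_dominates_p66_for_all_published_tables(self, all_tables):
        model = {"crc_screening": CRC_MODEL, "bp_control": BP_MODEL}
        for table in all_tables:
            lo = compute_impact(table, 1e6, model[table.measure_id], Scenario("p66"))
            hi = compute_impact(table, 1e6, model[table.measure_id], Scenario("p90"))
            assert hi.lives_saved_per_horizon >= lo.lives_saved_per_horizon
            assert hi.numerator_gain >= lo.numerator_gain

    @given(
        denom=st.floats(0, 1e8, allow_nan=False),
        k=st.floats(0.01, 100, allow_nan=False),
        horizon=st.floats(1, 50, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linear_in_denominator_and_horizon(self, denom, k, horizon):
        table = BenchmarkTable("bp_control", "s", dict(zip(PERCENTILES, [50, 55, 60, 65, 70])))
        base = compute_impact(table, denom, BP_MODEL, Scenario("p90", horizon_years=horizon))
        scaled = compute_impact(table, k * denom, BP_MODEL, Scenario("p90", horizon_years=horizon))
        assert scaled.numerator_gain == pytest.approx(k * base.numerator_gain, rel=1e-9, abs=1e-9)
        assert scaled.lives_saved_per_horizon == pytest.approx(
            k * base.lives_saved_per_horizon, rel=1e-9, abs=1e-9
        )
        longer = compute_impact(table, denom, BP_MODEL, Scenario("p90", horizon_years=2 * horizon))
        assert longer.lives_saved_per_horizon == pytest.approx(
            2 * base.lives_saved_per_horizon, rel=1e-9, abs=1e-9
        )
        assert base.annual_lives_saved == pytest.approx(
            base.lives_saved_per_horizon / horizon, rel=1e-9, abs=1e-12
        )

    def test_next_decile_needs_plan_data(self, ca_bp):
        with pytest.raises(ValidationError, match="plan-level"):
            compute_impact(ca_bp, 1e6, BP_MODEL, Scenario("next_decile"))
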