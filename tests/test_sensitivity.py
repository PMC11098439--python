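"""Next-decile targets, plan-level gains and market-share sensitivity."""

import pytest

from qualimpact.benchmarks import make_bins
from qualimpact.errors import ValidationError
from qualimpact.impact import BenefitModel, Scenario, numerator_gain
from qualimpact.sensitivity import (
    PlanRecord,
    assign_deciles,
    conservative_binned_gain,
    load_plan_roster,
    next_decile_targets,
    plan_level_numerator_gain,
    relative_change,
    sensitivity_analysis,
)

BP_MODEL = BenefitModel("bp_control", 101, "trial", trial_followup_years=4)


def _roster(scores, enrollments=None, segment="CA-Marketplace"):
    enrollments = enrollments or [1000] * len(scores)
    return [
        PlanRecord(f"plan-{i}", segment, e, s)
        for i, (s, e) in enumerate(zip(scores, enrollments))
    ]


class TestDeciles:
    def test_ten_plans_next_decile_capped_at_benchmark(self):
        plans = _roster([10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        targets = next_decile_targets(plans, benchmark_p66=66)
        # score-60 plan's next decile boundary is 70, capped at the benchmark
        assert targets["plan-5"] == 66
        assert targets["plan-4"] == 60  # score 50 -> decile-6 boundary
        assert targets["plan-0"] == 20

    def test_plans_at_or_above_benchmark_unchanged(self):
        plans = _roster([70, 50])
        targets = next_decile_targets(plans, benchmark_p66=66)
        assert targets["plan-0"] == 70

    def test_targets_bounded_by_score_and_benchmark(self):
        plans = _roster([12, 34, 47, 55, 58, 63, 65, 68, 72, 91, 44, 52])
        targets = next_decile_targets(plans, benchmark_p66=66)
        for p in plans:
            assert targets[p.plan_id] >= p.score
            if p.score < 66:
                assert targets[p.plan_id] <= 66

    def test_empty_roster_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            next_decile_targets([], 66)

    def test_member_weighted_deciles_follow_enrollment(self):
        # one dominant plan occupies most member-deciles on its own
        plans = _roster([10, 20, 30], enrollments=[8000, 1000, 1000])
        deciles = {p.plan_id: p.decile for p in assign_deciles(plans, basis="members")}
        assert deciles["plan-0"] < deciles["plan-1"] < deciles["plan-2"]
        assert deciles["plan-2"] == 10


class TestPlanLevelGain:
    def test_no_improvement_no_gain(self):
        plans = _roster([40, 60])
        targets = {p.plan_id: p.score for p in plans}
        assert plan_level_numerator_gain(plans, targets, 1000) == 0.0

    def test_even_split_hand_computation(self):
        plans = _roster([50, 70])
        targets = {"plan-0": 60, "plan-1": 70}
        assert plan_level_numerator_gain(plans, targets, 1000, "even") == pytest.approx(50.0)

    def test_target_below_score_rejected(self):
        plans = _roster([50])
        with pytest.raises(ValidationError, match="below"):
            plan_level_numerator_gain(plans, {"plan-0": 40}, 1000)

    def test_concentration_in_worst_plan_raises_enrollment_weighted_gain(self):
        """With 33% of members in the lowest performer, actual-share gains
        exceed even-share gains because that plan's gap exceeds the average."""
        plans = _roster([50, 60, 62, 64], enrollments=[3300, 2300, 2200, 2200])
        targets = {p.plan_id: 66.0 for p in plans}
        even = plan_level_numerator_gain(plans, targets, 1e6, "even")
        weighted = plan_level_numerator_gain(plans, targets, 1e6, "by_enrollment")
        assert weighted > even


class TestConservativeness:
    def test_binned_equals_plan_level_at_assumed_scores(self, ca_bp):
        """Plans placed exactly at bin assumed scores with matching shares
        reproduce the binned engine's gain (cross-module oracle)."""
        bins = make_bins(ca_bp, "percentile_width")
        denominator = 555_200
        plans = [
            PlanRecord(f"p{i}", "CA-Marketplace", 1000, b.assumed_score)
            for i, b in enumerate(bins)
        ]
        targets = {p.plan_id: max(p.score, ca_bp.scores[66]) for p in plans}
        binned = numerator_gain(bins, ca_bp.scores[66], denominator)
        # shares equal to bin weights: sum each plan's contribution directly
        plan_gain = sum(
            b.population_weight
            * denominator
            * (targets[p.plan_id] - p.score)
            / 100.0
            for p, b in zip(plans, bins)
        )
        assert binned == pytest.approx(plan_gain, abs=1e-9)

    def test_snapped_gain_never_exceeds_exact(self, ca_bp):
        plans = _roster([31.5, 58.2, 60.0, 65.9, 66.0, 70.3, 95.0])
        target = ca_bp.scores[66]
        targets = {p.plan_id: max(p.score, float(target)) for p in plans}
        for rule in ("even", "by_enrollment"):
            exact = plan_level_numerator_gain(plans, targets, 1e6, rule)
            snapped = conservative_binned_gain(plans, ca_bp, target, 1e6, rule)
            assert snapped <= exact + 1e-9


class TestRelativeChange:
    @pytest.mark.parametrize(
        "baseline, variant, expected", [(100, 118, 18), (100, 100, 0), (200, 194, -3)]
    )
    def test_examples(self, baseline, variant, expected):
        assert relative_change(baseline, variant) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            relative_change(0, 10)


def test_sensitivity_analysis_reports_both_variants(ca_bp):
    plans = _roster([50, 58, 62, 64, 67, 70], enrollments=[3300, 1600, 1500, 1300, 1200, 1100])
    reports = sensitivity_analysis(plans, ca_bp, 555_200, BP_MODEL, Scenario("p66"))
    labels = {r.label for r in reports}
    assert labels == {"next_decile_even_share", "next_decile_actual_share"}
    for r in reports:
        assert r.baseline_lives > 0
        assert r.relative_change_pct == pytest.approx(
            100 * (r.variant_lives - r.baseline_lives) / r.baseline_lives
        )


def test_roster_csv_round_trip(tmp_path):
    path = tmp_path / "roster.csv"
    path.write_text(
        "plan_id,segment,enrollment,score\nA,CA-Marketplace,5000,55\nB,CA-Marketplace,2000,68\n"
    )
    plans = load_plan_roster(path)
    assert [p.plan_id for p in plans] == ["A", "B"]
    assert plans[0].enrollment == 5000
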