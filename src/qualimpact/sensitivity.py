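"""Plan-level sensitivity analyses: next-decile improvement and actual market share.

The binned engine assumes market share is evenly spread across performance
percentiles and that every below-benchmark plan jumps to the benchmark.  When
a plan-level roster (id, enrollment, score) is available, both assumptions can
be relaxed: plans may improve only to the next performance decile, and the
segment denominator can be split in proportion to actual enrollment.  Reports
express the variant as a signed percent change in lives saved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .benchmarks import BenchmarkTable
from .errors import ValidationError
from .impact import BenefitModel, Scenario, compute_impact, lives_saved

DECILE_BASES = ("plans", "members")
SHARE_RULES = ("even", "by_enrollment")


@dataclass(frozen=True)
class PlanRecord:
    """One health plan: segment, enrollment and measure score."""

    plan_id: str
    segment: str
    enrollment: float
    score: float
    decile: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.enrollment > 0:
            raise ValidationError(f"plan {self.plan_id!r}: enrollment must be positive")
        if not 0.0 <= self.score <= 100.0:
            raise ValidationError(f"plan {self.plan_id!r}: score must lie in [0, 100]")
        if self.decile is not None and not 1 <= self.decile <= 10:
            raise ValidationError("decile must lie in 1..10")


@dataclass(frozen=True)
class SensitivityReport:
    """Lives saved under a variant assumption, relative to the baseline model."""

    label: str
    baseline_lives: float
    variant_lives: float
    relative_change_pct: float


def assign_deciles(plans: Sequence[PlanRecord], basis: str = "plans") -> list[PlanRecord]:
    """Attach performance deciles 1..10 to a roster.

    ``basis="plans"`` ranks plans (enrollment-unweighted): the i-th of n
    plans by score lands in decile ceil(10*i/n).  ``basis="members"`` ranks
    member-weighted: a plan's decile is set by the cumulative enrollment share
    up to and including it.  Score ties break by plan_id for determinism.
    """
    if basis not in DECILE_BASES:
        raise ValidationError(f"unknown decile basis {basis!r}")
    if not plans:
        raise ValidationError("empty plan roster")
    ordered = sorted(plans, key=lambda p: (p.score, p.plan_id))
    out = []
    if basis == "plans":
        n = len(ordered)
        for i, p in enumerate(ordered, start=1):
            d = -(-10 * i // n)  # ceil
            out.append(PlanRecord(p.plan_id, p.segment, p.enrollment, p.score, decile=min(d, 10)))
    else:
        total = sum(p.enrollment for p in ordered)
        cum = 0.0
        for p in ordered:
            cum += p.enrollment
            # decile of the plan's enrollment midpoint along the member axis
            d = max(1, min(10, int((cum - p.enrollment / 2) / total * 10) + 1))
            out.append(PlanRecord(p.plan_id, p.segment, p.enrollment, p.score, decile=d))
    return out


def decile_boundaries(plans: Sequence[PlanRecord]) -> dict[int, float]:
    """Upper score boundary of each non-empty decile (max score in decile)."""
    bounds: dict[int, float] = {}
    for p in plans:
        if p.decile is None:
            raise ValidationError("plans must carry deciles; call assign_deciles first")
        bounds[p.decile] = max(bounds.get(p.decile, 0.0), p.score)
    return bounds


def next_decile_targets(
    plans: Sequence[PlanRecord],
    benchmark_p66: float,
    basis: str = "plans",
) -> dict[str, float]:
    """Target score per plan when below-benchmark plans climb one decile.

    A plan below the 66th-percentile benchmark targets the upper score
    boundary of the next non-empty decile above its own, capped at the
    benchmark; plans at or above the benchmark keep their score.  Targets
    never fall below a plan's own score.
    """
    if not plans:
        raise ValidationError("empty plan roster")
    with_deciles = assign_deciles(plans, basis=basis)
    bounds = decile_boundaries(with_deciles)
    targets: dict[str, float] = {}
    for p in with_deciles:
        if p.score >= benchmark_p66:
            targets[p.plan_id] = p.score
            continue
        nxt = next((bounds[d] for d in range(p.decile + 1, 11) if d in bounds), p.score)
        targets[p.plan_id] = max(p.score, min(nxt, benchmark_p66))
    return targets


def plan_level_numerator_gain(
    plans: Sequence[PlanRecord],
    targets: Mapping[str, float],
    denominator: float,
    share_rule: str = "even",
) -> float:
    """Exact plan-by-plan numerator gain for a target assignment.

    The segment denominator is split across plans evenly (``"even"``, the
    default market-share assumption) or in proportion to enrollment
    (``"by_enrollment"``, the actual-market-share variant); each plan then
    contributes its share times its percentage-point gap to target.
    """
    if share_rule not in SHARE_RULES:
        raise ValidationError(f"unknown share rule {share_rule!r}")
    if not plans:
        raise ValidationError("empty plan roster")
    total_enrollment = sum(p.enrollment for p in plans)
    gain = 0.0
    for p in plans:
        t = targets[p.plan_id]
        if t < p.score:
            raise ValidationError(
                f"plan {p.plan_id!r}: target {t} below current score {p.score}"
            )
        denom_i = (
            denominator / len(plans)
            if share_rule == "even"
            else denominator * p.enrollment / total_enrollment
        )
        gain += denom_i * (t - p.score) / 100.0
    return gain


def conservative_binned_gain(
    plans: Sequence[PlanRecord],
    table: BenchmarkTable,
    target_score: float,
    denominator: float,
    share_rule: str = "even",
) -> float:
    """Numerator gain after snapping each plan up to its bin's assumed score.

    This is the binned engine's conservative rule applied plan-by-plan: every
    score is replaced by the next highest published percentile score before
    the gap is taken, so the result never exceeds the exact plan-level gain.
    """
    snapped = {
        p.plan_id: max(0.0, target_score - table.conservative_score(p.score))
        for p in plans
    }
    total_enrollment = sum(p.enrollment for p in plans)
    gain = 0.0
    for p in plans:
        denom_i = (
            denominator / len(plans)
            if share_rule == "even"
            else denominator * p.enrollment / total_enrollment
        )
        gain += denom_i * snapped[p.plan_id] / 100.0
    return gain


def relative_change(baseline: float, variant: float) -> float:
    """Signed percent change of ``variant`` relative to ``baseline``."""
    if baseline <= 0:
        raise ValidationError("baseline must be positive")
    return 100.0 * (variant - baseline) / baseline


def sensitivity_analysis(
    plans: Sequence[PlanRecord],
    table: BenchmarkTable,
    denominator: float,
    model: BenefitModel,
    scenario: Scenario,
    decile_basis: str = "plans",
) -> list[SensitivityReport]:
    """Compare the binned p66 baseline with next-decile / actual-share variants.

    Returns one report per variant: next-decile improvement with even shares,
    and next-decile improvement with enrollment-proportional shares.
    """
    base_scenario = Scenario("p66", scenario.weight_rule, scenario.horizon_years)
    baseline = compute_impact(table, denominator, model, base_scenario)
    targets = next_decile_targets(plans, table.target_score("p66"), basis=decile_basis)
    reports = []
    for share_rule, label in (
        ("even", "next_decile_even_share"),
        ("by_enrollment", "next_decile_actual_share"),
    ):
        gain = plan_level_numerator_gain(plans, targets, denominator, share_rule)
        variant_lives = lives_saved(gain, model, scenario.horizon_years)
        reports.append(
            SensitivityReport(
                label=label,
                baseline_lives=baseline.lives_saved_per_horizon,
                variant_lives=variant_lives,
                relative_change_pct=relative_change(
                    baseline.lives_saved_per_horizon, variant_lives
                ),
            )
        )
    return reports


PLAN_CSV_COLUMNS = ["plan_id", "segment", "enrollment", "score"]


def load_plan_roster(source: Union[str, Path, pd.DataFrame]) -> list[PlanRecord]:
    """Read a ``plan_id,segment,enrollment,score`` roster CSV."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in PLAN_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"plan roster missing columns {missing}")
    return [
        PlanRecord(str(r.plan_id), str(r.segment), float(r.enrollment), float(r.score))
        for r in df.itertuples()
    ]
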