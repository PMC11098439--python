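"""Benchmark-improvement scenarios -> numerator gains -> lives saved and events averted.

The benefit chain is number-needed-to-treat (NNT) arithmetic.  A scenario
moves plans below a percentile benchmark up to that benchmark; the resulting
extra members meeting the measure numerator (screened, or with controlled
blood pressure) are divided by the NNT to avert one death, then spread over
the scenario horizon with one of two annualization schemes:

* ``"lifetime"`` — the NNT expresses a lifetime benefit (colonoscopy
  screening: 27 deaths averted per 1000 screened over remaining lifetimes,
  NNT 37), converted to an annual rate via average remaining life expectancy
  (22 years after screening starts at age 50).
* ``"trial"`` — the NNT expresses a benefit over a trial's follow-up
  (antihypertensive therapy: NNT 101 over a 4-year median follow-up),
  converted via the follow-up duration.

Conflating the two schemes is the main implementation hazard; they are
explicit modes, never inferred from the numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .benchmarks import BenchmarkTable, PercentileBin, improvement_gap, make_bins
from .errors import ValidationError

SCENARIO_TARGETS = ("p66", "p90", "next_decile")

#: Segments summed into national totals.  The California Marketplace is a
#: state carve-out reported separately and never added to national figures.
NATIONAL_SEGMENTS: tuple[str, ...] = ("Medicare", "Medicaid", "Marketplace", "Commercial")


@dataclass(frozen=True)
class Scenario:
    """A benchmark-improvement scenario.

    ``target`` is ``"p66"`` or ``"p90"`` for the binned engine, or
    ``"next_decile"`` for the plan-level sensitivity path.  ``horizon_years``
    is the period over which improved performance is sustained (default one
    decade, matching the headline reporting).
    """

    target: str = "p66"
    weight_rule: str = "percentile_width"
    horizon_years: float = 10.0

    def __post_init__(self) -> None:
        if self.target not in SCENARIO_TARGETS:
            raise ValidationError(f"unknown scenario target {self.target!r}")
        if not self.horizon_years > 0:
            raise ValidationError("horizon_years must be positive")

    @property
    def label(self) -> str:
        return self.target


@dataclass(frozen=True)
class BenefitModel:
    """NNT and annualization constants for one measure."""

    measure_id: str
    nnt_death: float
    annualization: str  # "lifetime" | "trial"
    lifetime_years: Optional[float] = None
    trial_followup_years: Optional[float] = None
    nnt_event: Optional[float] = None

    def __post_init__(self) -> None:
        if self.nnt_death < 1:
            raise ValidationError("nnt_death must be >= 1")
        if self.annualization == "lifetime":
            if not (self.lifetime_years and self.lifetime_years > 0):
                raise ValidationError("lifetime annualization requires lifetime_years > 0")
        elif self.annualization == "trial":
            if not (self.trial_followup_years and self.trial_followup_years > 0):
                raise ValidationError("trial annualization requires trial_followup_years > 0")
        else:
            raise ValidationError(f"unknown annualization mode {self.annualization!r}")
        if self.nnt_event is not None and self.nnt_event < 1:
            raise ValidationError("nnt_event must be >= 1 when given")

    @property
    def benefit_period_years(self) -> float:
        """Years over which one NNT-worth of treatment yields one averted death."""
        return self.lifetime_years if self.annualization == "lifetime" else self.trial_followup_years


@dataclass(frozen=True)
class ImpactResult:
    """Outputs of one measure x segment x scenario cell."""

    measure_id: str
    segment: str
    scenario: str
    numerator_gain: float
    lives_saved_per_horizon: float
    annual_lives_saved: float
    events_averted_per_horizon: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.numerator_gain, self.lives_saved_per_horizon, self.annual_lives_saved) < 0:
            raise ValidationError("impact quantities must be non-negative")


def numerator_gain(
    bins: Sequence[PercentileBin], target_score: float, denominator: float
) -> float:
    """Extra members meeting the numerator when every bin reaches ``target_score``.

    Sum over bins of (bin population share) x (denominator) x (percentage-point
    gap to the target) / 100.
    """
    if denominator < 0:
        raise ValidationError("denominator must be non-negative")
    return sum(
        b.population_weight * denominator * improvement_gap(b, target_score) / 100.0
        for b in bins
    )


def nnt_from_deaths_per_1000(deaths_averted_per_1000: float) -> float:
    """NNT implied by an absolute benefit of ``deaths_averted_per_1000``.

    The exact reciprocal 1000/d; report with half-up integer rounding
    (27 deaths per 1000 -> NNT 37).
    """
    if not 0 < deaths_averted_per_1000 <= 1000:
        raise ValidationError("deaths averted per 1000 must lie in (0, 1000]")
    return 1000.0 / deaths_averted_per_1000


def lives_saved(gain: float, model: BenefitModel, horizon_years: float = 10.0) -> float:
    """Deaths averted over ``horizon_years`` from ``gain`` extra numerator members.

    (gain / NNT) deaths accrue over the model's benefit period (remaining life
    expectancy or trial follow-up); the horizon scales that annual rate.
    """
    if gain < 0:
        raise ValidationError("numerator gain must be non-negative")
    return (gain / model.nnt_death) * horizon_years / model.benefit_period_years


def events_averted(
    gain: float, model: BenefitModel, horizon_years: float = 10.0
) -> Optional[float]:
    """Major adverse cardiovascular events averted, or None if not modelled.

    Only measures with an event NNT (hypertension control) produce a value;
    the event benefit is trial-period based like the mortality benefit.
    """
    if model.nnt_event is None:
        return None
    if gain < 0:
        raise ValidationError("numerator gain must be non-negative")
    return (gain / model.nnt_event) * horizon_years / model.trial_followup_years


def compute_impact(
    table: BenchmarkTable,
    denominator: float,
    model: BenefitModel,
    scenario: Scenario,
) -> ImpactResult:
    """Run the full binned chain for one measure x segment x scenario."""
    if scenario.target == "next_decile":
        raise ValidationError(
            "next_decile scenarios need plan-level data; use the sensitivity module"
        )
    bins = make_bins(table, scenario.weight_rule)
    target = table.target_score(scenario.target)
    gain = numerator_gain(bins, target, denominator)
    lives = lives_saved(gain, model, scenario.horizon_years)
    events = events_averted(gain, model, scenario.horizon_years)
    return ImpactResult(
        measure_id=table.measure_id,
        segment=table.segment,
        scenario=scenario.label,
        numerator_gain=gain,
        lives_saved_per_horizon=lives,
        annual_lives_saved=lives / scenario.horizon_years,
        events_averted_per_horizon=events,
    )


def aggregate_national(
    results: Iterable[ImpactResult],
    segments: Sequence[str] = NATIONAL_SEGMENTS,
) -> ImpactResult:
    """Component-wise sum of results over the included national segments.

    All inputs must share one measure and one scenario; the California
    Marketplace is excluded by default (reported separately, never part of
    national totals).
    """
    included = [r for r in results if r.segment in segments]
    if not included:
        raise ValidationError("no results in the requested segments")
    measures = {r.measure_id for r in included}
    scenarios = {r.scenario for r in included}
    if len(measures) > 1 or len(scenarios) > 1:
        raise ValidationError(
            f"cannot aggregate mixed measures {measures} or scenarios {scenarios}"
        )
    events = [r.events_averted_per_horizon for r in included]
    return ImpactResult(
        measure_id=included[0].measure_id,
        segment="National",
        scenario=included[0].scenario,
        numerator_gain=sum(r.numerator_gain for r in included),
        lives_saved_per_horizon=sum(r.lives_saved_per_horizon for r in included),
        annual_lives_saved=sum(r.annual_lives_saved for r in included),
        events_averted_per_horizon=(
            None if all(e is None for e in events) else sum(e or 0.0 for e in events)
        ),
    )


def percent_annual_death_reduction(
    lives_per_horizon: float, horizon_years: float, annual_condition_deaths: float
) -> float:
    """Annualized lives saved as a percent of annual condition-specific deaths.

    Reported to one decimal at the presentation layer; returned unrounded.
    """
    if annual_condition_deaths <= 0:
        raise ValidationError("annual_condition_deaths must be positive")
    if horizon_years <= 0:
        raise ValidationError("horizon_years must be positive")
    return 100.0 * (lives_per_horizon / horizon_years) / annual_condition_deaths
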