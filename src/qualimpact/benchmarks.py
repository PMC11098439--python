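"""Quality measures, percentile benchmark tables and conservative percentile bins.

Health-plan performance on a quality measure is published only at a handful of
percentiles of the plan distribution (25th, 50th, 66th, 75th, 90th).  The model
discretizes a market segment's plan distribution into bins bounded by those
percentiles and, conservatively, assumes every plan inside a bin already
performs at the *next highest* reported percentile — so estimated improvement
gaps understate true gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from .errors import DataUnavailableError, ValidationError

#: Percentiles at which benchmark scores are published.
PERCENTILES: tuple[int, ...] = (25, 50, 66, 75, 90)

#: Bin edges used to partition the plan distribution (percent of plans).
BIN_EDGES: tuple[int, ...] = (0, 25, 50, 66, 75, 90, 100)

#: Market segments (lines of business) the model recognizes.
SEGMENTS: tuple[str, ...] = (
    "Medicare",
    "Medicaid",
    "Marketplace",
    "Commercial",
    "CA-Marketplace",
)

WEIGHT_RULES: tuple[str, ...] = ("percentile_width", "equal_bins")


@dataclass(frozen=True)
class MeasureSpec:
    """Definition of one clinical quality measure.

    Parameters
    ----------
    measure_id : str
        Stable identifier, e.g. ``"crc_screening"`` or ``"bp_control"``.
    name : str
        Human-readable measure name.
    numerator_definition : str
        What counts a member into the numerator.
    eligible_ages : tuple[int, int]
        Closed integer age interval (years) of the measure denominator.
    uses_prevalence : bool
        True when the denominator is restricted to members with a condition
        (hypertension), so an age-specific prevalence table is required.
    """

    measure_id: str
    name: str
    numerator_definition: str
    eligible_ages: tuple[int, int]
    uses_prevalence: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.eligible_ages
        if not lo < hi:
            raise ValidationError(f"eligible age range must satisfy lo < hi, got {self.eligible_ages}")


CRC_SCREENING = MeasureSpec(
    measure_id="crc_screening",
    name="Colorectal cancer screening",
    numerator_definition="Members aged 50-75 screened for colorectal cancer per guideline",
    eligible_ages=(50, 75),
    uses_prevalence=False,
)

#: Controlling high blood pressure.  The numerator requires SBP <140 mm Hg and
#: DBP <90 mm Hg among members with diagnosed hypertension; the denominator age
#: window defaults to the measure's conventional 18-85 years (configurable via
#: a custom MeasureSpec).
BP_CONTROL = MeasureSpec(
    measure_id="bp_control",
    name="Controlling high blood pressure",
    numerator_definition="Hypertensive members with SBP <140 mm Hg and DBP <90 mm Hg",
    eligible_ages=(18, 85),
    uses_prevalence=True,
)

MEASURES: dict[str, MeasureSpec] = {m.measure_id: m for m in (CRC_SCREENING, BP_CONTROL)}


@dataclass(frozen=True)
class BenchmarkTable:
    """Published percentile scores for one measure in one market segment.

    ``scores`` maps percentile (25/50/66/75/90) to the measure score, in
    percent of the denominator meeting the numerator (0-100).  Scores must be
    non-decreasing in percentile.
    """

    measure_id: str
    segment: str
    scores: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.scores) != set(PERCENTILES):
            raise ValidationError(
                f"scores must be keyed by percentiles {PERCENTILES}, got {sorted(self.scores)}"
            )
        vals = [self.scores[p] for p in PERCENTILES]
        if any(not (0.0 <= v <= 100.0) for v in vals):
            raise ValidationError(f"scores must lie in [0, 100], got {vals}")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                f"scores must be non-decreasing across percentiles for "
                f"{self.measure_id}/{self.segment}: {vals}"
            )
        object.__setattr__(self, "scores", dict(sorted(self.scores.items())))

    def score_at(self, percentile: int) -> float:
        return self.scores[percentile]

    def target_score(self, target: str) -> float:
        """Score for a named scenario target (``"p66"`` or ``"p90"``)."""
        try:
            return self.scores[int(target.lstrip("p"))]
        except (KeyError, ValueError):
            raise ValidationError(f"unknown target {target!r}; expected 'p66' or 'p90'") from None

    def conservative_score(self, score: float) -> float:
        """Snap a plan's true score up to the next highest reported percentile score.

        Scores above the 90th-percentile score map to the 90th-percentile
        score; because scenario targets never exceed that score, the implied
        improvement gap is never overstated.
        """
        for p in PERCENTILES:
            if score <= self.scores[p]:
                return self.scores[p]
        return self.scores[90]


@dataclass(frozen=True)
class PercentileBin:
    """One slice of the plan distribution with its assumed score and weight."""

    lower_percentile: float
    upper_percentile: float
    assumed_score: float
    population_weight: float

    def __post_init__(self) -> None:
        if not self.lower_percentile < self.upper_percentile:
            raise ValidationError("bin must have lower_percentile < upper_percentile")
        if not 0.0 <= self.population_weight <= 1.0:
            raise ValidationError("population_weight must lie in [0, 1]")


BENCHMARK_CSV_COLUMNS = ["measure_id", "segment", "p25", "p50", "p66", "p75", "p90"]


def load_benchmark_table(
    source: Union[str, Path, pd.DataFrame], measure_id: str, segment: str
) -> BenchmarkTable:
    """Load and validate one (measure, segment) row from a benchmark CSV.

    The CSV schema is ``measure_id,segment,p25,p50,p66,p75,p90``; empty score
    cells mark a known data gap and raise :class:`DataUnavailableError`, as
    does a missing row.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing_cols = [c for c in BENCHMARK_CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"benchmark table missing columns {missing_cols}")
    rows = df[(df["measure_id"] == measure_id) & (df["segment"] == segment)]
    if rows.empty:
        raise DataUnavailableError(measure_id, segment, "no row in benchmark table")
    row = rows.iloc[0]
    vals = [row[f"p{p}"] for p in PERCENTILES]
    if any(pd.isna(v) for v in vals):
        raise DataUnavailableError(measure_id, segment, "benchmark scores not reported")
    return BenchmarkTable(
        measure_id=measure_id,
        segment=segment,
        scores={p: float(v) for p, v in zip(PERCENTILES, vals)},
    )


def load_benchmark_tables(source: Union[str, Path, pd.DataFrame]) -> list[BenchmarkTable]:
    """Load every available (measure, segment) table from a benchmark CSV.

    Rows with empty score cells (known data gaps) are skipped silently here;
    callers that need the gap flagged use :func:`load_benchmark_table`.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    tables = []
    for _, row in df.iterrows():
        try:
            tables.append(load_benchmark_table(df, row["measure_id"], row["segment"]))
        except DataUnavailableError:
            continue
    return tables


def make_bins(table: BenchmarkTable, weight_rule: str = "percentile_width") -> list[PercentileBin]:
    """Discretize a segment's plan distribution into conservative percentile bins.

    Bins partition (0, 100] at edges ``{0,25,50,66,75,90,100}``.  Each bin's
    assumed score is the published score at the bin's upper percentile (the
    next-highest-percentile rule); the open-ended top bin (90, 100] keeps the
    90th-percentile score.  Weights are either proportional to percentile
    interval width (``"percentile_width"``, the default reading of market
    share "evenly distributed across the percentiles") or uniform across the
    six bins (``"equal_bins"``).
    """
    if weight_rule not in WEIGHT_RULES:
        raise ValidationError(f"unknown weight_rule {weight_rule!r}; expected one of {WEIGHT_RULES}")
    bins = []
    n = len(BIN_EDGES) - 1
    for lo, hi in zip(BIN_EDGES, BIN_EDGES[1:]):
        assumed = table.scores[hi] if hi in table.scores else table.scores[90]
        weight = (hi - lo) / 100.0 if weight_rule == "percentile_width" else 1.0 / n
        bins.append(
            PercentileBin(
                lower_percentile=lo,
                upper_percentile=hi,
                assumed_score=assumed,
                population_weight=weight,
            )
        )
    return bins


def improvement_gap(bin: PercentileBin, target_score: float) -> float:
    """Percentage-point improvement a bin must make to reach ``target_score``.

    Never negative: bins at or above the target contribute zero (plans already
    at the benchmark are not modelled as regressing).
    """
    if not 0.0 <= target_score <= 100.0:
        raise ValidationError(f"target_score must lie in [0, 100], got {target_score}")
    return max(0.0, target_score - bin.assumed_score)
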