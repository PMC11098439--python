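"""Measure-eligible denominator populations from enrollment-by-age tables.

A segment's denominator is the number of members eligible for a measure:
for screening, enrollment inside the eligible age window; for hypertension
control, enrollment multiplied by age-specific hypertension prevalence.
Age bands are closed integer intervals in years; bands that only partially
overlap the eligible window are prorated uniformly (no within-band age
distribution is available) with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .benchmarks import MeasureSpec
from .errors import ValidationError

logger = logging.getLogger(__name__)

AgeBand = tuple[int, int]


def _band_len(band: AgeBand) -> int:
    return band[1] - band[0] + 1


def _overlap_years(band: AgeBand, window: AgeBand) -> int:
    return max(0, min(band[1], window[1]) - max(band[0], window[0]) + 1)


def _check_bands(bands) -> None:
    ordered = sorted(bands)
    for band in ordered:
        if band[0] > band[1]:
            raise ValidationError(f"age band {band} has lo > hi")
    for a, b in zip(ordered, ordered[1:]):
        if b[0] <= a[1]:
            raise ValidationError(f"age bands {a} and {b} overlap")


@dataclass(frozen=True)
class SegmentPopulation:
    """Enrollment of one market segment, broken down by age band."""

    segment: str
    enrollment_by_age: Mapping[AgeBand, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_bands(self.enrollment_by_age)
        if any(v < 0 for v in self.enrollment_by_age.values()):
            raise ValidationError("enrollment counts must be non-negative")
        object.__setattr__(self, "enrollment_by_age", dict(self.enrollment_by_age))

    @property
    def total(self) -> float:
        return float(sum(self.enrollment_by_age.values()))


@dataclass(frozen=True)
class PrevalenceTable:
    """Age-specific prevalence of one condition (fractions in [0, 1])."""

    condition: str
    rates_by_age: Mapping[AgeBand, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_bands(self.rates_by_age)
        if any(not 0.0 <= r <= 1.0 for r in self.rates_by_age.values()):
            raise ValidationError("prevalence rates must lie in [0, 1]")
        object.__setattr__(self, "rates_by_age", dict(self.rates_by_age))

    def rate_for_band(self, band: AgeBand) -> float:
        """Length-weighted average prevalence over ``band``.

        The prevalence table's bands need not align with the enrollment
        table's; the average assumes ages are uniform within each band.
        """
        total_years = 0
        acc = 0.0
        for pband, rate in self.rates_by_age.items():
            years = _overlap_years(band, pband)
            acc += years * rate
            total_years += years
        if total_years == 0:
            raise ValidationError(
                f"prevalence table {self.condition!r} does not cover ages {band}"
            )
        if total_years < _band_len(band):
            logger.warning(
                "prevalence table %r covers only %d of %d years of band %s",
                self.condition, total_years, _band_len(band), band,
            )
        return acc / total_years


def eligible_denominator(
    pop: SegmentPopulation,
    measure: MeasureSpec,
    prevalence: Optional[PrevalenceTable] = None,
) -> float:
    """Number of members in ``pop`` eligible for ``measure``.

    Enrollment in bands partially overlapping the eligible age window is
    prorated uniformly within the band.  For prevalence-based measures the
    prorated enrollment is multiplied by the age-band prevalence.
    """
    if measure.uses_prevalence and prevalence is None:
        raise ValidationError(
            f"measure {measure.measure_id!r} requires a prevalence table"
        )
    window = measure.eligible_ages
    total = 0.0
    for band, enrollment in pop.enrollment_by_age.items():
        years = _overlap_years(band, window)
        if years == 0:
            continue
        frac = years / _band_len(band)
        if frac < 1.0:
            logger.warning(
                "age band %s of segment %r only partially overlaps eligible range %s; "
                "prorating uniformly (%.0f%% of band)",
                band, pop.segment, window, 100 * frac,
            )
        eligible = enrollment * frac
        if measure.uses_prevalence:
            clipped = (max(band[0], window[0]), min(band[1], window[1]))
            eligible *= prevalence.rate_for_band(clipped)
        total += eligible
    return total


POPULATION_CSV_COLUMNS = ["segment", "age_lo", "age_hi", "enrollment"]
PREVALENCE_CSV_COLUMNS = ["condition", "age_lo", "age_hi", "rate"]


def load_population_csv(source: Union[str, Path, pd.DataFrame]) -> dict[str, SegmentPopulation]:
    """Read ``segment,age_lo,age_hi,enrollment`` rows into per-segment tables."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in POPULATION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"population table missing columns {missing}")
    out: dict[str, SegmentPopulation] = {}
    for segment, grp in df.groupby("segment", sort=False):
        bands = {
            (int(r.age_lo), int(r.age_hi)): float(r.enrollment) for r in grp.itertuples()
        }
        out[str(segment)] = SegmentPopulation(segment=str(segment), enrollment_by_age=bands)
    return out


def load_prevalence_csv(source: Union[str, Path, pd.DataFrame]) -> dict[str, PrevalenceTable]:
    """Read ``condition,age_lo,age_hi,rate`` rows into per-condition tables."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in PREVALENCE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"prevalence table missing columns {missing}")
    out: dict[str, PrevalenceTable] = {}
    for condition, grp in df.groupby("condition", sort=False):
        rates = {(int(r.age_lo), int(r.age_hi)): float(r.rate) for r in grp.itertuples()}
        out[str(condition)] = PrevalenceTable(condition=str(condition), rates_by_age=rates)
    return out
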