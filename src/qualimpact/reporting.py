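"""Pipeline orchestration, report tables, and documented-inconsistency warnings."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import refdata
from ._util import round_half_up
from .benchmarks import BenchmarkTable, MEASURES, load_benchmark_table, make_bins
from .errors import DataUnavailableError, ValidationError
from .impact import (
    ImpactResult,
    NATIONAL_SEGMENTS,
    Scenario,
    aggregate_national,
    compute_impact,
    numerator_gain,
    percent_annual_death_reduction,
)
from .population import eligible_denominator, load_population_csv, load_prevalence_csv
from .sensitivity import SensitivityReport, load_plan_roster, sensitivity_analysis

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "measure",
    "segment",
    "scenario",
    "numerator_gain",
    "lives_saved",
    "events_averted",
    "annual_lives_saved",
]

#: Row order for deterministic output files.
_SEGMENT_ORDER = ("Medicare", "Medicaid", "Marketplace", "Commercial", "CA-Marketplace", "National")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    CSV paths left as None fall back to the packaged reference inputs (the
    2019 measurement-year benchmarks and the synthetic back-solved
    populations).  ``scenarios`` hold binned targets ("p66"/"p90"); the
    next-decile sensitivity path runs whenever ``plans_csv`` is given.
    """

    benchmarks_csv: Optional[Union[str, Path]] = None
    population_csv: Optional[Union[str, Path]] = None
    prevalence_csv: Optional[Union[str, Path]] = None
    plans_csv: Optional[Union[str, Path]] = None
    measures: Sequence[str] = ("crc_screening", "bp_control")
    scenarios: Sequence[str] = ("p66", "p90")
    weight_rule: str = "percentile_width"
    horizon_years: float = 10.0
    annual_condition_deaths: dict = field(
        default_factory=lambda: dict(refdata.ANNUAL_CONDITION_DEATHS)
    )
    decile_basis: str = "plans"
    out_dir: Optional[Union[str, Path]] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Stable digest of the run configuration (logged for reproducibility)."""
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineOutput:
    """Results of one pipeline run."""

    results: list[ImpactResult]
    unavailable: list[tuple[str, str, str]]  # (measure, segment, reason)
    sensitivity: dict[tuple[str, str], list[SensitivityReport]]
    summary: dict
    paths: dict[str, Path]


def results_to_frame(results: Sequence[ImpactResult]) -> pd.DataFrame:
    """Tidy results frame in deterministic row order."""
    rows = [
        {
            "measure": r.measure_id,
            "segment": r.segment,
            "scenario": r.scenario,
            "numerator_gain": r.numerator_gain,
            "lives_saved": r.lives_saved_per_horizon,
            "events_averted": r.events_averted_per_horizon,
            "annual_lives_saved": r.annual_lives_saved,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if df.empty:
        return df
    df["_seg"] = df["segment"].map({s: i for i, s in enumerate(_SEGMENT_ORDER)}).fillna(99)
    df = df.sort_values(["measure", "scenario", "_seg", "segment"]).drop(columns="_seg")
    return df.reset_index(drop=True)


def frame_to_results(df: pd.DataFrame) -> list[ImpactResult]:
    """Inverse of :func:`results_to_frame` (round-trips written CSVs)."""
    out = []
    for r in df.itertuples():
        events = None if pd.isna(r.events_averted) else float(r.events_averted)
        out.append(
            ImpactResult(
                measure_id=str(r.measure),
                segment=str(r.segment),
                scenario=str(r.scenario),
                numerator_gain=float(r.numerator_gain),
                lives_saved_per_horizon=float(r.lives_saved),
                annual_lives_saved=float(r.annual_lives_saved),
                events_averted_per_horizon=events,
            )
        )
    return out


def table1_summary(tables: Sequence[BenchmarkTable]) -> dict:
    """Global score range and per-segment spread of the benchmark tables.

    Per-segment spread is the 90th-minus-25th-percentile score range averaged
    over that segment's measures; widest/narrowest are identified among
    segments reporting every measure present in the input (a segment with a
    data gap is not comparable on spread).
    """
    if not tables:
        raise ValidationError("need at least one benchmark table")
    all_scores = [s for t in tables for s in t.scores.values()]
    all_measures = {t.measure_id for t in tables}
    per_segment: dict[str, dict[str, float]] = {}
    for t in tables:
        per_segment.setdefault(t.segment, {})[t.measure_id] = t.scores[90] - t.scores[25]
    mean_range = {
        seg: sum(r.values()) / len(r) for seg, r in per_segment.items()
    }
    complete = {seg: m for seg, m in mean_range.items() if set(per_segment[seg]) == all_measures}
    ranked = sorted(complete, key=lambda s: (complete[s], s))
    return {
        "min_score": min(all_scores),
        "max_score": max(all_scores),
        "segment_ranges": per_segment,
        "segment_mean_range": mean_range,
        "widest_segment": ranked[-1] if ranked else None,
        "narrowest_segment": ranked[0] if ranked else None,
    }


def report_known_discrepancies() -> list[str]:
    """Recompute and log the known internal inconsistencies of the reference results.

    Three published figures do not follow from the published inputs under the
    model's own arithmetic; they are recomputed here at run time and logged as
    warnings, never silently reconciled:

    1. the hypertension 90th-percentile national total vs the sum of its
       published segment values;
    2. the screening percent-reductions in annual deaths vs the defining
       formula applied to the published decade lives;
    3. the Medicare/commercial screening p90:p66 lives ratios vs the ratios
       implied by either bin-weighting rule.
    """
    warnings: list[str] = []

    bp90 = refdata.REFERENCE_LIVES_SAVED["bp_control"]["p90"]
    seg_sum = sum(v for k, v in bp90.items() if k in NATIONAL_SEGMENTS)
    if abs(seg_sum - bp90["National"]) > 0.5:
        warnings.append(
            f"hypertension p90 published segment lives sum to {seg_sum:,.0f} "
            f"but the published national total is {bp90['National']:,.0f}; "
            "reporting the segment sum"
        )

    deaths = refdata.ANNUAL_CONDITION_DEATHS["crc_screening"]
    for target in ("p66", "p90"):
        lives = refdata.REFERENCE_LIVES_SAVED["crc_screening"][target]["National"]
        computed = percent_annual_death_reduction(lives, 10.0, deaths)
        published = refdata.REFERENCE_PERCENT_REDUCTIONS["crc_screening"][target]
        if abs(computed - published) > 0.1:
            warnings.append(
                f"screening {target} percent annual death reduction computes to "
                f"{computed:.1f}% from the published decade lives but {published}% "
                "is published; reporting the formula value"
            )

    csv = refdata.benchmark_csv_path()
    for segment in ("Medicare", "Commercial"):
        lives = refdata.REFERENCE_LIVES_SAVED["crc_screening"]
        published_ratio = lives["p90"][segment] / lives["p66"][segment]
        table = load_benchmark_table(csv, "crc_screening", segment)
        implied = {}
        for rule in ("percentile_width", "equal_bins"):
            bins = make_bins(table, rule)
            implied[rule] = numerator_gain(bins, table.scores[90], 1.0) / numerator_gain(
                bins, table.scores[66], 1.0
            )
        if all(abs(v - published_ratio) / published_ratio > 0.02 for v in implied.values()):
            warnings.append(
                f"screening {segment} p90:p66 lives ratio {published_ratio:.2f} (published) "
                f"is not reproduced by either weight rule "
                f"(percentile_width {implied['percentile_width']:.2f}, "
                f"equal_bins {implied['equal_bins']:.2f})"
            )

    for w in warnings:
        logger.warning(w)
    return warnings


def format_impact_table(results: Sequence[ImpactResult]) -> str:
    """Plain-text report: lives saved per decade by measure, segment, scenario."""
    df = results_to_frame(results)
    if df.empty:
        return "(no results)\n"
    lines = []
    for (measure, scenario), grp in df.groupby(["measure", "scenario"], sort=True):
        name = MEASURES[measure].name if measure in MEASURES else measure
        lines.append(f"{name} — improvement to {scenario}")
        show = grp.assign(
            numerator_gain=grp["numerator_gain"].map(round_half_up),
            lives_saved=grp["lives_saved"].map(round_half_up),
            annual_lives_saved=grp["annual_lives_saved"].round(1),
            events_averted=grp["events_averted"].map(
                lambda v: "-" if pd.isna(v) else f"{round_half_up(v):,}"
            ),
        )[["segment", "numerator_gain", "lives_saved", "events_averted", "annual_lives_saved"]]
        lines.append(show.to_string(index=False))
        lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> PipelineOutput:
    """Execute the full model: bins -> denominators -> gains -> lives/events.

    For every requested measure x segment x scenario the binned engine runs on
    the configured (or packaged reference) inputs; national aggregates exclude
    the California Marketplace.  Segments with missing benchmark data are
    flagged, not silently dropped.  When a plan roster is supplied, the
    next-decile / actual-market-share sensitivity analysis runs per segment.
    """
    logger.info("run config hash=%s seed=%d", config.config_hash(), config.seed)

    bench_src = Path(config.benchmarks_csv) if config.benchmarks_csv else refdata.benchmark_csv_path()
    bench_df = pd.read_csv(bench_src)
    if config.population_csv:
        populations = load_population_csv(config.population_csv)
    else:
        populations, ref_prev = refdata.reference_population_tables(config.weight_rule)
    if config.prevalence_csv:
        prevalences = load_prevalence_csv(config.prevalence_csv)
    elif config.population_csv:
        prevalences = {}
    else:
        prevalences = {ref_prev.condition: ref_prev}

    models = refdata.benefit_models()
    plans = load_plan_roster(config.plans_csv) if config.plans_csv else []

    results: list[ImpactResult] = []
    unavailable: list[tuple[str, str, str]] = []
    sens: dict[tuple[str, str], list[SensitivityReport]] = {}
    scenario_objs = [
        Scenario(target=t, weight_rule=config.weight_rule, horizon_years=config.horizon_years)
        for t in config.scenarios
    ]

    for measure_id in config.measures:
        measure = MEASURES[measure_id]
        model = models[measure_id]
        prevalence = prevalences.get("hypertension") if measure.uses_prevalence else None
        if measure.uses_prevalence and prevalence is None:
            raise ValidationError(
                f"measure {measure_id!r} needs a hypertension prevalence table; "
                "provide prevalence_csv"
            )
        for segment in (*NATIONAL_SEGMENTS, "CA-Marketplace"):
            if segment not in populations:
                continue
            try:
                table = load_benchmark_table(bench_df, measure_id, segment)
            except DataUnavailableError as exc:
                unavailable.append((measure_id, segment, str(exc)))
                logger.warning("skipping %s/%s: %s", measure_id, segment, exc)
                continue
            denom = eligible_denominator(populations[segment], measure, prevalence)
            for scenario in scenario_objs:
                results.append(compute_impact(table, denom, model, scenario))
            roster = [p for p in plans if p.segment == segment]
            if roster:
                sens[(measure_id, segment)] = sensitivity_analysis(
                    roster,
                    table,
                    denom,
                    model,
                    Scenario("p66", config.weight_rule, config.horizon_years),
                    decile_basis=config.decile_basis,
                )
        for scenario in scenario_objs:
            cell = [
                r
                for r in results
                if r.measure_id == measure_id and r.scenario == scenario.label
            ]
            if any(r.segment in NATIONAL_SEGMENTS for r in cell):
                results.append(aggregate_national(cell))

    summary = _summarize(config, results, unavailable, sens)
    report_known_discrepancies()

    paths: dict[str, Path] = {}
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths["results_csv"] = out_dir / "results.csv"
        results_to_frame(results).to_csv(paths["results_csv"], index=False, float_format="%.6f")
        paths["summary_json"] = out_dir / "summary.json"
        paths["summary_json"].write_text(json.dumps(summary, indent=2, sort_keys=True))
        paths["report_txt"] = out_dir / "report.txt"
        paths["report_txt"].write_text(format_impact_table(results))
    return PipelineOutput(results, unavailable, sens, summary, paths)


def _summarize(config, results, unavailable, sens) -> dict:
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "horizon_years": config.horizon_years,
        "national_lives_saved": {},
        "national_events_averted": {},
        "percent_annual_death_reduction": {},
        "data_unavailable": [list(u) for u in unavailable],
        "sensitivity": {
            f"{m}/{s}": [
                {
                    "label": r.label,
                    "baseline_lives": r.baseline_lives,
                    "variant_lives": r.variant_lives,
                    "relative_change_pct": r.relative_change_pct,
                }
                for r in reports
            ]
            for (m, s), reports in sens.items()
        },
    }
    for r in results:
        if r.segment != "National":
            continue
        key = f"{r.measure_id}/{r.scenario}"
        summary["national_lives_saved"][key] = r.lives_saved_per_horizon
        if r.events_averted_per_horizon is not None:
            summary["national_events_averted"][key] = r.events_averted_per_horizon
        deaths = config.annual_condition_deaths.get(r.measure_id)
        if deaths:
            summary["percent_annual_death_reduction"][key] = round(
                percent_annual_death_reduction(
                    r.lives_saved_per_horizon, config.horizon_years, deaths
                ),
                1,
            )
    return summary
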