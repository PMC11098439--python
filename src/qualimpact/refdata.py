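"""Packaged reference inputs: 2019 measurement-year benchmarks and model constants.

The benchmark percentile scores (NCQA Quality Compass / Medicare Part C & D /
Marketplace QRS, 2019 measurement year) and the headline estimates of the
published national quality-impact analysis are shipped here as the model's
reference scenario.  The original enrollment-by-age and prevalence source
tables behind the published numerator gains are not public; the reference
populations returned by :func:`reference_population_tables` are therefore
synthetic — back-solved so each segment's eligible denominator reproduces the
published numerator gain under the default percentile-width bins, with the
age-band split following a plausible hypertension-prevalence-by-age profile.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

from ._util import round_half_up
from .benchmarks import BenchmarkTable, load_benchmark_table, load_benchmark_tables, make_bins
from .impact import BenefitModel, numerator_gain
from .population import AgeBand, PrevalenceTable, SegmentPopulation

#: Deaths averted per 1000 screened (colonoscopy, ages 50-75, lifetime;
#: microsimulation average behind the USPSTF recommendation) and the constants
#: of the two NNT chains.
CRC_DEATHS_AVERTED_PER_1000 = 27.0
CRC_NNT_DEATH = 37.0            # published rounding of 1000/27
CRC_REMAINING_LIFE_YEARS = 22.0  # average remaining life expectancy at age 50
BP_NNT_DEATH = 101.0            # all-cause mortality, primary-prevention meta-analysis
BP_TRIAL_FOLLOWUP_YEARS = 4.0   # median follow-up of that meta-analysis
DEFAULT_HORIZON_YEARS = 10.0

#: Annual US condition-specific deaths (denominators of percent-reduction stats).
ANNUAL_CONDITION_DEATHS = {"crc_screening": 51_869.0, "bp_control": 691_095.0}

#: Published numerator gains (additional members meeting the numerator) when
#: every plan below the 66th-percentile benchmark reaches it.
REFERENCE_NUMERATOR_GAINS_P66 = {
    "crc_screening": {
        "Medicare": 1_228_663.0,
        "Marketplace": 217_638.0,
        "Commercial": 1_274_794.0,
        "CA-Marketplace": 20_865.0,
    },
    "bp_control": {
        "Medicare": 1_168_105.0,
        "Medicaid": 875_763.0,
        "Marketplace": 192_372.0,
        "Commercial": 2_192_477.0,
        "CA-Marketplace": 13_880.0,
    },
}

#: Published lives saved per decade, by scenario target and segment
#: ("National" excludes the California Marketplace).
REFERENCE_LIVES_SAVED = {
    "crc_screening": {
        "p66": {
            "Medicare": 15_127.0,
            "Marketplace": 2_680.0,
            "Commercial": 15_695.0,
            "CA-Marketplace": 257.0,
            "National": 33_502.0,
        },
        "p90": {
            "Medicare": 46_027.0,
            "Marketplace": 5_992.0,
            "Commercial": 33_412.0,
            "CA-Marketplace": 679.0,
            "National": 85_432.0,
        },
    },
    "bp_control": {
        "p66": {"CA-Marketplace": 330.0, "National": 110_067.0},
        "p90": {
            "Medicare": 80_080.0,
            "Medicaid": 51_760.0,
            "Marketplace": 12_260.0,
            "Commercial": 140_060.0,
            "CA-Marketplace": 1_320.0,
            "National": 280_487.0,
        },
    },
}

#: Published major-adverse-cardiovascular-event totals (10 years, all markets).
REFERENCE_MACE_AVERTED = {"p66": 137_164.0, "p90": 335_006.0}

#: Published percent reductions in annual condition-specific deaths.
REFERENCE_PERCENT_REDUCTIONS = {
    "crc_screening": {"p66": 6.9, "p90": 17.5},
    "bp_control": {"p66": 1.6, "p90": 4.0},
}

#: Share of California Marketplace members in the lowest-performing plan,
#: by measure (the enrollment-concentration facts the generator emulates).
ENROLLMENT_CONCENTRATION = {"bp_control": 0.33, "crc_screening": 0.16}


def benchmark_csv_path() -> Path:
    """Path of the packaged 2019 measurement-year benchmark CSV."""
    return Path(resources.files("qualimpact").joinpath("data/benchmarks_my2019.csv"))


def reference_benchmark_tables() -> list[BenchmarkTable]:
    """All nine available measure x segment benchmark tables."""
    return load_benchmark_tables(benchmark_csv_path())


def calibrated_mace_nnt(horizon_years: float = DEFAULT_HORIZON_YEARS) -> float:
    """NNT to avert one major cardiovascular event — a calibrated constant.

    No event NNT is published; this back-solves it from the published national
    66th-percentile numerator gains and the published 137,164 events averted
    over a decade (trial-period annualization, like the mortality chain).
    """
    national_gain = sum(
        g
        for seg, g in REFERENCE_NUMERATOR_GAINS_P66["bp_control"].items()
        if seg != "CA-Marketplace"
    )
    factor = horizon_years / BP_TRIAL_FOLLOWUP_YEARS
    return national_gain * factor / REFERENCE_MACE_AVERTED["p66"]


def benefit_models() -> dict[str, BenefitModel]:
    """Default benefit models for the two measures."""
    return {
        "crc_screening": BenefitModel(
            measure_id="crc_screening",
            nnt_death=CRC_NNT_DEATH,
            annualization="lifetime",
            lifetime_years=CRC_REMAINING_LIFE_YEARS,
        ),
        "bp_control": BenefitModel(
            measure_id="bp_control",
            nnt_death=BP_NNT_DEATH,
            annualization="trial",
            trial_followup_years=BP_TRIAL_FOLLOWUP_YEARS,
            nnt_event=calibrated_mace_nnt(),
        ),
    }


def reference_denominators(weight_rule: str = "percentile_width") -> dict[str, dict[str, float]]:
    """Segment denominators back-solved from the published p66 numerator gains.

    gain = denominator x (weighted percentage-point gap)/100, so the
    denominator is gain divided by the per-member gain fraction of the
    segment's bins at the 66th-percentile target.
    """
    csv = benchmark_csv_path()
    out: dict[str, dict[str, float]] = {}
    for measure_id, gains in REFERENCE_NUMERATOR_GAINS_P66.items():
        out[measure_id] = {}
        for segment, gain in gains.items():
            table = load_benchmark_table(csv, measure_id, segment)
            bins = make_bins(table, weight_rule)
            per_member = numerator_gain(bins, table.target_score("p66"), 1.0)
            out[measure_id][segment] = gain / per_member
    return out


#: Hypertension prevalence by age band used to split back-solved denominators
#: into age bands (synthetic profile, roughly tracking US adult prevalence).
HYPERTENSION_PREVALENCE_BY_AGE: dict[AgeBand, float] = {
    (18, 49): 0.30,
    (50, 75): 0.60,
    (76, 85): 0.78,
}

#: Share of the residual hypertension denominator (after the 50-75 band is
#: pinned by the screening denominator) placed in the 18-49 band, per segment.
_YOUNG_RESIDUAL_SHARE = {
    "Medicare": 0.08,
    "Marketplace": 0.85,
    "Commercial": 0.95,
    "CA-Marketplace": 1.0,
}

#: Medicaid has no screening benchmark, so its full hypertension denominator
#: is split by these band shares (young-skewed membership).
_MEDICAID_BP_DENOM_SHARES = {(18, 49): 0.65, (50, 75): 0.30, (76, 85): 0.05}


def reference_population_tables(
    weight_rule: str = "percentile_width",
) -> tuple[dict[str, SegmentPopulation], PrevalenceTable]:
    """Synthetic enrollment-by-age tables consistent with the published gains.

    For each segment, the 50-75 band equals the back-solved screening
    denominator (where a screening benchmark exists) and the 18-49 / 76-85
    bands absorb the remaining hypertension denominator under the synthetic
    prevalence profile.  Feeding these tables through the population module
    reproduces the back-solved denominators to within rounding.
    """
    denoms = reference_denominators(weight_rule)
    prev = PrevalenceTable(condition="hypertension", rates_by_age=HYPERTENSION_PREVALENCE_BY_AGE)
    r1 = HYPERTENSION_PREVALENCE_BY_AGE[(18, 49)]
    r2 = HYPERTENSION_PREVALENCE_BY_AGE[(50, 75)]
    r3 = HYPERTENSION_PREVALENCE_BY_AGE[(76, 85)]

    pops: dict[str, SegmentPopulation] = {}
    for segment, bp_denom in denoms["bp_control"].items():
        if segment == "Medicaid":
            bands = {
                band: round_half_up(share * bp_denom / HYPERTENSION_PREVALENCE_BY_AGE[band])
                for band, share in _MEDICAID_BP_DENOM_SHARES.items()
            }
        else:
            e2 = denoms["crc_screening"][segment]
            residual = bp_denom - r2 * e2
            alpha = _YOUNG_RESIDUAL_SHARE[segment]
            bands = {
                (18, 49): round_half_up(alpha * residual / r1),
                (50, 75): round_half_up(e2),
                (76, 85): round_half_up((1.0 - alpha) * residual / r3),
            }
        pops[segment] = SegmentPopulation(
            segment=segment,
            enrollment_by_age={b: float(v) for b, v in bands.items()},
        )
    return pops, prev


def write_reference_inputs(out_dir: Union[str, Path]) -> dict[str, Path]:
    """Materialize the reference benchmark/population/prevalence CSVs.

    Returns the paths keyed by role, in the schemas the loaders consume.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"benchmarks": out_dir / "benchmarks.csv"}
    pd.read_csv(benchmark_csv_path()).to_csv(paths["benchmarks"], index=False)

    pops, prev = reference_population_tables()
    pop_rows = [
        {"segment": seg, "age_lo": lo, "age_hi": hi, "enrollment": e}
        for seg, pop in pops.items()
        for (lo, hi), e in sorted(pop.enrollment_by_age.items())
    ]
    paths["population"] = out_dir / "population.csv"
    pd.DataFrame(pop_rows).to_csv(paths["population"], index=False)

    prev_rows = [
        {"condition": prev.condition, "age_lo": lo, "age_hi": hi, "rate": r}
        for (lo, hi), r in sorted(prev.rates_by_age.items())
    ]
    paths["prevalence"] = out_dir / "prevalence.csv"
    pd.DataFrame(prev_rows).to_csv(paths["prevalence"], index=False)
    return paths
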