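# Methods

## Model

The package estimates the mortality and cardiovascular-event benefit of
health plans improving to percentile benchmarks of the national performance
distribution on two quality measures:

* **Colorectal cancer screening** — members aged 50–75 screened per
  guideline. Benefit constant: 27 deaths averted per 1000 screened over the
  screened cohort's remaining lifetimes (colonoscopy, microsimulation-based),
  i.e. NNT = 1000/27, reported half-up as 37. Because the benefit accrues
  over a lifetime, decade-horizon lives saved are annualized by average
  remaining life expectancy at screening initiation, `L = 22` years:
  `lives(H) = ΔN/NNT · H/L`.
* **Controlling high blood pressure** — members with diagnosed hypertension
  whose SBP <140 mm Hg and DBP <90 mm Hg. Benefit constants from a
  primary-prevention meta-analysis of antihypertensive trials: all-cause
  mortality NNT = 101 over a median follow-up `F = 4` years, so
  `lives(H) = ΔN/NNT · H/F`. Major adverse cardiovascular events (MACE) use
  the same trial-period form with a separate event NNT.

The two annualization schemes are explicit, non-interchangeable modes of
`BenefitModel` (`"lifetime"` vs `"trial"`); applying the wrong period is the
model's main silent-failure risk and is covered by a dedicated test.

### Conservative percentile binning

Only five percentile scores per measure × segment are published. The plan
distribution is partitioned at percentile edges {0, 25, 50, 66, 75, 90, 100};
each bin's assumed score is the published score at its upper edge (the top
bin (90, 100] keeps the P90 score), so plans are assumed to already perform
at the next highest published percentile and gaps to a target are
understated. A plan-level restatement of the same rule
(`BenchmarkTable.conservative_score`, `conservative_binned_gain`) snaps
individual plan scores up to the next published percentile score; it is
provably never above the exact plan-level gain and is property-tested on
seeded synthetic rosters.

Market share across percentiles: "evenly distributed" admits two readings,
both implemented and selectable (`weight_rule`):

* `percentile_width` (default): bin weight ∝ percentile interval width,
  weights (0.25, 0.25, 0.16, 0.09, 0.15, 0.10);
* `equal_bins`: 1/6 per bin.

Neither reading reproduces every published p90:p66 lives ratio (see
*Known non-reproductions*); the knob is exposed rather than tuned.

Scores are carried as percentages (0–100), matching how benchmark tables are
printed, and converted to fractions only inside arithmetic. Ties at a
benchmark contribute zero gain (a plan "at" the benchmark is not below it).

### Denominators

`eligible_denominator` sums enrollment over the measure's age window
(screening 50–75; hypertension 18–85 by convention — the window is a
`MeasureSpec` field, not hard-coded), prorating bands that partially overlap
the window uniformly (no within-band age distribution is available; a warning
is logged). Prevalence-based measures multiply by a length-weighted average
of age-specific prevalence. Medicare/Medicaid benchmark scores come from
managed-care plans but are extrapolated to the full population simply by
supplying full-population enrollment in the population table; no separate
managed-care scaling factor exists.

### Aggregation and summary statistics

National totals sum Medicare, Medicaid, Marketplace and commercial;
the California Marketplace is a state carve-out reported separately and never
added to national totals. The percent reduction in annual condition-specific
deaths is `100 · (lives_per_horizon/H) / annual_condition_deaths`, with
annual deaths 51,869 (colorectal cancer) and 691,095 (hypertension). Person
counts are rounded half-up only at the reporting layer.

### Sensitivity analyses

With a plan roster (id, segment, enrollment, score), two assumptions are
relaxed:

* **Next-decile improvement**: plans below the P66 benchmark target the upper
  score boundary of the next non-empty performance decile, capped at the
  benchmark; plans at/above the benchmark keep their score. Deciles are
  ranks of plans by default (`decile_basis="plans"`); a member-weighted
  variant (`"members"`) is provided because the decile basis is genuinely
  ambiguous.
* **Actual market share**: the segment denominator is split across plans
  proportionally to enrollment (`by_enrollment`) instead of evenly.

Reports give lives saved under each variant as a signed percent change from
the binned P66 baseline.

## Synthetic data

`synthetic` draws plan scores from the monotone piecewise-linear quantile
function through the published points (0.25, P25) … (0.90, P90), extended
linearly to (0, P25−5) and (1, P90+5) and clipped to [0, 100]. The ±5-point
tail extension is arbitrary by design: nothing is published about the tails,
and the generator's contract is only to reproduce the five published
percentiles (within 2 score points for n ≥ 200, tested at n ∈ {200, 1000}).
Enrollment concentrates a configurable fraction in the lowest-scoring plan —
defaults follow the published concentration facts for the California
Marketplace (33% of members for the hypertension measure, 16% for screening)
— with the remainder split uniformly (or Dirichlet). Integer conservation
uses largest-remainder apportionment with position tie-breaks. All
randomness flows from the single `SynthConfig.seed`; there is no global
random state.

What the generator does *not* emulate: real rosters have correlated
enrollment and performance ("larger plans perform better"), regional
structure, and score dynamics over time. Passing tests therefore validate
the pipeline's arithmetic and its conservativeness direction, not the
realism of any particular market.

## Reference inputs

The packaged benchmark CSV carries the 2019 measurement-year percentile
scores for nine measure × segment pairs (no Medicaid screening distribution
exists; the gap is an explicit `DataUnavailableError`, never a zero). The
enrollment/prevalence tables behind the published numerator gains are not
public, so the published gains are treated as inputs: reference segment
denominators are **back-solved** as gain ÷ per-member gain fraction of the
segment's P66 bins, and `reference_population_tables` splits them into
synthetic age bands under a plausible hypertension-prevalence-by-age profile
(0.30 / 0.60 / 0.78 for ages 18–49 / 50–75 / 76–85). Feeding those tables
through the population and impact modules reproduces the published P66
numerator gains to within integer rounding — that is the point: the
acceptance surface is the benefit-conversion chain, aggregation, summary
statistics and distribution engine, not the proprietary denominator
construction. The MACE NNT has no published value; the shipped default
(≈80.72) is calibrated at run time from the published national P66 gains and
the published 137,164 events per decade.

## Numerical choices

* Internal arithmetic is float; reported persons are rounded half-up at the
  reporting layer only; results CSVs are written at 6 decimals and round-trip
  bit-identically at that precision.
* Worked-example tolerance for published lives figures is 1% relative: the
  published values embed unstated intermediate rounding
  (e.g. 20,865/37 × 10/22 = 256.3 vs a printed 257).
* Largest-remainder ties break on position (ascending band / plan order);
  score ties in decile assignment break on plan id.
* Degenerate inputs: constant benchmark tables give every bin the same
  assumed score; empty scenario lists produce an empty, successful run;
  empty rosters are an error.

## Problem sizes

Tests and the acceptance script use synthetic rosters of 30–2000 plans,
100 seeded conservativeness draws and 1000-plan calibration checks — sizes at
which percentile calibration is stable to well under the 2-point contract and
the full suite runs in seconds on one CPU.

## Known non-reproductions

Recomputed and logged as warnings by `report_known_discrepancies`, never
reconciled silently:

* the hypertension P90 published segment lives sum to 284,160 while the
  published national total is 280,487; the pipeline reports the sum;
* the screening percent reductions in annual deaths compute to 6.5% (P66)
  and 16.5% (P90) from the published decade lives and the 51,869 annual
  deaths, vs published 6.9% and 17.5%; the formula value is reported;
* the Medicare and commercial screening p90:p66 lives ratios are not
  reproduced by either bin-weighting rule (e.g. Medicare: published 3.04 vs
  1.95 / 2.20), so P90 national screening and hypertension totals computed by
  the engine differ from the published ones; per-segment residuals are
  visible in the logs rather than forced to agree.

## Limitations

Only mortality (and, for hypertension, MACE) benefits are modelled — no
non-fatal, non-major endpoints, no spillover to members outside the measure
numerator. National distributions are used throughout; regional variation,
uninsured populations and longitudinal improvement dynamics are out of
scope. The published ±% sensitivity figures for the California Marketplace
require its proprietary roster and are deliberately not asserted; the
sensitivity machinery is instead property-tested on synthetic rosters
calibrated to the published concentration facts.
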