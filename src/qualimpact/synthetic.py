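"""Synthetic plan rosters and population tables with the model's assumed structure.

Real plan-level performance distributions are proprietary; what is public is
five percentile scores per measure and segment, plus the stylized fact that a
large share of members can sit in the lowest-performing plan (33% of the
California Marketplace hypertension-measure population, 16% for colorectal
screening).  The generator draws plan scores from the monotone piecewise-linear
quantile function through the published percentile points, and concentrates a
configurable fraction of enrollment in the lowest-scoring plan, so every stage
of the pipeline is testable without any proprietary download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import largest_remainder
from .benchmarks import PERCENTILES, BenchmarkTable
from .errors import ValidationError
from .population import AgeBand, SegmentPopulation
from .sensitivity import PLAN_CSV_COLUMNS, PlanRecord

#: How far the quantile function extends past the outermost published
#: percentiles (score points at quantile 0 and 1), before clipping to [0, 100].
TAIL_EXTENSION_POINTS = 5.0


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic roster draw.

    ``enrollment_concentration`` is the fraction of members assigned to the
    lowest-scoring plan (0 means a uniform split); the remainder is split
    uniformly, or Dirichlet-randomly when ``remainder="dirichlet"``.  All
    randomness flows from ``seed``; there is no global random state.
    """

    n_plans: int
    target_percentiles: BenchmarkTable
    enrollment_total: int
    enrollment_concentration: float = 0.0
    seed: int = 0
    segment: str = "synthetic"
    remainder: str = "uniform"  # "uniform" | "dirichlet"

    def __post_init__(self) -> None:
        if self.n_plans < 2:
            raise ValidationError("n_plans must be >= 2")
        if not self.enrollment_total > 0:
            raise ValidationError("enrollment_total must be positive")
        if not 0.0 <= self.enrollment_concentration < 1.0:
            raise ValidationError("enrollment_concentration must lie in [0, 1)")
        if self.remainder not in ("uniform", "dirichlet"):
            raise ValidationError(f"unknown remainder rule {self.remainder!r}")


def quantile_nodes(table: BenchmarkTable) -> tuple[np.ndarray, np.ndarray]:
    """Nodes of the piecewise-linear quantile function through the published points.

    Interpolates through (0.25, P25) ... (0.90, P90), extended linearly to
    (0, P25 - 5) and (1, P90 + 5) and clipped to [0, 100].  BenchmarkTable
    validation guarantees monotone scores, hence a valid quantile function.
    """
    q = np.array([0.0] + [p / 100.0 for p in PERCENTILES] + [1.0])
    scores = [table.scores[p] for p in PERCENTILES]
    v = np.array(
        [scores[0] - TAIL_EXTENSION_POINTS] + scores + [scores[-1] + TAIL_EXTENSION_POINTS]
    )
    return q, np.clip(v, 0.0, 100.0)


def synth_plan_scores(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw ``n_plans`` scores from the table-implied quantile function.

    Empirical 25/50/66/75/90th percentiles of large draws (n >= 200) track the
    target table to within about 2 score points.  Reproducible given the seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    q, v = quantile_nodes(config.target_percentiles)
    u = rng.uniform(size=config.n_plans)
    return np.interp(u, q, v)


def synth_enrollment(
    config: SynthConfig,
    scores: Sequence[float],
    rng: Optional[np.random.Generator] = None,
) -> list[PlanRecord]:
    """Assign enrollment to scored plans, concentrating the lowest performer.

    The lowest-scoring plan (first by score, ties broken by index) receives
    ``enrollment_concentration x enrollment_total``; the remainder is split
    uniformly or Dirichlet-randomly across the other plans.  Integer member
    counts are produced by largest-remainder apportionment, so the configured
    total is conserved exactly.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 2:
        raise ValidationError("need at least 2 scored plans")
    lowest = int(np.argmin(scores))
    c = config.enrollment_concentration
    fractions = np.empty(n)
    if c == 0.0:
        fractions[:] = 1.0 / n
    else:
        rest = np.ones(n - 1) / (n - 1)
        if config.remainder == "dirichlet":
            rng = rng or np.random.default_rng(config.seed + 1)
            rest = rng.dirichlet(np.ones(n - 1))
        fractions[lowest] = c
        fractions[np.arange(n) != lowest] = (1.0 - c) * rest
    counts = largest_remainder(config.enrollment_total, fractions.tolist())
    width = len(str(n - 1))
    return [
        PlanRecord(
            plan_id=f"{config.segment}-{i:0{width}d}",
            segment=config.segment,
            enrollment=float(counts[i]),
            score=float(scores[i]),
        )
        for i in range(n)
        if counts[i] > 0
    ]


def synth_roster(config: SynthConfig) -> list[PlanRecord]:
    """Scores + enrollment in one call, all randomness from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    scores = synth_plan_scores(config, rng=rng)
    return synth_enrollment(config, scores, rng=rng)


def synth_population(
    segment: str,
    total: int,
    age_profile: Mapping[AgeBand, float],
    atol: float = 1e-9,
) -> SegmentPopulation:
    """Build an enrollment-by-age table from a total and age-share profile.

    Band counts are largest-remainder rounded so they sum exactly to
    ``total``; ties break on band order (ascending age).
    """
    bands = sorted(age_profile)
    fractions = [age_profile[b] for b in bands]
    if abs(sum(fractions) - 1.0) > atol:
        raise ValidationError(f"age profile fractions must sum to 1, got {sum(fractions)!r}")
    counts = largest_remainder(total, fractions)
    return SegmentPopulation(
        segment=segment,
        enrollment_by_age={b: float(c) for b, c in zip(bands, counts)},
    )


def write_roster_csv(plans: Sequence[PlanRecord], path: Union[str, Path]) -> None:
    """Emit a roster in the schema the sensitivity module consumes."""
    pd.DataFrame(
        [
            {"plan_id": p.plan_id, "segment": p.segment, "enrollment": p.enrollment, "score": p.score}
            for p in plans
        ],
        columns=PLAN_CSV_COLUMNS,
    ).to_csv(path, index=False)
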