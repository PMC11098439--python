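"""Small numeric helpers: reporting-layer rounding and integer apportionment."""

from __future__ import annotations

import math
from collections.abc import Sequence


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves upward.

    Person counts are reported with conventional half-up rounding rather than
    banker's rounding; internal arithmetic stays real-valued.
    """
    return math.floor(x + 0.5)


def largest_remainder(total: int, fractions: Sequence[float], *, atol: float = 1e-9) -> list[int]:
    """Apportion ``total`` integer units across ``fractions`` (which sum to 1).

    Hamilton / largest-remainder method: floor each quota, then hand out the
    leftover units in order of decreasing fractional remainder.  Ties break on
    position (earlier entry wins), which makes the result deterministic.
    """
    if not fractions:
        raise ValueError("fractions must be non-empty")
    s = float(sum(fractions))
    if abs(s - 1.0) > atol:
        raise ValueError(f"fractions must sum to 1 (got {s!r})")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    quotas = [total * f for f in fractions]
    base = [math.floor(q) for q in quotas]
    leftover = total - sum(base)
    # stable sort => earlier index wins ties on remainder
    order = sorted(range(len(fractions)), key=lambda i: quotas[i] - base[i], reverse=True)
    for i in order[:leftover]:
        base[i] += 1
    return base
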