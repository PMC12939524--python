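"""Small shared numeric helpers."""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; cohort composition
    counts (cases, errors, undecided calls) use half-away-from-zero so that
    tallies derived from printed, rounded rates are reproduced exactly.
    """
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def check_fraction(value: float, name: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return float(value)
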