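"""Agreement of diagnostic strategies against a clinical reference.

Implements the diagnostic-concordance toolkit used to compare a probability
score and physician groups against an adjudicated reference diagnosis:
overall / positive / negative percent agreement (OPA/PPA/NPA) with Wilson
score intervals, Gwet's AC1 chance-corrected agreement with bootstrap
percentile intervals, response-level pooling across raters, and Stage-I
indecision rates.

AC1's chance term is based on the mean of the two raters' marginal positive
proportions, ``pe = 2*pi*(1-pi)``, which keeps the coefficient stable at the
prevalence extremes where kappa collapses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "AgreementEstimate",
    "build_confusion",
    "opa",
    "ppa",
    "npa",
    "wilson_interval",
    "gwet_ac1",
    "bootstrap_interval",
    "pool_calls",
    "indecision_rate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally of binary calls against the reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Reference-positive count."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        """Reference-negative count."""
        return self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class AgreementEstimate:
    """A named agreement statistic with its confidence interval."""

    statistic: str
    point: float
    ci_low: float
    ci_high: float
    method: str  # "wilson" or "bootstrap"
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.point + 1e-12 and self.point <= self.ci_high + 1e-12):
            raise ValueError("point estimate must lie inside its interval")


def build_confusion(
    calls: Sequence[str],
    reference: Sequence[str],
    positive_label: str = "PJI",
) -> ConfusionCounts:
    """Tally binary calls against the reference; undecided calls are rejected."""
    if len(calls) != len(reference):
        raise ValueError("calls and reference must have equal length")
    labels = set(calls) | set(reference)
    if "undecided" in labels:
        raise ValueError("undecided call present; a definitive binary stage is required")
    tp = fp = fn = tn = 0
    for c, r in zip(calls, reference):
        if c == positive_label:
            if r == positive_label:
                tp += 1
            else:
                fp += 1
        else:
            if r == positive_label:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def opa(c: ConfusionCounts) -> float:
    """Overall percent agreement, (tp+tn)/n, as a fraction."""
    return (c.tp + c.tn) / c.n


def ppa(c: ConfusionCounts) -> float:
    """Positive percent agreement, tp/(tp+fn)."""
    if c.positives == 0:
        raise ValueError("PPA undefined: no reference-positive cases")
    return c.tp / c.positives


def npa(c: ConfusionCounts) -> float:
    """Negative percent agreement, tn/(tn+fp)."""
    if c.negatives == 0:
        raise ValueError("NPA undefined: no reference-negative cases")
    return c.tn / c.negatives


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k!r}, n={n!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return float(lo), float(hi)


def gwet_ac1(c: ConfusionCounts) -> float:
    """Gwet's AC1 chance-corrected agreement from a 2x2 tally.

    AC1 = (pa - pe)/(1 - pe) with pa = (tp+tn)/n and pe = 2*pi*(1-pi),
    where pi is the mean of the two marginal positive proportions.
    """
    n = c.n
    pa = (c.tp + c.tn) / n
    pi = ((c.tp + c.fn) / n + (c.tp + c.fp) / n) / 2.0
    pe = 2.0 * pi * (1.0 - pi)
    if pe >= 1.0:
        raise ValueError("AC1 undefined: chance agreement pe = 1")
    return (pa - pe) / (1.0 - pe)


def bootstrap_interval(
    statistic: Callable[[Sequence], float],
    data: Sequence,
    B: int = 2000,
    seed: Optional[int] = None,
    conf: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval over case-resampled replicates.

    ``data`` is a sequence of per-case records (whatever ``statistic``
    consumes); each replicate resamples cases with replacement.  Replicates
    on which the statistic is undefined (raises ValueError or
    ZeroDivisionError) are skipped; more than 50% skipped is a failure.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(data)
    if n == 0:
        raise ValueError("data must be non-empty")
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    items = list(data)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = [items[i] for i in idx]
        try:
            values.append(statistic(sample))
        except (ValueError, ZeroDivisionError):
            skipped += 1
    if skipped > B / 2:
        raise RuntimeError(
            f"bootstrap failed: statistic undefined on {skipped}/{B} replicates"
        )
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def pool_calls(
    calls: Sequence[Sequence[str]],
    reference: Sequence[str],
    positive_label: str = "PJI",
) -> ConfusionCounts:
    """Response-level pooling across raters: sum of per-rater 2x2 tallies.

    Every rater must have scored the same vignette sequence (``reference``
    gives the per-vignette truth).  Each response counts as one observation,
    so 12 raters x 274 vignettes pool to n = 3288.
    """
    if not calls:
        raise ValueError("at least one rater's calls are required")
    total: Optional[ConfusionCounts] = None
    for rater_calls in calls:
        if len(rater_calls) != len(reference):
            raise ValueError(
                "mismatched vignette sets: every rater must score the same vignettes"
            )
        c = build_confusion(rater_calls, reference, positive_label)
        total = c if total is None else total + c
    return total


def indecision_rate(stage1_calls: Sequence[str]) -> float:
    """Fraction of Stage-I calls that are 'undecided'."""
    if len(stage1_calls) == 0:
        raise ValueError("stage1_calls must be non-empty")
    return sum(1 for c in stage1_calls if c == "undecided") / len(stage1_calls)
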