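"""Decision curve analysis for diagnostic strategies.

Net benefit at threshold probability ``pt`` follows the Vickers-Elkin
framework: NB = tp/n - (fp/n) * pt/(1-pt).  The module evaluates net-benefit
curves for fixed-call strategies (a binary call held constant across the
grid, pooled over raters when several scored the same cases) and for
continuous 0-100 probability scores (either binarized once at the clinical
cutoff, the default, or re-thresholded at each grid point), together with
treat-all / treat-none references, bootstrap intervals on net-benefit
improvement, the economically derived threshold pt* = C_FP/(C_FP + C_FN),
and the interventions-avoided conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .agreement import ConfusionCounts, build_confusion

__all__ = [
    "FixedCallStrategy",
    "ScoreStrategy",
    "NetBenefitCurve",
    "ThresholdDerivation",
    "ImprovementEstimate",
    "default_grid",
    "net_benefit",
    "decision_curve",
    "nb_improvement",
    "economic_threshold",
    "interventions_avoided_per100",
]


def default_grid() -> np.ndarray:
    return np.round(np.arange(0.01, 1.00, 0.01), 2)


def _check_pt(pt: float) -> float:
    if not (0.0 < pt < 1.0):
        raise ValueError(f"threshold probability must lie in (0, 1), got {pt!r}")
    return float(pt)


def net_benefit(c: ConfusionCounts, pt: float) -> float:
    """NB = tp/n - (fp/n) * pt/(1-pt); may be negative."""
    _check_pt(pt)
    return c.tp / c.n - (c.fp / c.n) * pt / (1.0 - pt)


@dataclass
class FixedCallStrategy:
    """Binary calls held constant across thresholds.

    ``calls`` is a 1-D sequence (one call per case) or a 2-D array of shape
    (raters, cases); 2-D calls are pooled at response level, so the
    strategy's curve equals the response-weighted mean of the per-rater
    curves.
    """

    name: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.atleast_2d(np.asarray(self.calls, dtype=object))

    @property
    def n_cases(self) -> int:
        return self.calls.shape[1]

    def confusion(self, truth: Sequence[str], idx: Optional[np.ndarray] = None) -> ConfusionCounts:
        truth = np.asarray(truth, dtype=object)
        calls = self.calls
        if idx is not None:
            truth = truth[idx]
            calls = calls[:, idx]
        pooled_calls = [str(c) for row in calls for c in row]
        pooled_truth = [str(t) for _ in range(calls.shape[0]) for t in truth]
        return build_confusion(pooled_calls, pooled_truth)

    def confusion_at(self, truth, pt: float, idx=None) -> ConfusionCounts:
        return self.confusion(truth, idx)


@dataclass
class ScoreStrategy:
    """A continuous 0-100 probability score.

    ``mode='fixed'`` (default) binarizes once at ``cutoff`` and holds the
    call constant across the grid; ``mode='threshold'`` classifies positive
    at score/100 >= pt at each grid point.
    """

    name: str
    scores: np.ndarray
    mode: str = "fixed"
    cutoff: float = 20.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.mode not in ("fixed", "threshold"):
            raise ValueError(f"mode must be 'fixed' or 'threshold', got {self.mode!r}")

    @property
    def n_cases(self) -> int:
        return len(self.scores)

    def confusion_at(self, truth, pt: float, idx=None) -> ConfusionCounts:
        truth = np.asarray(truth, dtype=object)
        scores = self.scores
        if idx is not None:
            truth = truth[idx]
            scores = scores[idx]
        if self.mode == "fixed":
            positive = scores >= self.cutoff
        else:
            positive = scores / 100.0 >= pt
        calls = np.where(positive, "PJI", "aseptic")
        return build_confusion([str(c) for c in calls], [str(t) for t in truth])


Strategy = Union[FixedCallStrategy, ScoreStrategy]


@dataclass
class NetBenefitCurve:
    """Net benefit per strategy over a grid of threshold probabilities,
    with treat-all and treat-none reference curves."""

    thresholds: np.ndarray
    values: Mapping[str, np.ndarray]
    n: int
    prevalence: float

    def at(self, name: str, pt: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - pt)))
        if abs(self.thresholds[i] - pt) > 1e-9:
            raise KeyError(f"threshold {pt} not on the grid")
        return float(self.values[name][i])


def decision_curve(
    strategies: Sequence[Strategy],
    truth: Sequence[str],
    grid: Optional[Sequence[float]] = None,
) -> NetBenefitCurve:
    """Evaluate net-benefit curves for the given strategies plus references.

    The treat-all reference uses the sample prevalence pi of ``truth``:
    NB = pi - (1-pi)*pt/(1-pt); treat-none is identically zero.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    for pt in grid:
        _check_pt(pt)
    truth = [str(t) for t in truth]
    n = len(truth)
    pi = sum(1 for t in truth if t == "PJI") / n

    values: dict[str, np.ndarray] = {}
    for strat in strategies:
        if strat.n_cases != n:
            raise ValueError(f"strategy {strat.name!r} does not cover the truth set")
        values[strat.name] = np.array(
            [net_benefit(strat.confusion_at(truth, pt), pt) for pt in grid]
        )
    values["treat_all"] = np.array([pi - (1 - pi) * pt / (1 - pt) for pt in grid])
    values["treat_none"] = np.zeros_like(grid)
    return NetBenefitCurve(thresholds=grid, values=values, n=n, prevalence=pi)


@dataclass(frozen=True)
class ImprovementEstimate:
    point: float
    ci_low: float
    ci_high: float
    pt: float
    B: int


def nb_improvement(
    a: Strategy,
    b: Strategy,
    truth: Sequence[str],
    pt: float,
    B: int = 2000,
    seed: Optional[int] = None,
    conf: float = 0.95,
) -> ImprovementEstimate:
    """Net-benefit improvement NB(a) - NB(b) at pt, with a percentile
    interval from joint case resampling (both strategies resampled on the
    same vignettes, preserving within-case correlation)."""
    _check_pt(pt)
    if B < 1:
        raise ValueError("B must be >= 1")
    truth_arr = np.asarray([str(t) for t in truth], dtype=object)
    n = len(truth_arr)
    if a.n_cases != n or b.n_cases != n:
        raise ValueError("both strategies must cover the same vignette set")

    def delta(idx: Optional[np.ndarray]) -> float:
        return net_benefit(a.confusion_at(truth_arr, pt, idx), pt) - net_benefit(
            b.confusion_at(truth_arr, pt, idx), pt
        )

    point = delta(None)
    rng = np.random.default_rng(seed)
    reps = np.array([delta(rng.integers(0, n, size=n)) for _ in range(B)])
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return ImprovementEstimate(point=point, ci_low=float(lo), ci_high=float(hi), pt=pt, B=B)


@dataclass(frozen=True)
class ThresholdDerivation:
    """Economically derived threshold probability pt* = c_fp/(c_fp + c_fn)."""

    c_fp: float
    c_fn: float
    pt_star: float


def economic_threshold(c_fp: float, c_fn: float) -> ThresholdDerivation:
    """Threshold at which expected treatment and no-treatment costs break even."""
    if c_fp <= 0 or c_fn <= 0:
        raise ValueError("both misdiagnosis costs must be positive")
    return ThresholdDerivation(c_fp=c_fp, c_fn=c_fn, pt_star=c_fp / (c_fp + c_fn))


def interventions_avoided_per100(
    delta_nb: float, pt: float, mode: str = "standard"
) -> float:
    """Convert a net-benefit improvement into interventions avoided per 100
    patients.

    ``standard`` is the Vickers-Elkin conversion delta_nb*(1-pt)/pt*100.
    ``alternate`` is the non-standard reversed ratio delta_nb*pt/(1-pt)*100,
    provided because some reports print that mapping; it is not the
    framework's conversion.
    """
    _check_pt(pt)
    if mode == "standard":
        return delta_nb * (1.0 - pt) / pt * 100.0
    if mode == "alternate":
        return delta_nb * pt / (1.0 - pt) * 100.0
    raise ValueError(f"mode must be 'standard' or 'alternate', got {mode!r}")
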