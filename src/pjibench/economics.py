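"""Decision-analytic misdiagnosis cost model.

For a hypothetical cohort of suspected-PJI cases, expected false-negative
and false-positive counts follow from the cohort composition and a
strategy's PPA/NPA:

    N_FN = round(N * prevalence * (1 - PPA))
    N_FP = round(N * (1 - prevalence) * (1 - NPA))

with rounding half away from zero, which reproduces printed tallies derived
from rounded agreement percentages.  A missed infection follows one of two
downstream pathways — a repeat diagnostic episode (default $1,000) or a
delayed two-stage septic revision after a failed aseptic revision (default
$123,750) — weighted equally by default, giving an expected false-negative
cost of $62,375 per case.  A false positive costs one unnecessary two-stage
septic revision (default $75,000).

Currency is held in integer cents internally so totals are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._util import check_fraction, round_half_away

__all__ = [
    "CostParameters",
    "EconomicResult",
    "expected_fn_cost",
    "misdiagnosis_cost",
    "compare_strategies",
    "monte_carlo_oracle",
]


def _cents(usd: float) -> int:
    return round_half_away(usd * 100.0)


@dataclass(frozen=True)
class CostParameters:
    """Unit costs (USD) and the false-negative pathway weight.

    ``pathway_weight`` is the probability a missed infection resolves via a
    repeat diagnostic work-up rather than delayed surgical management.
    """

    c_repeat_workup: float = 1_000.0
    c_delayed_surgical: float = 123_750.0
    pathway_weight: float = 0.5
    c_fp: float = 75_000.0

    def __post_init__(self) -> None:
        for name in ("c_repeat_workup", "c_delayed_surgical", "c_fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        check_fraction(self.pathway_weight, "pathway_weight")


def expected_fn_cost(p: CostParameters) -> float:
    """Scenario-weighted expected cost (USD) of one false-negative case."""
    cents = round_half_away(
        p.pathway_weight * _cents(p.c_repeat_workup)
        + (1.0 - p.pathway_weight) * _cents(p.c_delayed_surgical)
    )
    return cents / 100.0


@dataclass(frozen=True)
class EconomicResult:
    """Expected misdiagnosis counts and costs for one strategy on one cohort.

    ``n_fn_expected``/``n_fp_expected`` are the unrounded expectations;
    the integer counts (rounded half away from zero) drive the cost totals.
    """

    n_cohort: int
    n_pji: int
    n_aseptic: int
    n_fn: int
    n_fp: int
    n_fn_expected: float
    n_fp_expected: float
    c_fn_expected: float
    cost_fn_total: float
    cost_fp_total: float
    cost_total: float


def misdiagnosis_cost(
    n_cohort: int,
    prevalence: float,
    ppa: float,
    npa: float,
    p: Optional[CostParameters] = None,
) -> EconomicResult:
    """Expected misdiagnosis counts and costs for a strategy with the given
    PPA/NPA applied to a cohort of ``n_cohort`` suspected cases."""
    if p is None:
        p = CostParameters()
    if n_cohort < 1:
        raise ValueError("n_cohort must be >= 1")
    check_fraction(prevalence, "prevalence")
    check_fraction(ppa, "ppa")
    check_fraction(npa, "npa")

    n_pji = round_half_away(n_cohort * prevalence)
    n_aseptic = n_cohort - n_pji
    fn_expected = n_pji * (1.0 - ppa)
    fp_expected = n_aseptic * (1.0 - npa)
    n_fn = round_half_away(fn_expected)
    n_fp = round_half_away(fp_expected)

    c_fn = expected_fn_cost(p)
    cost_fn_cents = n_fn * _cents(c_fn)
    cost_fp_cents = n_fp * _cents(p.c_fp)
    return EconomicResult(
        n_cohort=n_cohort,
        n_pji=n_pji,
        n_aseptic=n_aseptic,
        n_fn=n_fn,
        n_fp=n_fp,
        n_fn_expected=fn_expected,
        n_fp_expected=fp_expected,
        c_fn_expected=c_fn,
        cost_fn_total=cost_fn_cents / 100.0,
        cost_fp_total=cost_fp_cents / 100.0,
        cost_total=(cost_fn_cents + cost_fp_cents) / 100.0,
    )


def compare_strategies(a: EconomicResult, b: EconomicResult) -> dict[str, float]:
    """Savings of strategy ``a`` over strategy ``b`` on the same cohort."""
    if a.n_cohort != b.n_cohort:
        raise ValueError("strategies were evaluated on different cohort sizes")
    savings = b.cost_total - a.cost_total
    return {
        "savings_total": savings,
        "savings_per_case": savings / a.n_cohort,
    }


def monte_carlo_oracle(
    n_cohort: int,
    prevalence: float,
    ppa: float,
    npa: float,
    p: Optional[CostParameters] = None,
    reps: int = 10_000,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Patient-level simulation oracle: replicate totals of misdiagnosis cost.

    Each replicate draws Bernoulli disease status per patient and Bernoulli
    test errors (miss probability 1-PPA on infected, false-call probability
    1-NPA on aseptic).  The mean over replicates converges to the unrounded
    closed-form expectation of :func:`misdiagnosis_cost`.
    """
    if p is None:
        p = CostParameters()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    check_fraction(prevalence, "prevalence")
    check_fraction(ppa, "ppa")
    check_fraction(npa, "npa")
    rng = np.random.default_rng(seed)
    n_pji = rng.binomial(n_cohort, prevalence, size=reps)
    n_fn = rng.binomial(n_pji, 1.0 - ppa)
    n_fp = rng.binomial(n_cohort - n_pji, 1.0 - npa)
    return n_fn * expected_fn_cost(p) + n_fp * p.c_fp
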