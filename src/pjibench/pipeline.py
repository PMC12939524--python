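"""End-to-end orchestration: cohort -> score -> agreement -> DCA -> economics.

``run_pipeline`` exercises the full benchmark on a synthetic vignette
cohort and emits Table-style report frames (indecision, agreement, decision
curve, economics), all deterministic under the configured seeds.
``reproduce_printed`` recomputes, from published summary counts only, the
headline agreement, decision-curve and economic numbers of the study this
package models.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    ConfusionCounts,
    build_confusion,
    gwet_ac1,
    indecision_rate,
    npa,
    opa,
    pool_calls,
    ppa,
    wilson_interval,
)
from .cohort import (
    CohortSpec,
    RaterCall,
    RaterProfile,
    Vignette,
    default_rater_profiles,
    generate_cohort,
    rater_calls_to_csv,
    simulate_raters,
    vignettes_to_csv,
)
from .dca import (
    FixedCallStrategy,
    ScoreStrategy,
    decision_curve,
    economic_threshold,
    nb_improvement,
    net_benefit,
)
from .economics import CostParameters, compare_strategies, misdiagnosis_cost
from .score import fit_surrogate, forced_call, score_vignettes, triage

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "reproduce_printed"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Seeds are split by purpose: ``cohort_seed`` fixes the study cohort,
    ``train_seed`` the surrogate training cohort and fit, ``rater_seed`` the
    simulated survey, ``bootstrap_seed`` all resampling.
    """

    n_cases: int = 274
    prevalence: float = 0.153
    n_train: int = 2000
    cohort_seed: int = 1
    train_seed: int = 2
    rater_seed: int = 3
    bootstrap_seed: int = 4
    bootstrap_B: int = 2000
    dca_grid_step: float = 0.05
    costs: CostParameters = field(default_factory=CostParameters)
    profiles: Sequence[RaterProfile] = field(default_factory=default_rater_profiles)
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.dca_grid_step < 1.0):
            raise ValueError("dca_grid_step must lie in (0, 1)")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        known = {
            "n_cases", "prevalence", "n_train", "cohort_seed", "train_seed",
            "rater_seed", "bootstrap_seed", "bootstrap_B", "dca_grid_step",
        }
        unknown = set(doc) - known - {"costs", "profiles", "outdir"}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = {k: doc[k] for k in known if k in doc}
        if "costs" in doc:
            kwargs["costs"] = CostParameters(**doc["costs"])
        if "profiles" in doc:
            kwargs["profiles"] = [RaterProfile(**p) for p in doc["profiles"]]
        if "outdir" in doc:
            kwargs["outdir"] = Path(doc["outdir"])
        return cls(**kwargs)

    def canonical_json(self) -> str:
        doc = {
            "n_cases": self.n_cases,
            "prevalence": self.prevalence,
            "n_train": self.n_train,
            "cohort_seed": self.cohort_seed,
            "train_seed": self.train_seed,
            "rater_seed": self.rater_seed,
            "bootstrap_seed": self.bootstrap_seed,
            "bootstrap_B": self.bootstrap_B,
            "dca_grid_step": self.dca_grid_step,
            "costs": vars(self.costs).copy(),
            "profiles": [vars(p).copy() for p in self.profiles],
        }
        return json.dumps(doc, sort_keys=True)


@dataclass
class ReportBundle:
    """All report tables of one run plus a provenance block."""

    indecision: pd.DataFrame
    agreement: pd.DataFrame
    dca: pd.DataFrame
    economics: pd.DataFrame
    provenance: Mapping[str, object]

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.indecision.to_csv(outdir / "indecision.csv", index=False)
        self.agreement.to_csv(outdir / "agreement.csv", index=False)
        self.dca.to_csv(outdir / "dca.csv", index=False)
        self.economics.to_csv(outdir / "economics.csv", index=False)
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(dict(self.provenance), fh, indent=1, sort_keys=True)


def _ac1_bootstrap_from_case_counts(
    case_counts: np.ndarray, B: int, rng: np.random.Generator, conf: float = 0.95
) -> tuple[float, float]:
    """Vignette-level percentile bootstrap of AC1.

    ``case_counts`` has one row per vignette: (tp, fp, fn, tn) summed over
    the strategy's responses on that vignette, so pooled statistics resample
    a vignette together with all raters' calls on it.
    """
    n = case_counts.shape[0]
    idx = rng.integers(0, n, size=(B, n))
    sums = case_counts[idx].sum(axis=1)  # (B, 4)
    values = []
    for tp, fp, fn, tn in sums:
        try:
            values.append(gwet_ac1(ConfusionCounts(int(tp), int(fp), int(fn), int(tn))))
        except ValueError:
            continue
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _case_counts(calls_rows: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-vignette (tp, fp, fn, tn) summed over raters (rows)."""
    n = len(truth)
    out = np.zeros((n, 4), dtype=int)
    pos = truth == "PJI"
    for row in calls_rows:
        called_pos = np.asarray(row, dtype=object) == "PJI"
        out[:, 0] += (called_pos & pos).astype(int)
        out[:, 1] += (called_pos & ~pos).astype(int)
        out[:, 2] += (~called_pos & pos).astype(int)
        out[:, 3] += (~called_pos & ~pos).astype(int)
    return out


def _agreement_row(
    name: str,
    calls_rows: np.ndarray,
    truth: np.ndarray,
    B: int,
    rng: np.random.Generator,
) -> dict[str, float | str | int]:
    pooled_calls = [str(c) for row in calls_rows for c in row]
    pooled_truth = [str(t) for _ in range(len(calls_rows)) for t in truth]
    c = build_confusion(pooled_calls, pooled_truth)
    opa_lo, opa_hi = wilson_interval(c.tp + c.tn, c.n)
    ppa_lo, ppa_hi = wilson_interval(c.tp, c.positives)
    npa_lo, npa_hi = wilson_interval(c.tn, c.negatives)
    ac1_lo, ac1_hi = _ac1_bootstrap_from_case_counts(
        _case_counts(calls_rows, truth), B, rng
    )
    return {
        "strategy": name,
        "n": c.n,
        "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
        "opa": opa(c), "opa_lo": opa_lo, "opa_hi": opa_hi,
        "ppa": ppa(c), "ppa_lo": ppa_lo, "ppa_hi": ppa_hi,
        "npa": npa(c), "npa_lo": npa_lo, "npa_hi": npa_hi,
        "ac1": gwet_ac1(c), "ac1_lo": ac1_lo, "ac1_hi": ac1_hi,
    }


_GROUP_LABELS = {
    "academic_surgeon": "academic_surgeons",
    "community_surgeon": "community_surgeons",
    "id_physician": "id_physicians",
}


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run the full benchmark on a synthetic cohort; see module docstring."""
    # 1. study cohort and surrogate training cohort
    cohort = generate_cohort(
        CohortSpec(n_cases=cfg.n_cases, prevalence=cfg.prevalence, rng_seed=cfg.cohort_seed)
    )
    training = generate_cohort(
        CohortSpec(n_cases=cfg.n_train, prevalence=cfg.prevalence, rng_seed=cfg.train_seed)
    )
    truth = np.array([v.clinical_dx for v in cohort], dtype=object)

    # 2. fit and apply the surrogate score
    model = fit_surrogate(training, seed=cfg.train_seed)
    scores = score_vignettes(model, cohort)
    score_df = pd.DataFrame(
        {
            "id": [v.id for v in cohort],
            "score": scores,
            "triage": [triage(s) for s in scores],
            "forced_call": [forced_call(s) for s in scores],
        }
    )

    # 3. simulated survey
    calls = simulate_raters(cohort, cfg.profiles, seed=cfg.rater_seed)
    by_rater: dict[str, list[RaterCall]] = {}
    for call in calls:
        by_rater.setdefault(call.rater_id, []).append(call)
    rater_groups = {p.rater_id: p.group for p in cfg.profiles}

    # 4. Stage-I indecision table
    indecision_rows = []
    triage_stage1 = ["undecided" if t == "equivocal" else t for t in score_df["triage"]]
    score_stage1 = [
        {"low": "aseptic", "high": "PJI", "undecided": "undecided"}[t]
        for t in triage_stage1
    ]
    indecision_rows.append(_indecision_row("surrogate_score", score_stage1))
    all_stage1 = [c.stage1 for c in calls]
    indecision_rows.append(_indecision_row("all_physicians", all_stage1))
    for group, label in _GROUP_LABELS.items():
        gcalls = [c.stage1 for c in calls if c.group == group]
        if gcalls:
            indecision_rows.append(_indecision_row(label, gcalls))
    for rater_id, rcalls in by_rater.items():
        indecision_rows.append(_indecision_row(rater_id, [c.stage1 for c in rcalls]))
    indecision_df = pd.DataFrame(indecision_rows)

    # 5. agreement table (Stage-II / forced-call vs clinical reference)
    rng = np.random.default_rng(cfg.bootstrap_seed)
    forced = np.array(score_df["forced_call"], dtype=object)
    rows = [_agreement_row("surrogate_score", forced[None, :], truth, cfg.bootstrap_B, rng)]
    all_rows = np.array(
        [[c.stage2 for c in by_rater[r]] for r in by_rater], dtype=object
    )
    rows.append(_agreement_row("all_physicians", all_rows, truth, cfg.bootstrap_B, rng))
    for group, label in _GROUP_LABELS.items():
        grp = np.array(
            [[c.stage2 for c in by_rater[r]] for r in by_rater if rater_groups[r] == group],
            dtype=object,
        )
        if len(grp):
            rows.append(_agreement_row(label, grp, truth, cfg.bootstrap_B, rng))
    for rater_id in by_rater:
        rows.append(
            _agreement_row(
                rater_id,
                np.array([[c.stage2 for c in by_rater[rater_id]]], dtype=object),
                truth,
                cfg.bootstrap_B,
                rng,
            )
        )
    agreement_df = pd.DataFrame(rows)

    # 6. decision curve analysis
    score_strategy = ScoreStrategy("surrogate_score", scores, mode="fixed")
    phys_strategy = FixedCallStrategy("all_physicians", all_rows)
    grid = np.round(
        np.arange(cfg.dca_grid_step, 1.0, cfg.dca_grid_step), 10
    )
    grid = grid[(grid > 0) & (grid < 1)]
    curve = decision_curve([score_strategy, phys_strategy], list(truth), grid)
    dca_rows = [
        {"strategy": name, "pt": float(pt), "net_benefit": float(nb)}
        for name, series in curve.values.items()
        for pt, nb in zip(curve.thresholds, series)
    ]
    pt_star = economic_threshold(
        cfg.costs.c_fp,
        _expected_fn(cfg.costs),
    ).pt_star
    imp = nb_improvement(
        score_strategy, phys_strategy, list(truth), round(pt_star, 2),
        B=cfg.bootstrap_B, seed=cfg.bootstrap_seed,
    )
    dca_df = pd.DataFrame(dca_rows)

    # 7. economics from realized agreement (printed-precision inputs)
    srow = agreement_df.loc[agreement_df["strategy"] == "surrogate_score"].iloc[0]
    prow = agreement_df.loc[agreement_df["strategy"] == "all_physicians"].iloc[0]
    prev = float((truth == "PJI").mean())
    res_score = misdiagnosis_cost(
        1000, round(prev, 3), round(srow["ppa"], 3), round(srow["npa"], 3), cfg.costs
    )
    res_phys = misdiagnosis_cost(
        1000, round(prev, 3), round(prow["ppa"], 3), round(prow["npa"], 3), cfg.costs
    )
    comp = compare_strategies(res_score, res_phys)
    econ_df = pd.DataFrame(
        [
            {"strategy": "surrogate_score", **vars(res_score)},
            {"strategy": "all_physicians", **vars(res_phys)},
        ]
    )
    econ_df["savings_total"] = [comp["savings_total"], -comp["savings_total"]]
    econ_df["savings_per_case"] = [comp["savings_per_case"], -comp["savings_per_case"]]

    provenance = {
        "version": __version__,
        "config_sha256": hashlib.sha256(cfg.canonical_json().encode()).hexdigest(),
        "seeds": {
            "cohort": cfg.cohort_seed,
            "train": cfg.train_seed,
            "rater": cfg.rater_seed,
            "bootstrap": cfg.bootstrap_seed,
        },
        "pt_star": pt_star,
        "nb_improvement_at_pt_star": {
            "point": imp.point, "ci_low": imp.ci_low, "ci_high": imp.ci_high,
        },
        "equivocal_fraction": float(np.mean(score_df["triage"] == "equivocal")),
    }

    bundle = ReportBundle(
        indecision=indecision_df,
        agreement=agreement_df,
        dca=dca_df,
        economics=econ_df,
        provenance=provenance,
    )
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vignettes_to_csv(cohort, outdir / "vignettes.csv")
        score_df.to_csv(outdir / "scores.csv", index=False)
        rater_calls_to_csv(calls, outdir / "rater_calls.csv")
        model.save(outdir / "score_model.json")
        bundle.write(outdir)
    return bundle


def _expected_fn(costs: CostParameters) -> float:
    from .economics import expected_fn_cost

    return expected_fn_cost(costs)


def _indecision_row(name: str, stage1: Sequence[str]) -> dict[str, object]:
    n = len(stage1)
    n_pji = sum(1 for c in stage1 if c == "PJI")
    n_aseptic = sum(1 for c in stage1 if c == "aseptic")
    n_und = sum(1 for c in stage1 if c == "undecided")
    return {
        "strategy": name,
        "n": n,
        "pji": n_pji,
        "aseptic": n_aseptic,
        "undecided": n_und,
        "indecision_rate": indecision_rate(stage1),
    }


# ---------------------------------------------------------------------------
# Printed-number reproduction (summary-count inputs only)

#: Confusion matrices implied by the published tallies: the score made 47
#: positive calls with 3 false negatives against 42/232 reference labels;
#: the 12 pooled physicians made 790 positive calls over 3288 responses with
#: 8 false negatives.
SCORE_CONFUSION = ConfusionCounts(tp=39, fp=8, fn=3, tn=224)
POOLED_PHYSICIAN_CONFUSION = ConfusionCounts(tp=496, fp=294, fn=8, tn=2490)


def _confusion_to_labels(c: ConfusionCounts) -> tuple[list[str], list[str]]:
    """Expand a 2x2 tally into a paired (call, reference) label sequence."""
    calls = ["PJI"] * c.tp + ["PJI"] * c.fp + ["aseptic"] * c.fn + ["aseptic"] * c.tn
    refs = ["PJI"] * c.tp + ["aseptic"] * c.fp + ["PJI"] * c.fn + ["aseptic"] * c.tn
    return calls, refs


def reproduce_printed(bootstrap_B: int = 2000, seed: int = 0) -> dict[str, object]:
    """Recompute the study's headline numbers from published counts only.

    Returns a dict with an agreement table (score and pooled-physician rows:
    OPA/PPA/NPA with Wilson CIs, AC1 with a vignette-level bootstrap CI),
    the economic quantities (expected FN cost, pt*, FN/FP counts and totals
    for both strategies, savings), and the closed-form net-benefit
    improvement at pt*.  Percentages are formatted to one decimal and
    coefficients to two, with raw values co-emitted.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, c in (
        ("surrogate_score", SCORE_CONFUSION),
        ("all_physicians", POOLED_PHYSICIAN_CONFUSION),
    ):
        opa_lo, opa_hi = wilson_interval(c.tp + c.tn, c.n)
        ppa_lo, ppa_hi = wilson_interval(c.tp, c.positives)
        npa_lo, npa_hi = wilson_interval(c.tn, c.negatives)
        case_counts = np.array(
            [[1, 0, 0, 0]] * c.tp + [[0, 1, 0, 0]] * c.fp
            + [[0, 0, 1, 0]] * c.fn + [[0, 0, 0, 1]] * c.tn
        )
        ac1_lo, ac1_hi = _ac1_bootstrap_from_case_counts(case_counts, bootstrap_B, rng)
        rows.append(
            {
                "strategy": name, "n": c.n,
                "opa": opa(c), "opa_lo": opa_lo, "opa_hi": opa_hi,
                "ppa": ppa(c), "ppa_lo": ppa_lo, "ppa_hi": ppa_hi,
                "npa": npa(c), "npa_lo": npa_lo, "npa_hi": npa_hi,
                "ac1": gwet_ac1(c), "ac1_lo": ac1_lo, "ac1_hi": ac1_hi,
                "display_opa": _pct3(opa(c), opa_lo, opa_hi),
                "display_ppa": _pct3(ppa(c), ppa_lo, ppa_hi),
                "display_npa": _pct3(npa(c), npa_lo, npa_hi),
                "display_ac1": f"{gwet_ac1(c):.2f} ({ac1_lo:.2f}, {ac1_hi:.2f})",
            }
        )
    agreement_df = pd.DataFrame(rows)

    costs = CostParameters()
    from .economics import expected_fn_cost

    c_fn = expected_fn_cost(costs)
    deriv = economic_threshold(costs.c_fp, c_fn)
    res_score = misdiagnosis_cost(1000, 0.153, 0.929, 0.966, costs)
    res_phys = misdiagnosis_cost(1000, 0.153, 0.984, 0.894, costs)
    comp = compare_strategies(res_score, res_phys)

    pt = round(deriv.pt_star, 2)
    improvement = net_benefit(SCORE_CONFUSION, pt) - net_benefit(
        POOLED_PHYSICIAN_CONFUSION, pt
    )

    return {
        "agreement": agreement_df,
        "expected_fn_cost": c_fn,
        "pt_star": deriv.pt_star,
        "pt_star_rounded": pt,
        "economics": {
            "surrogate_score": res_score,
            "all_physicians": res_phys,
            "savings_total": comp["savings_total"],
            "savings_per_case": comp["savings_per_case"],
            "savings_per_case_nearest_1000": round_to(comp["savings_per_case"], 1000),
        },
        "nb_improvement_at_pt_star": improvement,
    }


def _pct3(point: float, lo: float, hi: float) -> str:
    return f"{100 * point:.1f} ({100 * lo:.1f}, {100 * hi:.1f})"


def round_to(x: float, base: float) -> float:
    return base * round(x / base)
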