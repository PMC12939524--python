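# Methods

This note documents the models and procedures implemented in `pjibench`,
their assumptions and default parameters, and the design choices made where
several reasonable options existed.

## Problem setting

Diagnosing periprosthetic joint infection (PJI) after hip or knee
replacement is hardest in borderline, frequently culture-negative cases.
The package benchmarks two diagnostic strategies against an adjudicated
binary clinical reference ("PJI" / "aseptic"): a continuous 0–100
probability score computed from 11 synovial-fluid (SF) biomarkers, and
physician judgement elicited in a two-stage survey (Stage I allows
"undecided"; Stage II forces a definitive call). Four analysis layers sit
on top: agreement statistics, indecision rates, decision curve analysis,
and a misdiagnosis cost model.

## Synthetic cohort generator

The generator emulates the *statistical structure the analyses assume*, not
any real patient population.

**Composition is deterministic.** A cohort of `n` cases at prevalence `π`
contains exactly `round(n·π)` infected cases (rounding half away from
zero), so tallies derived from printed prevalences (e.g. 42/232 at n=274,
π=0.153) reproduce for every seed. A second deterministic-count subgroup of
"borderline" cases (default 10.9% of the cohort) is drawn from clinically
aseptic joints whose inflammation markers sit in the intermediate
2018-ICM band; these are always culture-negative, matching the reported
inconclusive subset.

**Marker distributions.** Class-conditional defaults: log-normal for
SF-WBC, SF-RBC and CRP; scaled beta for SF-PMN%; a low mode near 0.2 for
aseptic alpha-defensin versus a mode of 3 for septic (the score's
signal-to-cutoff convention puts the decision region near 1); antigen
signals are baseline log-normal noise with a per-pathogen Bernoulli spike
(×20) in septic cases. Borderline parameters were chosen from the ICM band
arithmetic: SF-WBC median 6000 (clears the 3000 cells/µL minor criterion,
3 points) and CRP median 20 mg/L (clears 10 mg/L, 2 points) put most
borderline cases at 3–5 points, inside the default 2–5 inconclusive band,
while alpha-defensin and PMN% stay sub-threshold. All parameters live in
`CohortSpec.class_distributions`; none are hard-coded as "truth".

**Missingness** is independent per biomarker with probability
`1 − availability`, using the study's published availability fractions as
defaults (AD 99.6%, SF-WBC 97.8%, SF-PMN% 96.7%, SF-RBC 63.5%, CRP 86.9%;
A280 and the five antigen assays never measured). Joint missingness
patterns (e.g. the fraction of cases with all four main markers) are an
emergent statistic, not a constraint, because only marginal availability is
published.

**Culture.** Septic cases are culture-positive with configurable
sensitivity (default 0.70); aseptic cases are culture-negative (a small
fraction, default 3%, not done); borderline cases are forced
culture-negative.

**CRP units.** Published CRP values appear without units and are not
mutually consistent across tables; panels therefore carry an explicit
`crp_unit` tag, the generator declares mg/L and never mixes units, and the
published imputation constant (1.7) is carried verbatim.

**Random streams** are split per purpose (labels, biomarkers, missingness,
misc) via `numpy` seed sequences, so adding raters or changing missingness
never perturbs the biomarker draws.

### 2018-ICM classification

The ternary classification is driven by a configurable rule table because
the consensus thresholds and weights are defined in external references and
institutions adapt them. Defaults use standard preoperative minor criteria
— SF-WBC > 3000 cells/µL (3 points), alpha-defensin ≥ 1 S/CO (3), SF-PMN% >
80% (2), CRP > 10 mg/L (2) — with a positive SF culture as a major
criterion and bands ≥6 infected / 2–5 inconclusive / ≤1 aseptic. Missing
markers contribute no points.

### Simulated physician survey

Each rater profile carries Stage-I indecision rates (one for
ICM-inconclusive vignettes, one for the rest) and Stage-II PPA/NPA targets.
Stage-II calls realize the targets by **exact error counts**:
`round(n_pos·(1−PPA))` misses and `round(n_neg·(1−NPA))` false calls at
uniformly random positions, rather than per-call Bernoulli draws. This
extends the generator's deterministic-composition philosophy to the rater
layer: realized agreement equals the target up to count rounding for every
seed, which is what a calibration benchmark needs (parameter recovery
should fail only if the simulator or the estimator is wrong, not because
three independent 95% checks jointly fail ~14% of the time). Stage-I
undecided calls are likewise exact-count; decided Stage-I calls always
equal Stage II, so stage consistency holds by construction.

The twelve built-in profiles carry the published per-rater overall
indecision rates and PPA/NPA values, with group-level indecision rates on
the inconclusive subset (38.3% academic surgeons, 48.3% community surgeons,
47.5% infectious-disease physicians). Because the stored overall rate mixes
both subsets, the non-inconclusive rate is back-solved as
`(r_overall − f·r_inc)/(1 − f)` for inconclusive fraction `f` (default
0.109; pass the realized cohort fraction for exact pooled recovery).

## Surrogate probability score

The surrogate mirrors the deployed score's architecture at desk scale; it
is **not** that model, and its only contract is architectural fidelity
(two-stage, culture-free, bounded 0–100 output) plus strong discrimination
on its own synthetic training distribution.

1. **Imputation** replaces each missing biomarker with a published constant
   (raw scale, applied before scaling — this reproduces the published
   imputation values exactly). When enabled and available, a serum CRP
   value substitutes for a missing SF-CRP instead of the constant.
2. **Scaling**: log10(x+1) on counts and concentrations (SF-WBC, SF-RBC,
   CRP), identity on percentages and signal ratios, then standardization to
   training mean/SD. The exact transforms of the deployed model are
   undisclosed; these defaults are configurable.
3. **Stage 1** fits a full-covariance Gaussian mixture (default k=2,
   septic/aseptic interpretation) on scaled features, ignoring labels.
4. **Stage 2** fits a logistic regression from the concatenation of mixture
   responsibilities and scaled features to the clinical labels; the
   predicted probability ×100 is the score. Responsibilities alone carry
   the cluster structure; including the scaled features lets the logistic
   stage sharpen the boundary, and the fit remains deterministic under a
   fixed seed.

Models serialize to JSON (scaling, mixture, logistic parameters, threshold
config, version) and scoring uses only the stored parameters, so a model
round-trips exactly through its file form.

**Thresholds.** Triage: low = [0,20), equivocal = [20,80), high =
[80,100] — the published wording gives both "scores ≥ 80 high" and
"intermediate 20–80", resolved here in favour of the explicit "≥ 80".
Forced call: PJI iff score ≥ 20, making `forced_call(s) == "PJI"` exactly
equivalent to `triage(s) != "low"`.

On the default synthetic distributions the surrogate reaches held-out AUC
≈ 0.999 with an equivocal-zone occupancy of ~1%, and the three published
false-negative edge cases (very low SF-WBC with raised alpha-defensin;
CRP-dominated presentation; high SF-RBC suggesting blood contamination)
all score below 20. These are properties of the fitted default
configuration, verified by test, not guarantees for arbitrary configs.

## Agreement statistics

OPA, PPA and NPA are the accuracy / sensitivity / specificity analogues
against an imperfect reference. Wilson score intervals (via
`statsmodels`) accompany all three. Gwet's AC1 uses
`pe = 2π̄(1−π̄)` with π̄ the mean of the two marginal positive proportions;
for the general multi-category form used as a test oracle,
`pe = Σ_q π̄_q(1−π̄_q)/(Q−1)`.

**Pooling** is response-level by default (sum of per-rater 2×2 tallies;
12 raters × 274 vignettes → n = 3288), which reproduces published pooled
values; per-rater averaging is equivalent for OPA when raters share a
vignette set (a tested identity).

**Bootstrap** intervals are percentile with B = 2000 by default. The
resampling unit is the vignette for single strategies and the vignette
*jointly with all raters' calls on it* for pooled statistics, preserving
within-case correlation; resampling responses independently would
understate the variance. Replicates where a statistic is undefined are
skipped and counted; more than 50% skipped aborts.

## Decision curve analysis

`NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)`; treat-all uses the sample
prevalence, treat-none is identically zero. The score strategy's default
mode holds the forced call at cutoff 20 **fixed** across thresholds: the
published improvement at the economic threshold is consistent with this
reading and not with re-thresholding the continuous score, so fixed-call
is the default and score-threshold mode is available by flag. The
economically derived threshold is `p_t* = C_FP/(C_FP + C_FN)` = 75,000 /
137,375 ≈ 0.55 under default costs. Improvement CIs come from joint
vignette resampling. Both interventions-avoided conversions are exposed:
the standard `Δ·(1−p_t)/p_t·100` (default) and the reversed
`Δ·p_t/(1−p_t)·100` (labelled non-standard; some reports print this
mapping). Net benefit carries no test-harm term.

## Misdiagnosis cost model

Counts: `N_FN = round(N·π·(1−PPA))`, `N_FP = round(N·(1−π)·(1−NPA))`,
rounding half away from zero — the rule that reproduces every published
count from the published (rounded) agreement inputs; unrounded
expectations are co-reported. Default costs: repeat diagnostic work-up
$1,000, delayed surgical management $123,750, pathway weight 0.5 (expected
FN cost $62,375); false positive $75,000 (one unnecessary two-stage septic
revision). Currency is integer cents internally so totals are exact. The
Monte-Carlo oracle draws patient-level Bernoulli disease status and test
errors; its mean converges to the unrounded closed form (tested at 1%).

## Problem sizes and determinism

Default problem sizes used by the test-suite and pipeline: study cohort
n = 274, surrogate training n = 2000, held-out evaluation n = 1000,
availability calibration n = 5000, bootstrap B = 2000 (smaller in smoke
tests), Monte-Carlo 10,000 replicates, parameter recovery over 20 seeds.
These sizes keep every stochastic check's Monte-Carlo error well below its
assertion tolerance while the full suite runs in seconds. All randomness
flows through explicit integer seeds; identical configuration yields
byte-identical report files.

## What passing tests do and do not show

Synthetic cohorts match the published *marginal* structure (prevalence,
availability, indecision and agreement rates, the inconclusive-band
fraction) but use independent missingness and parametric class-conditional
distributions without real biomarker covariance; the surrogate's
near-perfect AUC reflects the configured class separation, not clinical
performance. Agreement, decision-curve and economic computations on
published summary counts are exact reproductions; everything that depends
on the withheld case-level study data (per-vignette scores, subgroup
breakdowns beyond printed rates) is exercised qualitatively on synthetic
data only.
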