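# pjibench

Benchmarking diagnostic strategies for suspected **periprosthetic joint
infection (PJI)** — a machine-learning probability score versus physician
standard of care — with agreement statistics, decision curve analysis, and a
decision-analytic misdiagnosis cost model, all exercisable end-to-end on
synthetic vignette cohorts so that no restricted clinical data are needed.

It is written for biostatisticians and outcomes researchers who want a
tested, reusable implementation of the full comparison pipeline:

- **Synthetic cohorts** (`pjibench.cohort`): vignette cohorts with an
  11-marker synovial-fluid biomarker panel (alpha-defensin, SF-WBC, SF-PMN%,
  SF-RBC, CRP, A280, five microbial antigen signals), realistic per-marker
  missingness, culture results, a binary adjudicated reference diagnosis,
  and a configurable 2018-ICM style ternary classification; plus a simulator
  of two-stage physician surveys (PJI / aseptic / undecided, then a forced
  definitive call) calibrated to published per-rater indecision and
  agreement rates.
- **Surrogate score** (`pjibench.score`): constant-value imputation of
  incomplete panels, a two-stage Gaussian-mixture → logistic-regression
  pipeline emitting a 0–100 probability of infection, 20/80 triage
  (low / equivocal / high) and the forced call at 20.
- **Agreement** (`pjibench.agreement`): overall / positive / negative
  percent agreement with Wilson score intervals, Gwet's AC1 with bootstrap
  intervals, response-level pooling across raters, indecision rates.
- **Decision curves** (`pjibench.dca`): net benefit
  `NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t)`, curves for fixed-call and
  score-threshold strategies with treat-all/treat-none references,
  net-benefit improvement with bootstrap CIs, the economically derived
  threshold `p_t* = C_FP/(C_FP + C_FN)`, and interventions avoided per 100
  patients.
- **Economics** (`pjibench.economics`): expected misdiagnosis counts
  `N_FN = round(N·π·(1−PPA))`, `N_FP = round(N·(1−π)·(1−NPA))`, a
  scenario-weighted false-negative cost, strategy comparison, and a
  patient-level Monte-Carlo oracle.

## Worked example

Gwet's AC1 corrects percent agreement for chance using the mean marginal
positive proportion π̄: `AC1 = (p_a − p_e)/(1 − p_e)` with
`p_e = 2π̄(1−π̄)`. From the two study confusion matrices
(score: TP=39, FP=8, FN=3, TN=224 against a 42 PJI / 232 aseptic reference;
pooled 12 physicians: TP=496, FP=294, FN=8, TN=2490):

```bash
$ pjibench reproduce-paper
       strategy       display_opa       display_ppa       display_npa       display_ac1
surrogate_score 96.0 (93.0, 97.7) 92.9 (81.0, 97.5) 96.6 (93.3, 98.2) 0.94 (0.91, 0.98)
 all_physicians 90.8 (89.8, 91.8) 98.4 (96.9, 99.2) 89.4 (88.2, 90.5) 0.87 (0.85, 0.88)
expected FN cost: $62,375
economic threshold pt*: 0.55
surrogate_score: 11 FN / 29 FP, total $2,861,125
all_physicians: 2 FN / 90 FP, total $6,874,750
savings: $4,013,625 total, $4,000 per suspected case
net-benefit improvement at pt*: 0.0651
```

Reading this: the score agrees with the adjudicated reference on 96.0% of
cases overall versus 90.8% for the pooled physicians; it trades some
positive agreement (92.9% vs 98.4%) for substantially higher negative
agreement (96.6% vs 89.4%) — i.e., far fewer over-calls of infection. At
the cost-derived threshold (where one avoidable $75,000 revision balances a
$62,375 expected missed-infection cost), its net benefit exceeds pooled
physician judgement by 0.065, and projecting both strategies onto 1000
suspected cases at 15.3% prevalence cuts misdiagnosis costs from $6.9M to
$2.9M, about $4,000 per suspected case.

The `examples/` directory holds one short narrative script per capability
(cohort generation, scoring, agreement, decision curves, economics, the
full pipeline); each prints what it computes and what the numbers mean.
The `pjibench` CLI exposes `simulate`, `score`, `agree`, `dca`, `econ`,
`run` and `reproduce-paper` subcommands over the same library.

## Limitations

The surrogate score is architecturally faithful (two-stage, culture-free,
0–100 output) but is **not** the deployed clinical model; it is fit to this
package's own synthetic distributions. Synthetic cohorts use independent
per-marker missingness and parametric class-conditional distributions, not
real biomarker covariance. See `docs/methods.md` for the full model
description, parameter defaults, and design rationale.
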