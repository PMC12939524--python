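"""Agreement statistics: OPA/PPA/NPA, Wilson, Gwet's AC1, pooling, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pjibench.agreement import (
    ConfusionCounts,
    bootstrap_interval,
    build_confusion,
    gwet_ac1,
    indecision_rate,
    npa,
    opa,
    pool_calls,
    ppa,
    wilson_interval,
)

SCORE = ConfusionCounts(39, 8, 3, 224)
POOLED = ConfusionCounts(496, 294, 8, 2490)


def brute_force_ac1(calls, refs):
    """Independent oracle: Gwet's general multi-category AC1 computed
    directly from the raw paired label sequence."""
    n = len(calls)
    categories = sorted(set(calls) | set(refs))
    q = len(categories)
    pa = sum(c == r for c, r in zip(calls, refs)) / n
    pe = 0.0
    for cat in categories:
        pi = (sum(c == cat for c in calls) / n + sum(r == cat for r in refs) / n) / 2
        pe += pi * (1 - pi) / (q - 1)
    return (pa - pe) / (1 - pe)


def counts_to_labels(c):
    calls = ["PJI"] * c.tp + ["PJI"] * c.fp + ["aseptic"] * c.fn + ["aseptic"] * c.tn
    refs = ["PJI"] * c.tp + ["aseptic"] * c.fp + ["PJI"] * c.fn + ["aseptic"] * c.tn
    return calls, refs


class TestBuildConfusion:
    def test_study_matrix_from_labels(self):
        calls, refs = counts_to_labels(SCORE)
        assert build_confusion(calls, refs) == SCORE

    def test_perfect_calls_no_errors(self):
        refs = ["PJI"] * 5 + ["aseptic"] * 7
        c = build_confusion(refs, refs)
        assert c.fp == c.fn == 0 and c.tp == 5 and c.tn == 7

    def test_undecided_rejected(self):
        with pytest.raises(ValueError, match="undecided"):
            build_confusion(["PJI", "undecided"], ["PJI", "aseptic"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_confusion(["PJI"], ["PJI", "aseptic"])


class TestPercentAgreement:
    def test_score_row_matches_published_rounding(self):
        assert round(100 * opa(SCORE), 1) == 96.0
        assert round(100 * ppa(SCORE), 1) == 92.9
        assert round(100 * npa(SCORE), 1) == 96.6

    def test_pooled_physician_opa(self):
        assert round(100 * opa(POOLED), 1) == 90.8

    def test_perfect_matrix_all_100(self):
        c = ConfusionCounts(4, 0, 0, 9)
        assert opa(c) == ppa(c) == npa(c) == 1.0

    def test_zero_denominator_signalled(self):
        with pytest.raises(ValueError, match="PPA"):
            ppa(ConfusionCounts(0, 3, 0, 5))
        with pytest.raises(ValueError, match="NPA"):
            npa(ConfusionCounts(2, 0, 1, 0))

    def test_opa_is_weighted_mix_of_ppa_npa(self):
        for c in (SCORE, POOLED, ConfusionCounts(3, 2, 1, 4)):
            w = c.positives / c.n
            assert opa(c) == pytest.approx(w * ppa(c) + (1 - w) * npa(c))


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [(263, 274, 93.0, 97.7), (39, 42, 81.0, 97.5), (224, 232, 93.3, 98.2)],
    )
    def test_published_intervals(self, k, n, lo, hi):
        w_lo, w_hi = wilson_interval(k, n)
        assert round(100 * w_lo, 1) == lo
        assert round(100 * w_hi, 1) == hi

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = wilson_interval(0, 30)
        assert lo == 0.0 and hi > 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(5, 3)
        with pytest.raises(ValueError):
            wilson_interval(0, 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=1, max_value=500), st.floats(min_value=0.0, max_value=1.0))
    def test_contains_point_estimate(self, n, frac):
        k = round(n * frac)
        lo, hi = wilson_interval(k, n)
        assert lo - 1e-12 <= k / n <= hi + 1e-12

    def test_width_shrinks_with_n_at_fixed_fraction(self):
        widths = []
        for n in (20, 80, 320, 1280):
            lo, hi = wilson_interval(int(0.75 * n), n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestGwetAc1:
    def test_published_values(self):
        assert round(gwet_ac1(SCORE), 2) == 0.94
        assert round(gwet_ac1(POOLED), 2) == 0.87

    def test_perfect_agreement_is_one(self):
        assert gwet_ac1(ConfusionCounts(10, 0, 0, 40)) == pytest.approx(1.0)

    def test_one_iff_no_errors(self):
        assert gwet_ac1(ConfusionCounts(10, 1, 0, 40)) < 1.0
        assert gwet_ac1(ConfusionCounts(10, 0, 2, 40)) < 1.0

    def test_label_swap_invariance(self):
        # swapping positive/negative for both raters maps (tp,fp,fn,tn)->(tn,fn,fp,tp)
        for c in (SCORE, POOLED, ConfusionCounts(3, 2, 1, 4)):
            swapped = ConfusionCounts(c.tn, c.fn, c.fp, c.tp)
            assert gwet_ac1(c) == pytest.approx(gwet_ac1(swapped))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            tp, fp, fn, tn = rng.integers(0, 20, size=4)
            if tp + fp + fn + tn == 0:
                continue
            c = ConfusionCounts(int(tp), int(fp), int(fn), int(tn))
            calls, refs = counts_to_labels(c)
            try:
                expected = brute_force_ac1(calls, refs)
            except ZeroDivisionError:
                continue
            assert gwet_ac1(c) == pytest.approx(expected)


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_interval(lambda d: float(np.mean(d)), [3.0] * 20, B=200, seed=0)
        assert lo == hi == 3.0

    def test_ac1_interval_matches_published(self):
        calls, refs = counts_to_labels(SCORE)
        data = list(zip(calls, refs))

        def stat(sample):
            return gwet_ac1(build_confusion([c for c, _ in sample], [r for _, r in sample]))

        lo, hi = bootstrap_interval(stat, data, B=2000, seed=1)
        assert lo == pytest.approx(0.91, abs=0.02)
        assert hi == pytest.approx(0.98, abs=0.02)

    def test_reproducible_under_seed(self):
        data = list(np.random.default_rng(0).normal(size=30))
        a = bootstrap_interval(lambda d: float(np.mean(d)), data, B=100, seed=7)
        b = bootstrap_interval(lambda d: float(np.mean(d)), data, B=100, seed=7)
        assert a == b

    def test_mostly_degenerate_resamples_fail(self):
        def stat(sample):
            raise ValueError("undefined")

        with pytest.raises(RuntimeError, match="bootstrap failed"):
            bootstrap_interval(stat, [1, 2, 3], B=50, seed=0)

    def test_coverage_of_percentile_interval(self):
        """95% bootstrap intervals for a binomial proportion cover the true p
        in about 95% of simulations."""
        rng = np.random.default_rng(3)
        p_true, n = 0.3, 100
        covered = 0
        sims = 300
        for _ in range(sims):
            data = (rng.random(n) < p_true).astype(float)
            lo, hi = bootstrap_interval(lambda d: float(np.mean(d)), list(data), B=200, seed=int(rng.integers(2**31)))
            covered += lo <= p_true <= hi
        assert abs(covered / sims - 0.95) < 0.04


class TestPooling:
    def test_twelve_raters_pool_to_3288(self):
        refs = ["PJI"] * 42 + ["aseptic"] * 232
        calls = [refs] * 12
        pooled = pool_calls(calls, refs)
        assert pooled.n == 3288

    def test_single_rater_identity(self):
        refs = ["PJI", "aseptic", "PJI"]
        calls = ["PJI", "PJI", "aseptic"]
        assert pool_calls([calls], refs) == build_confusion(calls, refs)

    def test_pooled_opa_is_response_weighted_mean(self):
        rng = np.random.default_rng(5)
        refs = ["PJI" if x < 0.2 else "aseptic" for x in rng.random(50)]
        calls = [
            ["PJI" if x < 0.25 else "aseptic" for x in rng.random(50)] for _ in range(4)
        ]
        pooled = pool_calls(calls, refs)
        per = [opa(build_confusion(c, refs)) for c in calls]
        assert opa(pooled) == pytest.approx(np.mean(per))

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            pool_calls([["PJI"], ["PJI", "aseptic"]], ["PJI"])


class TestIndecision:
    def test_published_pooled_rate(self):
        stage1 = ["undecided"] * 754 + ["PJI"] * 597 + ["aseptic"] * 1937
        assert round(100 * indecision_rate(stage1), 1) == 22.9

    def test_no_undecided_is_zero(self):
        assert indecision_rate(["PJI", "aseptic"]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            indecision_rate([])

    def test_inconclusive_subset_rate_recovery(self, study_cohort, rater_profiles):
        """Simulated academic surgeons reproduce the configured 38.3%
        indecision rate on the ICM-inconclusive subset within 3 binomial SD."""
        from pjibench.cohort import simulate_raters

        calls = simulate_raters(study_cohort, rater_profiles, seed=2)
        inc_ids = {v.id for v in study_cohort if v.icm_class == "inconclusive"}
        subset = [
            c.stage1 for c in calls
            if c.group == "academic_surgeon" and c.vignette_id in inc_ids
        ]
        rate = indecision_rate(subset)
        sd = np.sqrt(0.383 * 0.617 / len(subset))
        assert abs(rate - 0.383) <= 3 * sd
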