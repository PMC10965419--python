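"""Confusion summaries, averaging, the threshold sweep and best-score rows."""

import math

import numpy as np
import pytest

from ontoeval import (MetricRecord, best_scores, confusion_per_target,
                      default_tau_grid, pr_rc_f, ru_mi_s, sweep_thresholds)
from ontoeval.metrics import ThresholdConfusion, aggregate

from conftest import engine_evaluate, random_instance


def rows(truth_ids, pred_scores, order="ABCD"):
    truth = np.array([t in truth_ids for t in order])
    scores = np.array([pred_scores.get(t, 0.0) for t in order])
    return truth, scores


class TestConfusionPerTarget:
    def test_perfect_prediction(self):
        truth, scores = rows("ABD", {"A": 1, "B": 1, "D": 1})
        tp, fp, fn, flag = confusion_per_target(truth, scores, 0.5)
        assert (tp, fp, fn, flag) == (3, 0, 0, True)
        assert pr_rc_f(tp, fp, fn) == (1, 1, 1)

    def test_mixed_prediction_counts(self):
        truth, scores = rows("ABD", {"A": 1, "B": 1, "C": 1})
        assert confusion_per_target(truth, scores, 0.5)[:3] == (2, 1, 1)

    def test_ia_weighted_diamond_three_four_five(self):
        # T={A,B,D}, P={A,B,C}, IA = A:0 B:1 C:4 D:3 -> (1,4,3), s=5
        truth, scores = rows("ABD", {"A": 1, "B": 1, "C": 1})
        ia = np.array([0.0, 1.0, 4.0, 3.0])
        wtp, wfp, wfn, flag = confusion_per_target(truth, scores, 0.5, weights=ia)
        assert (wtp, wfp, wfn) == (1.0, 4.0, 3.0)
        ru, mi, s = ru_mi_s(wfn, wfp)
        assert (ru, mi, s) == (3.0, 4.0, 5.0)

    def test_root_exclusion_unflags_root_only_prediction(self):
        truth, scores = rows("AB", {"A": 0.9})
        tp, fp, fn, flag = confusion_per_target(
            truth, scores, 0.5, exclude_roots=True, roots={0})
        assert flag is False and tp == 0 and fn == 1

    def test_threshold_is_inclusive_by_default_strict_optional(self):
        truth, scores = rows("B", {"B": 0.5})
        assert confusion_per_target(truth, scores, 0.5)[3] is True
        assert confusion_per_target(truth, scores, 0.5, strict=True)[3] is False


class TestScalarMetrics:
    @pytest.mark.parametrize("conf,expected", [
        ((3, 0, 0), (1, 1, 1)),
        ((0, 0, 5), (0, 0, 0)),
        ((2, 1, 1), (2 / 3, 2 / 3, 2 / 3)),
        ((0, 0, 0), (0, 0, 0)),
    ])
    def test_pr_rc_f(self, conf, expected):
        assert pr_rc_f(*conf) == pytest.approx(expected)

    @pytest.mark.parametrize("fnfp,expected", [
        ((0, 0), (0, 0, 0)),
        ((3, 4), (3, 4, 5)),
        ((5, 0), (5, 0, 5)),
    ])
    def test_ru_mi_s(self, fnfp, expected):
        assert ru_mi_s(*fnfp) == pytest.approx(expected)


def conf_of(tp, fp, fn, flags, tau=0.1):
    return ThresholdConfusion(
        namespace="default", tau=tau,
        tp=np.array(tp, float), fp=np.array(fp, float),
        fn=np.array(fn, float), predicted_flag=np.array(flags, bool))


class TestAggregate:
    def test_single_target_macro_equals_micro(self):
        c = conf_of([2], [1], [1], [True])
        ma = aggregate(c, "macro", "cafa")
        mi = aggregate(c, "micro", "cafa")
        assert (ma.pr, ma.rc, ma.f) == pytest.approx((mi.pr, mi.rc, mi.f))

    def test_macro_average_of_two_covered_targets(self):
        # per-target (pr, rc) = (1,1) and (0.5,0.5) -> macro 0.75 each
        c = conf_of([2, 1], [0, 1], [0, 1], [True, True])
        rec = aggregate(c, "macro", "cafa")
        assert (rec.pr, rec.rc) == pytest.approx((0.75, 0.75))

    def test_cafa_norm_averages_precision_over_covered_only(self):
        c = conf_of([2, 0], [0, 0], [0, 2], [True, False])
        cafa = aggregate(c, "macro", "cafa")
        full = aggregate(c, "macro", "full")
        assert cafa.pr == 1.0        # over 1 covered target
        assert full.pr == 0.5        # over both ground-truth targets
        assert cafa.rc == full.rc == 0.5
        assert cafa.coverage == 0.5

    def test_nothing_predicted_yields_zero_precision_and_coverage(self):
        c = conf_of([0, 0], [0, 0], [2, 3], [False, False])
        rec = aggregate(c, "macro", "cafa")
        assert rec.pr == rec.rc == rec.f == rec.coverage == 0.0

    def test_record_invariants_f_and_s(self):
        c = conf_of([2, 1], [1, 1], [1, 2], [True, True])
        c.wtp, c.wfp, c.wfn = (np.array(x, float) for x in
                               ([1.5, 0.5], [2.0, 1.0], [0.5, 1.0]))
        rec = aggregate(c, "macro", "cafa")
        assert rec.f == pytest.approx(2 * rec.pr * rec.rc / (rec.pr + rec.rc))
        assert rec.s == pytest.approx(math.hypot(rec.ru, rec.mi))


class TestSweepThresholds:
    def test_default_grid_is_100_cutoffs(self):
        taus = default_tau_grid()
        assert len(taus) == 100
        assert taus[0] == 0.0 and taus[-1] == pytest.approx(0.99)
        assert np.allclose(np.diff(taus), 0.01)

    def test_one_record_per_tau_in_order(self):
        rng = np.random.default_rng(0)
        parents, truth, preds, _ = random_instance(rng, 15, 4)
        recs = engine_evaluate(parents, truth, preds, default_tau_grid())
        assert len(recs) == 100
        assert [r.tau for r in recs] == pytest.approx(list(default_tau_grid()))

    def test_coverage_at_zero_threshold(self):
        rng = np.random.default_rng(1)
        parents, truth, preds, _ = random_instance(rng, 15, 5)
        preds[sorted(preds)[0]] = {}  # one target with no predictions
        recs = engine_evaluate(parents, truth, preds, [0.0])
        predicted = sum(1 for t in truth if preds[t])
        assert recs[0].coverage == pytest.approx(predicted / len(truth))

    def test_recall_and_coverage_monotone_non_increasing_in_tau(self):
        rng = np.random.default_rng(2)
        parents, truth, preds, _ = random_instance(rng, 25, 8)
        recs = engine_evaluate(parents, truth, preds, default_tau_grid())
        rc = [r.rc for r in recs]
        cov = [r.coverage for r in recs]
        assert all(a >= b - 1e-15 for a, b in zip(rc, rc[1:]))
        assert all(a >= b - 1e-15 for a, b in zip(cov, cov[1:]))

    def test_unit_ia_reduces_weighted_to_unweighted(self):
        rng = np.random.default_rng(3)
        parents, truth, preds, _ = random_instance(rng, 20, 6)
        ones = {t: 1.0 for t in parents}
        recs = engine_evaluate(parents, truth, preds, default_tau_grid(11), ia=ones)
        for r in recs:
            assert (r.wpr, r.wrc, r.wf) == pytest.approx((r.pr, r.rc, r.f), abs=1e-14)

    def test_thread_blocks_equal_sequential_bitwise(self):
        rng = np.random.default_rng(4)
        parents, truth, preds, ia = random_instance(rng, 25, 8)
        seq = engine_evaluate(parents, truth, preds, default_tau_grid(), ia=ia)
        par = engine_evaluate(parents, truth, preds, default_tau_grid(), ia=ia,
                              n_blocks=4)
        assert seq == par  # frozen dataclass equality, field by field

    def test_triangle_bounds_on_s(self):
        rng = np.random.default_rng(5)
        parents, truth, preds, ia = random_instance(rng, 20, 6)
        recs = engine_evaluate(parents, truth, preds, default_tau_grid(11), ia=ia)
        for r in recs:
            assert 0 <= r.f <= 1
            assert max(r.ru, r.mi) - 1e-12 <= r.s <= r.ru + r.mi + 1e-12

    def test_empty_grid_fatal(self):
        rng = np.random.default_rng(6)
        parents, truth, preds, _ = random_instance(rng, 10, 3)
        with pytest.raises(ValueError, match="grid"):
            engine_evaluate(parents, truth, preds, [])


class TestBestScores:
    def mk(self, tau, f=0.0, s=None, wf=None):
        return MetricRecord(namespace="ns", tau=tau, n_targets=2, coverage=1,
                            pr=f, rc=f, f=f, s=s, ru=s, mi=0.0, wf=wf,
                            wpr=wf, wrc=wf)

    def test_fmax_is_max_over_grid(self):
        recs = [self.mk(0.0, f=0.2), self.mk(0.5, f=0.9), self.mk(0.9, f=0.4)]
        best = best_scores(recs)
        assert best["f"].f == 0.9 and best["f"].tau == 0.5

    def test_constant_f_ties_break_to_lowest_tau(self):
        recs = [self.mk(t, f=0.5) for t in (0.0, 0.3, 0.6)]
        assert best_scores(recs)["f"].tau == 0.0

    def test_smin_is_min_over_grid(self):
        recs = [self.mk(t, f=0.1, s=s, wf=0.1) for t, s in
                zip((0.0, 0.5, 0.9), (5.0, 3.0, 4.0))]
        best = best_scores(recs)
        assert best["s"].s == 3.0 and best["s"].tau == 0.5
        assert "wf" in best

    def test_no_ia_means_no_smin_entry(self):
        assert set(best_scores([self.mk(0.0, f=0.3)])) == {"f"}
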