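"""Metric formulas against independent oracles; fold planning; aggregation."""

import numpy as np
import pytest

import eafcn.evaluation as ev
from eafcn import (ConfusionCounts, MetricsReport, all_metrics, confusion, make_fold_plan,
                   metric_accuracy, metric_f1, metric_mcc, metric_sensitivity,
                   metric_specificity)
from conftest import make_record


class TestConfusion:
    def test_all_correct(self):
        labels = ["AD"] * 5 + ["NC"] * 5
        c = confusion(labels, labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_all_inverted(self):
        labels = ["AD"] * 5 + ["NC"] * 5
        preds = ["NC"] * 5 + ["AD"] * 5
        c = confusion(preds, labels)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 0, 5, 5)

    def test_random_fixture_matches_loop_oracle(self, rng):
        preds = rng.integers(0, 2, 20)
        labels = rng.integers(0, 2, 20)
        c = confusion(preds, labels)
        tp = tn = fp = fn = 0
        for p, y in zip(preds, labels):
            if y == 1 and p == 1:
                tp += 1
            elif y == 0 and p == 0:
                tn += 1
            elif y == 0 and p == 1:
                fp += 1
            else:
                fn += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 20

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetricFormulas:
    def test_perfect_classifier(self):
        c = ConfusionCounts(tp=5, tn=5, fp=0, fn=0)
        m = all_metrics(c)
        assert all(v == 1.0 for v in m.values())

    def test_balanced_random_mcc_zero(self):
        assert metric_mcc(ConfusionCounts(tp=5, tn=5, fp=5, fn=5)) == 0.0

    def test_hand_arithmetic_case(self):
        c = ConfusionCounts(tp=3, fn=1, tn=4, fp=2)
        assert metric_accuracy(c) == pytest.approx(7 / 10)
        assert metric_sensitivity(c) == pytest.approx(3 / 4)
        assert metric_specificity(c) == pytest.approx(4 / 6)
        assert metric_f1(c) == pytest.approx(6 / 9)
        expect = (3 * 4 - 2 * 1) / np.sqrt(5 * 4 * 6 * 5)
        assert metric_mcc(c) == pytest.approx(expect)

    def test_degenerate_denominators_zero(self):
        assert metric_sensitivity(ConfusionCounts(0, 5, 0, 0)) == 0.0
        assert metric_specificity(ConfusionCounts(5, 0, 0, 0)) == 0.0
        assert metric_f1(ConfusionCounts(0, 5, 0, 0)) == 0.0
        assert metric_mcc(ConfusionCounts(3, 0, 0, 2)) == 0.0

    def test_mcc_equals_pearson_on_random_tables(self):
        # equivalence oracle over 500 random confusion tables
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(500):
            tp, tn, fp, fn = rng.integers(0, 12, 4)
            if tp + tn + fp + fn < 2:
                continue
            preds = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
            labels = np.array([1] * (tp + fn) + [0] * (fp + tn))
            mcc = metric_mcc(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            if preds.std() == 0 or labels.std() == 0:
                assert mcc == 0.0
            else:
                assert mcc == pytest.approx(np.corrcoef(preds, labels)[0, 1], abs=1e-12)
                checked += 1
        assert checked > 300

    def test_f1_equals_harmonic_mean_of_precision_recall(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 12, 4))
            c = ConfusionCounts(tp, tn, fp, fn)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            expect = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert metric_f1(c) == pytest.approx(expect, abs=1e-12)


class TestFoldPlan:
    def _records(self, n_ad=10, n_nc=10):
        return ([make_record(f"a{i}", "AD") for i in range(n_ad)] +
                [make_record(f"n{i}", "NC") for i in range(n_nc)])

    def test_balanced_stratified_folds(self):
        plan = make_fold_plan(self._records(), seed=3)
        for f in range(5):
            ids = plan.fold_ids(f)
            assert sum(i.startswith("a") for i in ids) == 2
            assert sum(i.startswith("n") for i in ids) == 2

    def test_partition(self):
        recs = self._records(11, 13)
        plan = make_fold_plan(recs, seed=5)
        all_ids = [sid for f in range(5) for sid in plan.fold_ids(f)]
        assert sorted(all_ids) == sorted(r.subject_id for r in recs)

    def test_order_invariance(self):
        recs = self._records()
        a = make_fold_plan(recs, seed=8)
        b = make_fold_plan(list(reversed(recs)), seed=8)
        assert a == b

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="per class"):
            make_fold_plan(self._records(3, 10), seed=1)


class TestAggregation:
    def test_report_mean_sd_match_recomputation(self, rng):
        rep = MetricsReport()
        rows = [dict(zip(ev.METRIC_NAMES, rng.random(5))) for _ in range(7)]
        for r in rows:
            rep.add(r)
        for m in ev.METRIC_NAMES:
            vals = [r[m] for r in rows]
            assert rep.mean(m) == pytest.approx(np.mean(vals))
            assert rep.sd(m) == pytest.approx(np.std(vals, ddof=1))

    def test_report_frame_schema(self):
        rep = MetricsReport()
        rep.add(dict.fromkeys(ev.METRIC_NAMES, 1.0))
        df = ev.report_frame({"A": rep})
        assert set(df.columns) >= {"variant", "metric", "mean", "sd"}
        assert set(df["variant"]) == {"MLP-A"}


@pytest.fixture
def stub_cohort(rng):
    from eafcn import BrainVolume
    recs = ([make_record(f"a{i}", "AD") for i in range(10)] +
            [make_record(f"n{i}", "NC") for i in range(10)])
    return [(r, BrainVolume(rng.random((4, 4, 4)), r.subject_id, normalized=True))
            for r in recs]


def test_cross_validate_perfect_stub_all_ones(monkeypatch, stub_cohort):
    # a pipeline stub that predicts the true held-out labels exactly
    def fake_fold(cohort_by_id, train_ids, val_ids, test_ids, cfg, seed):
        per_mode = {}
        for mode in cfg.modes:
            yte = [cohort_by_id[i][0].label for i in test_ids]
            per_mode[mode] = (np.zeros((len(train_ids), 1)),
                              [cohort_by_id[i][0].label for i in train_ids],
                              np.zeros((len(val_ids), 1)),
                              [cohort_by_id[i][0].label for i in val_ids],
                              np.zeros((len(test_ids), 1)), yte)
        return None, [], None, None, None, per_mode

    monkeypatch.setattr(ev, "run_fold_pipeline", fake_fold)

    def fake_train(X, y, spec, cfg, Xv=None, yv=None):
        return object()

    # the evaluation order of cross_validate is fold-major, mode-minor:
    # stage the true test labels so the stub "predicts" them exactly
    labels_stack = []

    def fake_predict(clf, X):
        yte = labels_stack.pop(0)
        return np.array([1 if l == "AD" else 0 for l in yte]), np.zeros(len(X))

    monkeypatch.setattr(ev, "train_mlp", fake_train)
    monkeypatch.setattr(ev, "predict_mlp", fake_predict)

    plan = ev.make_fold_plan([r for r, _ in stub_cohort], seed=1,
                             repeats_fcn=1, repeats_mlp=1)
    cfg = ev.PipelineConfig(seed=0)
    # prefill the expected test labels in evaluation order
    for r in range(1):
        for f in range(plan.n_folds):
            ids = plan.fold_ids(f)
            yte = [dict((rec.subject_id, rec.label) for rec, _ in stub_cohort)[i] for i in ids]
            for _ in cfg.modes:
                labels_stack.append(yte)
    reports = ev.cross_validate(stub_cohort, cfg, plan)
    for mode in cfg.modes:
        for m in ev.METRIC_NAMES:
            assert reports[mode].mean(m) == 1.0
            assert reports[mode].sd(m) == 0.0


def test_cross_validate_coinflip_stub_mcc_near_zero(monkeypatch, stub_cohort):
    flip_rng = np.random.default_rng(17)

    def fake_fold(cohort_by_id, train_ids, val_ids, test_ids, cfg, seed):
        per_mode = {}
        for mode in cfg.modes:
            per_mode[mode] = (np.zeros((len(train_ids), 1)),
                              [cohort_by_id[i][0].label for i in train_ids],
                              np.zeros((len(val_ids), 1)),
                              [cohort_by_id[i][0].label for i in val_ids],
                              np.zeros((len(test_ids), 1)),
                              [cohort_by_id[i][0].label for i in test_ids])
        return None, [], None, None, None, per_mode

    monkeypatch.setattr(ev, "run_fold_pipeline", fake_fold)
    monkeypatch.setattr(ev, "train_mlp", lambda X, y, spec, cfg, *a, **k: object())
    monkeypatch.setattr(ev, "predict_mlp",
                        lambda clf, X: (flip_rng.integers(0, 2, len(X)), np.zeros(len(X))))
    plan = ev.make_fold_plan([r for r, _ in stub_cohort], seed=2,
                             repeats_fcn=3, repeats_mlp=1)
    reports = ev.cross_validate(stub_cohort, ev.PipelineConfig(seed=0, modes=("A",)), plan)
    vals = reports["A"].raw["mcc"]
    se = 1 / np.sqrt(4 * len(vals))        # per-fold MCC sd ~ 1/sqrt(n_test)
    assert abs(np.mean(vals)) < 3 * se + 0.05
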