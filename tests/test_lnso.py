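"""LNSO planning, balancing, metric aggregation, CIs, and the paired test."""

import numpy as np
import pytest
import scipy.stats

from dmdeeg.lnso import (make_lnso_plan, balance_epochs, run_protocol,
                         aggregate_metrics, confidence_interval, paired_ttest,
                         macro_total, round2, task_classes)


def _groups(n_ad=35, n_ftd=22, n_cn=27):
    g = {}
    for i in range(n_ad):
        g[f"A{i:02d}"] = "AD"
    for i in range(n_ftd):
        g[f"F{i:02d}"] = "FTD"
    for i in range(n_cn):
        g[f"C{i:02d}"] = "CN"
    return g


class TestPlan:
    def test_exact_division_partition_sizes(self):
        plan = make_lnso_plan(_groups(), seed=0)
        for batch in plan.batches:
            assert [len(p) for p in batch["AD"]] == [7, 7, 7, 7, 7]

    def test_remainder_goes_to_earliest_partitions(self):
        plan = make_lnso_plan(_groups(), seed=0)
        for batch in plan.batches:
            assert [len(p) for p in batch["CN"]] == [6, 6, 5, 5, 5]
            assert [len(p) for p in batch["FTD"]] == [5, 5, 4, 4, 4]

    def test_every_fold_subject_disjoint_and_tested_once_per_batch(self):
        plan = make_lnso_plan(_groups(), seed=1)
        all_subjects = set(_groups())
        for b in range(plan.n_batches):
            tested = []
            for f in range(plan.n_partitions):
                train, test = plan.fold_split(b, f)
                assert not set(train) & set(test)
                assert set(train) | set(test) == all_subjects
                tested.extend(test)
            assert sorted(tested) == sorted(all_subjects)

    def test_batches_differ(self):
        plan = make_lnso_plan(_groups(), seed=2)
        assert plan.batches[0] != plan.batches[1]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="need >= 5"):
            make_lnso_plan(_groups(n_cn=4))


def _features(groups, n_epochs=10):
    return {sid: {"group": grp,
                  "tensors": [(i, None) for i in range(n_epochs)]}
            for sid, grp in groups.items()}


class TestBalanceEpochs:
    def test_combined_task_halves_dementia_epochs(self):
        """35 AD + 22 FTD + 27 CN with 10 epochs each: balancing leaves
        (35+22)*5 = 285 dementia epochs against 27*10 = 270 CN epochs."""
        feats = balance_epochs(_features(_groups()), "(AD+FTD)/CN")
        n_dem = sum(len(e["tensors"]) for e in feats.values()
                    if e["group"] in ("AD", "FTD"))
        n_cn = sum(len(e["tensors"]) for e in feats.values()
                   if e["group"] == "CN")
        assert (n_dem, n_cn) == (285, 270)
        kept = next(e["tensors"] for e in feats.values() if e["group"] == "AD")
        assert [i for i, _ in kept] == [0, 2, 4, 6, 8]

    def test_binary_tasks_unchanged(self):
        feats = _features(_groups())
        assert balance_epochs(feats, "AD/CN") == feats

    def test_deterministic(self):
        a = balance_epochs(_features(_groups()), "(AD+FTD)/CN")
        b = balance_epochs(_features(_groups()), "(AD+FTD)/CN")
        assert a == b


class _StubModel:
    """Predicts class 0 always; lets protocol accounting run in milliseconds."""

    def __init__(self, cfg, seed=0):
        pass

    def fit(self, X, y, cfg):
        return {"loss": [0.0], "accuracy": [1.0]}

    def predict_proba(self, X):
        p = np.zeros((len(X), 2))
        p[:, 0] = 1.0
        return p


class TestRunProtocol:
    @pytest.fixture
    def stubbed(self, monkeypatch):
        import dmdeeg.nn
        monkeypatch.setattr(dmdeeg.nn, "CNN3D", _StubModel)

    def _tensor_features(self, groups, n_epochs=2):
        rng = np.random.default_rng(0)
        return {sid: {"group": grp,
                      "tensors": [(i, rng.random((50, 50, 12)))
                                  for i in range(n_epochs)]}
                for sid, grp in groups.items()}

    def test_confusion_total_equals_scored_epochs(self, stubbed):
        groups = _groups(n_ad=5, n_ftd=0, n_cn=5)
        feats = self._tensor_features(groups)
        plan = make_lnso_plan(groups, n_batches=1, seed=0)
        records = run_protocol(plan, feats, "AD/CN", n_repetitions=2,
                               batches=[0], folds=[0, 1])
        # 2 folds x 2 test subjects x 2 epochs x 2 repetitions
        assert len(records) == 16
        report = aggregate_metrics(records)
        assert report.confusion.sum() == 16

    def test_missing_features_abort_before_training(self, stubbed):
        groups = _groups(n_ad=5, n_ftd=0, n_cn=5)
        feats = self._tensor_features(groups)
        feats.pop("A03")
        plan = make_lnso_plan(groups, n_batches=1, seed=0)
        with pytest.raises(ValueError, match="A03"):
            run_protocol(plan, feats, "AD/CN", batches=[0], folds=[0])

    def test_full_protocol_run_count(self, stubbed):
        groups = _groups(n_ad=5, n_ftd=0, n_cn=5)
        feats = self._tensor_features(groups, n_epochs=1)
        plan = make_lnso_plan(groups, n_batches=5, seed=0)
        records = run_protocol(plan, feats, "AD/CN", n_repetitions=5)
        runs = {(r["batch"], r["fold"], r["repetition"]) for r in records}
        assert len(runs) == 125  # 5 batches x 5 folds x 5 repetitions


class TestAggregateMetrics:
    def _records(self, tp, fn, fp, tn):
        recs = []
        for y, p, n in [(0, 0, tp), (0, 1, fn), (1, 0, fp), (1, 1, tn)]:
            recs += [{"task": "AD/CN", "batch": 0, "fold": 0, "repetition": 0,
                      "subject_id": "s", "epoch_index": 0,
                      "y_true": y, "y_pred": p, "probs": [0.5, 0.5]}] * n
        return recs

    def test_perfect_classifier(self):
        report = aggregate_metrics(self._records(10, 0, 0, 10))
        assert report.accuracy == 100.0
        assert all(v == 100.0 for v in report.totals.values())

    def test_confusion_and_f1_harmonic(self):
        report = aggregate_metrics(self._records(6, 2, 3, 9))
        assert report.confusion.tolist() == [[6, 2], [3, 9]]
        prec = report.per_class["precision"]["AD"]
        rec = report.per_class["recall"]["AD"]
        expect_f1 = round2(2 * prec * rec / (prec + rec))
        assert report.per_class["f1"]["AD"] == pytest.approx(expect_f1, abs=0.01)

    def test_macro_identity_reproduces_published_totals(self):
        """Unweighted macro averaging of the published per-class cells yields
        each published 'Total' cell exactly, for all three tasks."""
        cases = [
            ([78.67, 68.79], 73.73), ([76.57, 71.33], 73.95),
            ([77.61, 70.04], 73.83),                      # AD vs CN
            ([83.53, 69.05], 76.29), ([76.81, 77.35], 77.08),
            ([80.03, 72.97], 76.50),                      # FTD vs CN
            ([62.77, 83.76], 73.27), ([78.55, 70.37], 74.46),
            ([69.78, 76.48], 73.13),                      # combined vs CN
        ]
        for cells, total in cases:
            assert macro_total(cells) == total

    def test_f1_from_published_precision_recall(self):
        assert round2(2 * 78.67 * 76.57 / (78.67 + 76.57)) == 77.61
        assert round2(2 * 68.79 * 71.33 / (68.79 + 71.33)) == 70.04


class TestConfidenceInterval:
    def test_published_batch_accuracies(self):
        """The five AD-vs-CN batch accuracies aggregate to mean 74.23, sample
        std 1.92, and t-based MoE 2.38."""
        mean, std, moe, lo, hi = confidence_interval(
            [72.15, 73.41, 77.28, 74.61, 73.69])
        assert (round2(mean), round2(std), round2(moe)) == (74.23, 1.92, 2.38)
        assert lo < mean < hi

    def test_zero_variance(self):
        mean, std, moe, lo, hi = confidence_interval([80.0, 80.0, 80.0])
        assert moe == 0.0 and lo == hi == mean == 80.0

    def test_matches_independent_t_interval(self, rng):
        vals = rng.normal(70, 3, size=5)
        mean, std, moe, lo, hi = confidence_interval(vals)
        ref_lo, ref_hi = scipy.stats.t.interval(
            0.95, len(vals) - 1, loc=vals.mean(),
            scale=vals.std(ddof=1) / np.sqrt(len(vals)))
        assert (lo, hi) == pytest.approx((ref_lo, ref_hi))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval([74.0])


class TestPairedTTest:
    def test_identical_vectors(self):
        t, df, p, d = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and d == 0.0 and df == 2

    def test_full_protocol_df(self):
        rng = np.random.default_rng(0)
        a = rng.normal(74, 2, 25)
        t, df, p, d = paired_ttest(a, a + rng.normal(1, 1, 25))
        assert df == 24

    def test_matches_hand_formula_on_toy(self):
        a = np.array([70.0, 72.0, 68.0, 75.0])
        b = np.array([68.0, 71.0, 69.0, 71.0])
        t, df, p, d = paired_ttest(a, b)
        diff = a - b
        t_ref = diff.mean() / (diff.std(ddof=1) / np.sqrt(4))
        assert t == pytest.approx(t_ref)
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1))
        assert p == pytest.approx(
            2 * scipy.stats.t.sf(abs(t_ref), 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_ttest([1.0, 2.0], [1.0])


def test_task_classes():
    mapping, classes = task_classes("(AD+FTD)/CN")
    assert classes == ["AD+FTD", "CN"]
    assert mapping["AD"] == mapping["FTD"] == "AD+FTD"
    with pytest.raises(ValueError, match="unknown task"):
        task_classes("AD/FTD")
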