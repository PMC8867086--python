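import numpy as np
import pytest

from hierfc import (
    LabelTable,
    SelectionConfig,
    build_feature_table,
    contribution_trace,
    lasso_select,
    metrics,
    nested_cv,
    top_edges,
    train_svm,
    ttest_filter,
)
from hierfc.errors import ValidationError
from hierfc.feature_hierarchy import FeatureTable
from hierfc.select_classify import CvResult, FoldRecord, predict


def _make_table(x, block=None):
    n = x.shape[1]
    return FeatureTable(
        subject_ids=[f"s{i}" for i in range(x.shape[0])],
        values=x,
        provenance=[{"block": "all", "col": j} for j in range(n)],
        block_slices={"all": (0, n)} if block is None else block,
    )


def _labels(y):
    return LabelTable(labels={f"s{i}": int(v) for i, v in enumerate(y)})


class TestTtestFilter:
    def test_constant_feature_excluded(self, rng):
        y = np.array([1] * 5 + [-1] * 5)
        x = np.column_stack([np.ones(10), y + 0.01 * rng.standard_normal(10)])
        kept = ttest_filter(x, y, 0.05)
        assert 0 not in kept and 1 in kept

    def test_label_like_feature_included(self, rng):
        y = np.array([1] * 6 + [-1] * 6)
        x = (y + 0.05 * rng.standard_normal(12)).reshape(-1, 1)
        assert list(ttest_filter(x, y, 0.05)) == [0]

    def test_threshold_one_keeps_all_testable(self, rng):
        y = np.array([1] * 5 + [-1] * 5)
        x = rng.standard_normal((10, 8))
        assert len(ttest_filter(x, y, 1.0)) == 8

    def test_monotone_in_threshold(self, rng):
        y = np.array([1] * 8 + [-1] * 8)
        x = rng.standard_normal((16, 30))
        prev: set = set()
        for p in [0.01, 0.05, 0.2, 0.5, 1.0]:
            cur = set(ttest_filter(x, y, p))
            assert prev <= cur
            prev = cur

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            ttest_filter(rng.standard_normal((4, 3)), np.ones(4), 0.05)


class TestLassoSelect:
    def test_large_lambda_empty_selection(self, rng):
        x = rng.standard_normal((20, 5))
        y = np.sign(rng.standard_normal(20))
        w, nz = lasso_select(x, y, lam=1e6)
        assert nz.size == 0 and np.all(w == 0)

    def test_lambda_zero_matches_normal_equations(self, rng):
        x = rng.standard_normal((30, 4))
        y = np.sign(rng.standard_normal(30))
        w, _ = lasso_select(x, y, lam=0.0)
        oracle = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_single_predictor_soft_threshold(self, rng):
        """One column: ŵ = S(xᵀy, λ) / xᵀx, the closed-form soft threshold."""
        x = rng.standard_normal((25, 1))
        y = np.sign(x[:, 0]) * 1.0
        lam = 0.5
        w, nz = lasso_select(x, y, lam)
        xty = float(x[:, 0] @ y)
        expected = np.sign(xty) * max(abs(xty) - lam, 0.0) / float(x[:, 0] @ x[:, 0])
        assert w[0] == pytest.approx(expected, rel=1e-5)
        assert list(nz) == [0] and w[0] > 0

    def test_support_nonincreasing_in_lambda(self, rng):
        x = rng.standard_normal((30, 12))
        beta = np.zeros(12)
        beta[:4] = [2.0, -1.5, 1.0, 0.5]
        y = x @ beta + 0.1 * rng.standard_normal(30)
        sizes = [lasso_select(x, y, lam)[1].size
                 for lam in [round(0.1 * i, 1) for i in range(1, 10)]]
        # support can only shrink (weakly) along the default grid
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestSvm:
    def test_separable_toy_zero_training_error(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        clf = train_svm(x, y, cost=1.0)
        np.testing.assert_array_equal(predict(clf, x), y)

    def test_label_flip_flips_predictions(self, rng):
        x = rng.standard_normal((20, 3))
        y = np.sign(x[:, 0] + 0.1 * rng.standard_normal(20)).astype(int)
        y[y == 0] = 1
        grid = rng.standard_normal((7, 3))
        a = predict(train_svm(x, y, 1.0), grid)
        b = predict(train_svm(x, -y, 1.0), grid)
        np.testing.assert_array_equal(a, -b)

    def test_empty_feature_fallback_majority(self):
        with pytest.warns(UserWarning, match="empty feature"):
            clf = train_svm(np.empty((5, 0)), np.array([1, 1, 1, -1, -1]), 1.0)
        np.testing.assert_array_equal(predict(clf, np.empty((3, 0))), [1, 1, 1])


class TestMetrics:
    def test_arithmetic(self):
        m = metrics(tp=8, fp=1, tn=9, fn=2)
        assert m["ACC"] == pytest.approx(0.85)
        assert m["TPR"] == pytest.approx(0.8)
        assert m["TNR"] == pytest.approx(0.9)

    def test_all_correct(self):
        m = metrics(tp=5, fp=0, tn=5, fn=0)
        assert all(m[k] == 1.0 for k in ["ACC", "TPR", "TNR", "PPV", "NPV"])

    def test_undefined_ppv_flagged(self):
        m = metrics(tp=0, fp=0, tn=5, fn=5)
        assert m["PPV"] is None and "PPV" in m["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            metrics(tp=-1, fp=0, tn=1, fn=0)


class _Audit:
    def __init__(self):
        self.records = []

    def record(self, stage, repeat, fold, rows):
        self.records.append((stage, repeat, fold, set(int(r) for r in rows)))


class TestNestedCv:
    @staticmethod
    def _cfg(**kw):
        base = dict(p_grid=[0.1, 0.5], lambda_grid=[0.2], cost_grid=[1.0],
                    outer_folds=4, inner_folds=3, repeats=1, seed=11)
        base.update(kw)
        return SelectionConfig(**base)

    def test_label_leak_gives_perfect_accuracy(self, rng):
        y = np.array([1, -1] * 12)
        x = np.column_stack([y.astype(float), rng.standard_normal((24, 5))])
        res = nested_cv(_make_table(x), _labels(y), self._cfg())
        assert res.summary["over_folds"]["ACC"]["mean"] == 1.0

    def test_same_seed_identical_result(self, rng):
        y = np.array([1, -1] * 12)
        x = rng.standard_normal((24, 10))
        a = nested_cv(_make_table(x), _labels(y), self._cfg())
        b = nested_cv(_make_table(x), _labels(y), self._cfg())
        assert a.to_json() == b.to_json()

    def test_no_leakage_into_any_fit(self, rng):
        """Every recorded training-row set is disjoint from its outer test."""
        y = np.array([1, -1] * 12)
        x = rng.standard_normal((24, 10))
        audit = _Audit()
        cfg = self._cfg(repeats=2)
        res = nested_cv(_make_table(x), _labels(y), cfg, audit=audit)
        outer_train = {(f.repeat, f.fold): rec for f in res.folds
                       for rec in [None]}
        # reconstruct outer test sets from the recorded outer_fit rows
        all_rows = set(range(24))
        outer_fit = {(r, f): rows for (stage, r, f, rows) in audit.records
                     if stage == "outer_fit"}
        assert len(outer_fit) == cfg.repeats * cfg.outer_folds
        for (stage, r, f, rows) in audit.records:
            test_rows = all_rows - outer_fit[(r, f)]
            assert rows.isdisjoint(test_rows), (stage, r, f)

    def test_too_few_subjects_per_class(self, rng):
        y = np.array([1] * 3 + [-1] * 10)
        x = rng.standard_normal((13, 4))
        with pytest.raises(ValidationError):
            nested_cv(_make_table(x), _labels(y), self._cfg())

    def test_null_features_near_chance(self, rng):
        """Labels independent of features: mean accuracy inside the 95%
        binomial band around 0.5 for n = 60 subjects."""
        n = 60
        y = np.array([1, -1] * (n // 2))
        x = rng.standard_normal((n, 40))
        cfg = SelectionConfig(p_grid=[0.1, 0.5], lambda_grid=[0.3],
                              cost_grid=[1.0], outer_folds=5, inner_folds=3,
                              repeats=20, seed=2)
        res = nested_cv(_make_table(x), _labels(y), cfg)
        half_width = 1.96 * np.sqrt(0.25 / n)
        acc = res.summary["over_repeats"]["ACC"]["mean"]
        assert 0.5 - half_width < acc < 0.5 + half_width


class TestTracing:
    @staticmethod
    def _result(selected_by_fold):
        folds = [
            FoldRecord(repeat=r, fold=f, metrics={}, params={}, selected_columns=cols)
            for (r, f), cols in selected_by_fold.items()
        ]
        cfg = SelectionConfig(p_grid=[0.1], lambda_grid=[0.1], cost_grid=[1.0])
        return CvResult(folds=folds, summary={}, config=cfg)

    def test_single_network_takes_all(self):
        prov = [{"block": "intra_low", "network": "DMN", "i": 1, "j": 0, "role": "mean"}]
        res = self._result({(0, 0): [0], (0, 1): [0]})
        rates = contribution_trace(res, prov, ["DMN", "SMN"])
        assert rates == {"DMN": 1.0, "SMN": 0.0}

    def test_two_intra_networks_split_evenly(self):
        prov = [
            {"block": "intra_low", "network": "A", "i": 1, "j": 0, "role": "mean"},
            {"block": "intra_low", "network": "B", "i": 3, "j": 2, "role": "mean"},
        ]
        res = self._result({(0, 0): [0, 1]})
        rates = contribution_trace(res, prov, ["A", "B"])
        assert rates["A"] == pytest.approx(0.5) and rates["B"] == pytest.approx(0.5)

    def test_inter_feature_credits_both_endpoints(self):
        prov = [{"block": "inter_low", "network_i": "A", "network_j": "B",
                 "role": "mean"}]
        res = self._result({(0, 0): [0]})
        rates = contribution_trace(res, prov, ["A", "B"])
        assert rates["A"] == pytest.approx(0.5) and rates["B"] == pytest.approx(0.5)

    def test_top_edges_frequency_and_cap(self):
        prov = [
            {"block": "intra_low", "network": "A", "i": 1, "j": 0, "role": "mean"},
            {"block": "intra_low", "network": "A", "i": 2, "j": 0, "role": "mean"},
            {"block": "intra_high", "network": "A", "i": 1, "j": 1, "role": "factor"},
        ]
        # ten repeats, edge 0 always selected, edge 1 in half, factor ignored
        sel = {(r, 0): ([0, 2] if r % 2 else [0, 1, 2]) for r in range(10)}
        res = self._result(sel)
        edges = top_edges(res, prov, n=10)
        assert len(edges) == 2
        assert edges[0]["column"] == 0 and edges[0]["frequency"] == 10
        assert edges[1]["frequency"] == 5
        assert all(e["frequency"] <= 10 for e in edges)

    def test_single_repeat_all_frequency_one_with_warning(self):
        prov = [
            {"block": "intra_low", "network": "A", "i": i + 1, "j": 0, "role": "mean"}
            for i in range(3)
        ]
        res = self._result({(0, 0): [0, 1, 2]})
        with pytest.warns(UserWarning, match="only 3"):
            edges = top_edges(res, prov, n=10)
        assert [e["frequency"] for e in edges] == [1, 1, 1]

    def test_tie_breaks_lexicographic(self):
        prov = [
            {"block": "intra_low", "network": "A", "i": 2, "j": 1, "role": "mean"},
            {"block": "intra_low", "network": "A", "i": 1, "j": 0, "role": "mean"},
        ]
        res = self._result({(0, 0): [0, 1]})
        edges = top_edges(res, prov, n=2, roi_names=["aa", "bb", "cc"])
        assert [e["roi_i"] for e in edges] == ["bb", "cc"]


class TestEndToEndPower:
    def test_effect_cohort_beats_null_band(self, small_cohort, small_partition,
                                           window30):
        """With a strong injected group effect in DMN the classifier must
        exceed chance and the contribution trace must rank DMN first."""
        _, subjects, labels, _ = small_cohort
        table = build_feature_table(subjects, small_partition, window30)
        cfg = SelectionConfig(p_grid=[0.1, 0.5], lambda_grid=[0.3], cost_grid=[1.0],
                              outer_folds=4, inner_folds=3, repeats=2, seed=5)
        res = nested_cv(table, labels, cfg)
        n = len(subjects)
        assert res.summary["over_repeats"]["ACC"]["mean"] > 0.5 + 1.96 * np.sqrt(0.25 / n)
        rates = contribution_trace(res, table.provenance, list(small_partition.networks))
        assert max(rates, key=rates.get) == "DMN"
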