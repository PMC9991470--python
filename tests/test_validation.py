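import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eggchem.validation import (
    ConfusionCounts,
    MCCVGrid,
    confusion,
    default_lssvm_grid,
    default_lv_grid,
    grid_search,
    mccv_error,
    mccv_splits,
    metrics,
)


class TestConfusion:
    def test_all_correct(self):
        y = [1] * 45 + [-1] * 41
        c = confusion(y, y)
        assert (c.tp, c.fn, c.tn, c.fp) == (45, 0, 41, 0)

    def test_all_wrong(self):
        y_true = np.array([1] * 45 + [-1] * 41)
        c = confusion(y_true, -y_true)
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 45, 0, 41)

    def test_mixed_counts(self):
        # 4 positives and 3 negatives misclassified out of 45 + 41
        y_true = np.array([1] * 45 + [-1] * 41)
        y_pred = y_true.copy()
        y_pred[:4] = -1
        y_pred[45:48] = 1
        c = confusion(y_true, y_pred)
        assert (c.tp, c.fn, c.tn, c.fp) == (41, 4, 38, 3)

    def test_string_labels(self):
        c = confusion(["free-range", "caged"], ["caged", "caged"])
        assert (c.tp, c.fn, c.tn, c.fp) == (0, 1, 1, 0)

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            confusion(["free-range"], ["organic"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            confusion([1, -1], [1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)


class TestMetrics:
    def test_plsda_printed_percentages(self):
        m = metrics(ConfusionCounts(tp=41, fn=4, tn=38, fp=3))
        assert m.sensitivity_pct == 91.1
        assert m.specificity_pct == 92.7
        assert m.accuracy_pct == 91.9

    def test_lssvm_printed_percentages(self):
        m = metrics(ConfusionCounts(tp=43, fn=2, tn=39, fp=2))
        assert m.sensitivity_pct == 95.6
        assert m.specificity_pct == 95.1
        assert m.accuracy_pct == 95.3

    def test_perfect(self):
        m = metrics(ConfusionCounts(tp=45, fn=0, tn=41, fp=0))
        assert m.sensitivity_pct == m.specificity_pct == m.accuracy_pct == 100.0

    def test_empty_class_undefined_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert m.sensitivity is None
        assert m.sensitivity_pct is None
        assert m.specificity == 0.75

    def test_half_up_rounding(self):
        # 1/8 = 12.5% exactly: half-up gives 12.5; 1/16 = 6.25 -> 6.3
        assert metrics(ConfusionCounts(1, 7, 1, 0)).sensitivity_pct == 12.5
        assert metrics(ConfusionCounts(1, 15, 1, 0)).sensitivity_pct == 6.3

    @given(
        tp=st.integers(0, 200),
        fn=st.integers(0, 200),
        tn=st.integers(0, 200),
        fp=st.integers(0, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_accuracy_identity(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = metrics(ConfusionCounts(tp, fn, tn, fp))
        P, N = tp + fn, tn + fp
        assert m.accuracy == pytest.approx(
            (m.sensitivity * P + m.specificity * N) / (P + N)
        )
        assert min(m.sensitivity, m.specificity) <= m.accuracy
        assert m.accuracy <= max(m.sensitivity, m.specificity)


class _ConstantPositive:
    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.ones(len(X), dtype=int)


class _SignOfFirstFeature:
    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.where(np.asarray(X)[:, 0] >= 0, 1, -1)


class TestMCCV:
    def test_splits_are_deterministic(self):
        y = np.array([1] * 20 + [-1] * 20)
        s1 = mccv_splits(y, n_splits=5, seed=3)
        s2 = mccv_splits(y, n_splits=5, seed=3)
        for (a, b), (c, d) in zip(s1, s2):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_stratified_sizes(self):
        y = np.array([1] * 30 + [-1] * 20)
        for train, val in mccv_splits(y, n_splits=10, train_frac=0.7, seed=1):
            # floor(0.3*30)=9 positives, floor(0.3*20)=6 negatives
            assert len(val) == 15
            assert np.sum(y[val] == 1) == 9
            assert set(y[train]) == {1, -1}

    def test_constant_classifier_balanced_error_half(self):
        y = np.array([1] * 30 + [-1] * 30)
        X = np.zeros((60, 2))
        err = mccv_error(_ConstantPositive, X, y, n_splits=50, seed=7)
        assert err == pytest.approx(0.5, abs=1e-12)  # stratified: exact

    def test_separable_error_zero(self):
        X = np.concatenate([np.ones(20), -np.ones(20)])[:, None]
        y = np.array([1] * 20 + [-1] * 20)
        err = mccv_error(_SignOfFirstFeature, X, y, n_splits=30, seed=2)
        assert err == 0.0

    def test_exhaustive_leave_3_out_oracle(self):
        """Unstratified MCCV with a fixed rule converges to the mean error
        over all C(10,3) validation subsets."""
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 2))
        y = np.where(rng.standard_normal(10) > 0, 1, -1)
        y[:2] = [1, -1]  # ensure both classes
        rule = _SignOfFirstFeature()
        point_err = (rule.predict(X) != y).astype(float)
        exhaustive = np.mean(
            [
                point_err[list(combo)].mean()
                for combo in itertools.combinations(range(10), 3)
            ]
        )
        err, per_split = mccv_error(
            _SignOfFirstFeature,
            X,
            y,
            n_splits=3000,
            seed=4,
            stratified=False,
            return_per_split=True,
        )
        se = per_split.std(ddof=1) / np.sqrt(len(per_split))
        assert abs(err - exhaustive) <= 3 * se + 1e-12

    def test_empty_validation_rejected(self):
        y = np.array([1, 1, -1, -1])
        with pytest.raises(ValueError, match="empty"):
            mccv_splits(y, n_splits=1, train_frac=0.9, seed=0)


class TestGridSearch:
    def test_single_candidate_selected(self):
        X = np.concatenate([np.ones(10), -np.ones(10)])[:, None]
        y = np.array([1] * 10 + [-1] * 10)
        grid = grid_search(
            lambda **kw: _SignOfFirstFeature(), X, y, [{"dummy": 1}],
            n_splits=10, seed=1,
        )
        assert grid.selected_params == {"dummy": 1}
        assert grid.min_error == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search(lambda **kw: _SignOfFirstFeature(), np.zeros((4, 1)),
                        np.array([1, 1, -1, -1]), [])

    def test_tie_prefers_earliest_candidate(self):
        X = np.concatenate([np.ones(10), -np.ones(10)])[:, None]
        y = np.array([1] * 10 + [-1] * 10)
        grid = grid_search(
            lambda **kw: _SignOfFirstFeature(), X, y,
            [{"a": 1}, {"a": 2}, {"a": 3}], n_splits=5, seed=0,
        )
        assert grid.selected_index == 0

    def test_noise_features_never_win(self):
        """Paired-split comparison: a model fed pure-noise features never
        beats the same model on the informative feature (20 seeds)."""

        class _FeatureRule:
            def __init__(self, col):
                self.col = col

            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.where(np.asarray(X)[:, self.col] >= 0, 1, -1)

        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.array([1] * 20 + [-1] * 20)
            signal = y + 0.3 * rng.standard_normal(n)
            noise = rng.standard_normal(n)
            X = np.column_stack([signal, noise])
            grid = grid_search(
                lambda col: _FeatureRule(col), X, y,
                [{"col": 0}, {"col": 1}], n_splits=30, seed=seed + 1,
            )
            assert grid.selected_params == {"col": 0}

    def test_default_grids_cover_reported_optima(self):
        lv = default_lv_grid()
        assert lv[0] == {"n_components": 1}
        assert {"n_components": 4} in lv
        svm = default_lssvm_grid()
        assert {"sigma2": 700.0, "gamma": 5.0} in svm
        # ordering encodes the tie rule: small gamma first, large sigma2 first
        assert svm[0] == {"sigma2": 3000.0, "gamma": 0.5}

    def test_grid_invariant_enforced(self):
        with pytest.raises(ValueError, match="minimum"):
            MCCVGrid(
                candidates=[{"a": 1}, {"a": 2}],
                errors=np.array([0.1, 0.05]),
                n_splits=10,
                train_frac=0.7,
                seed=0,
                selected_index=0,
            )

    def test_feature_order_invariance(self):
        X = np.concatenate([np.ones(10), -np.ones(10)])[:, None]
        X = np.hstack([X, np.linspace(-1, 1, 20)[:, None]])
        y = np.array([1] * 10 + [-1] * 10)
        e1 = mccv_error(_SignOfFirstFeature, X, y, n_splits=20, seed=5)
        # swapping feature columns does not change the split sequence
        from eggchem.validation import mccv_splits as ms

        splits = ms(y, n_splits=20, seed=5)
        e2 = mccv_error(_SignOfFirstFeature, X, y, splits=splits)
        assert e1 == e2
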