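"""Interval splitting, SiPLS search and SPA selection: oracles and invariants."""

import itertools

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from nirwood.metrics import rmsecv_loo
from nirwood.selection import (
    SiPLSSelector,
    SPASelector,
    sipls_search,
    spa_chain,
    spa_select,
    spa_select_cv,
    split_intervals,
)
from nirwood.synthetic import planted_columns_dataset, planted_interval_dataset


class TestSplitIntervals:
    def test_reference_grid_ten_intervals(self):
        sizes = split_intervals(117, 10).sizes()
        assert sizes == [12, 12, 12, 12, 12, 12, 12, 11, 11, 11]

    @pytest.mark.parametrize("n_vars,n_int,expected", [(10, 5, [2] * 5), (6, 6, [1] * 6)])
    def test_even_splits(self, n_vars, n_int, expected):
        assert split_intervals(n_vars, n_int).sizes() == expected

    def test_tiles_all_columns(self):
        scheme = split_intervals(53, 7)
        cols = np.concatenate([scheme.columns(i) for i in range(7)])
        assert np.array_equal(cols, np.arange(53))
        assert max(scheme.sizes()) - min(scheme.sizes()) <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            split_intervals(10, 11)
        with pytest.raises(ValueError):
            split_intervals(10, 0)


class TestRmsecvLoo:
    def test_noiseless_linear_is_zero(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 4.0
        assert rmsecv_loo(X, y, 3) <= 1e-8

    def test_matches_sklearn_holdout_loop(self, rng):
        """Brute-force oracle: one sklearn PLS fit per left-out sample."""
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        press = 0.0
        for i in range(5):
            tr = np.arange(5) != i
            m = PLSRegression(n_components=1, scale=False).fit(X[tr], y[tr])
            press += float(y[i] - m.predict(X[i : i + 1]).ravel()[0]) ** 2
        assert rmsecv_loo(X, y, 1) == pytest.approx(np.sqrt(press / 5), abs=1e-9)

    def test_matches_sklearn_on_larger_case(self, rng):
        X = rng.normal(size=(20, 8))
        y = X[:, 0] - X[:, 3] + rng.normal(0, 0.3, 20)
        for ncomp in (1, 2, 4):
            press = 0.0
            for i in range(20):
                tr = np.arange(20) != i
                m = PLSRegression(n_components=ncomp, scale=False).fit(X[tr], y[tr])
                press += float(y[i] - m.predict(X[i : i + 1]).ravel()[0]) ** 2
            assert rmsecv_loo(X, y, ncomp) == pytest.approx(np.sqrt(press / 20), rel=1e-8)

    def test_infeasible_component_count_rejected(self, rng):
        with pytest.raises(ValueError):
            rmsecv_loo(rng.normal(size=(5, 3)), rng.normal(size=5), 4)


class TestSiPLS:
    def test_one_row_per_interval_count(self, rng):
        X = rng.normal(size=(20, 24))
        y = X[:, 3] + rng.normal(0, 0.2, 20)
        res = sipls_search(X, y, N_values=range(5, 9), combo_sizes=(2,), max_components=3)
        assert res.table["n_intervals"].tolist() == [5, 6, 7, 8]

    def test_reported_rmsecv_is_per_n_minimum(self, rng):
        """Argmin oracle: naive double loop over all pairs for one N."""
        X = rng.normal(size=(15, 12))
        y = X[:, 1] - 0.5 * X[:, 7] + rng.normal(0, 0.1, 15)
        N = 6
        res = sipls_search(X, y, N_values=[N], combo_sizes=(2,), max_components=3)
        scheme = split_intervals(12, N)
        best = np.inf
        best_combo = None
        for combo in itertools.combinations(range(N), 2):
            cols = np.concatenate([scheme.columns(i) for i in combo])
            curve = [rmsecv_loo(X[:, cols], y, a) for a in range(1, 4)]
            if min(curve) < best:
                best = min(curve)
                best_combo = tuple(c + 1 for c in combo)
        row = res.table.iloc[0]
        assert row["rmsecv"] == pytest.approx(best, rel=1e-10)
        assert row["intervals"] == best_combo

    def test_best_row_attains_table_minimum(self, rng):
        X, y = planted_interval_dataset(seed=4)
        res = sipls_search(X, y, N_values=[4, 8], combo_sizes=(2,), max_components=4)
        assert res.best_rmsecv == pytest.approx(res.table["rmsecv"].min())

    def test_retained_columns_are_union_of_best_intervals(self):
        X, y = planted_interval_dataset(seed=5)
        res = sipls_search(X, y, N_values=[8], combo_sizes=(2,), max_components=4)
        scheme = split_intervals(64, 8)
        expect = np.sort(np.concatenate([scheme.columns(i - 1) for i in res.best_intervals]))
        assert np.array_equal(res.selected_columns, expect)

    def test_planted_intervals_recovered(self):
        X, y = planted_interval_dataset(seed=6)
        res = sipls_search(X, y, N_values=[8], combo_sizes=(2, 3), max_components=5)
        assert {2, 5} <= set(res.best_intervals)

    def test_selector_facade_transform(self):
        X, y = planted_interval_dataset(seed=7)
        sel = SiPLSSelector(N_values=[8], combo_sizes=(2,), max_components=4).fit(X, y)
        assert sel.transform(X).shape[1] == sel.support_.sum() == len(sel.result_.selected_columns)


class TestSPAChain:
    def test_orthogonal_columns_follow_descending_norms(self):
        raw = np.random.default_rng(0).normal(size=(12, 3))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # orthonormal and zero-mean
        X = Q * np.array([5.0, 4.0, 3.0])
        chain = spa_chain(X, start_column=0, n_max=3)
        assert chain == [0, 1, 2]

    def test_duplicate_column_never_picked_twice(self, rng):
        X = rng.normal(size=(10, 4))
        X = np.column_stack([X, X[:, 1]])  # column 4 duplicates column 1
        chain = spa_chain(X, start_column=1, n_max=4)
        assert len(set(chain)) == len(chain)
        assert not ({1, 4} <= set(chain))

    def test_chain_length_respects_rank(self, rng):
        base = rng.normal(size=(10, 2))
        X = np.column_stack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        chain = spa_chain(X, start_column=0, n_max=5)
        assert len(chain) == 2

    def test_residuals_orthogonal_to_selected(self, rng):
        """After every step the unselected residual columns are orthogonal to
        the span of the selected (centred) columns."""
        X = rng.normal(size=(15, 8))
        Xc = X - X.mean(axis=0)
        chain = spa_chain(X, start_column=2, n_max=5)
        R = Xc.copy()
        for step, j in enumerate(chain[:-1]):
            v = R[:, j]
            R = R - np.outer(v, v @ R) / (v @ v)
            basis = Xc[:, chain[: step + 1]]
            others = [c for c in range(8) if c not in chain[: step + 1]]
            assert np.abs(basis.T @ R[:, others]).max() < 1e-8


class TestSPASelect:
    def test_chosen_count_minimizes_curve(self, rng):
        X, y = planted_columns_dataset(seed=8)
        res = spa_select(X[:40], y[:40], X[40:], y[40:], n_max=6)
        curve = res.rmse_curve
        assert np.nanmin(curve) == pytest.approx(curve[res.n_selected - 1])

    def test_planted_columns_recovered(self):
        X, y = planted_columns_dataset(seed=9)
        res = spa_select(X[:40], y[:40], X[40:], y[40:], n_max=6)
        assert {3, 9, 15} <= set(res.selected_columns)

    def test_cv_mode_recovers_planted_columns(self):
        X, y = planted_columns_dataset(seed=10)
        res = spa_select_cv(X, y, n_max=6)
        assert {3, 9, 15} <= set(res.selected_columns)

    def test_selected_indices_distinct_and_subset(self):
        X, y = planted_columns_dataset(seed=11)
        res = spa_select(X[:40], y[:40], X[40:], y[40:], n_max=8)
        assert len(set(res.selected_columns)) == res.n_selected
        assert all(0 <= j < 20 for j in res.selected_columns)

    def test_mismatched_columns_rejected(self, rng):
        with pytest.raises(ValueError):
            spa_select(rng.normal(size=(10, 5)), rng.normal(size=10),
                       rng.normal(size=(5, 4)), rng.normal(size=5), n_max=3)

    def test_selector_facade_requires_validation(self, rng):
        X, y = planted_columns_dataset(seed=12)
        with pytest.raises(ValueError, match="X_val"):
            SPASelector(n_max=4).fit(X, y)
        sel = SPASelector(n_max=4).fit(X[:40], y[:40], X_val=X[40:], y_val=y[40:])
        assert sel.transform(X).shape[1] == sel.result_.n_selected
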