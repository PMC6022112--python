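"""Two-stage characteristic-wavelength extraction: SiPLS then SPA.

Stage 1 — synergy interval PLS (SiPLS): the spectrum is cut into N equal
contiguous intervals; every combination of 2–4 intervals is scored by the
leave-one-out RMSECV of a PLS1 model on the concatenated columns (component
count chosen by the inner LOO minimum).  The search is repeated for
N = 5 .. 15 and the global RMSECV minimum picks the retained intervals.

Stage 2 — successive projections algorithm (SPA): starting from each retained
column in turn, variables are added greedily by maximum norm of the column's
projection onto the orthogonal complement of the span of the columns already
chosen (minimising collinearity); each chain prefix is scored by the
validation RMSE of a multiple linear regression, and the overall minimum
picks the final characteristic wavelengths.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .models import pls1_loo_rmsecv

__all__ = [
    "IntervalScheme",
    "SiPLSResult",
    "SPAResult",
    "split_intervals",
    "sipls_search",
    "spa_chain",
    "spa_select",
    "spa_select_cv",
    "SiPLSSelector",
    "SPASelector",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalScheme:
    """Equidistant split of ``n_vars`` columns into contiguous intervals.

    ``boundaries`` are half-open 0-based (start, end) pairs; the first
    ``n_vars mod n_intervals`` intervals carry the extra column, so sizes
    differ by at most one and the intervals tile all columns.
    """

    n_intervals: int
    boundaries: tuple[tuple[int, int], ...]

    def columns(self, interval: int) -> np.ndarray:
        """0-based column indices of one (0-based) interval."""
        s, e = self.boundaries[interval]
        return np.arange(s, e)

    def sizes(self) -> list[int]:
        return [e - s for s, e in self.boundaries]


def split_intervals(n_vars: int, n_intervals: int) -> IntervalScheme:
    """Split ``n_vars`` columns into ``n_intervals`` near-equal contiguous pieces."""
    if not 1 <= n_intervals <= n_vars:
        raise ValueError(f"n_intervals must be in 1..{n_vars}, got {n_intervals}")
    base, rem = divmod(n_vars, n_intervals)
    bounds = []
    start = 0
    for i in range(n_intervals):
        size = base + (1 if i < rem else 0)
        bounds.append((start, start + size))
        start += size
    return IntervalScheme(n_intervals=n_intervals, boundaries=tuple(bounds))


@dataclass
class SiPLSResult:
    """Search table and winner of a synergy-interval PLS run.

    ``table`` has one row per interval count N (columns: n_intervals,
    n_components, intervals — 1-based ascending tuple — and rmsecv, GPa).
    The best row attains the table's minimum RMSECV; ``selected_columns`` is
    the union of the winning intervals' columns.
    """

    table: pd.DataFrame
    best_n_intervals: int
    best_intervals: tuple[int, ...]  # 1-based, ascending
    best_n_components: int
    best_rmsecv: float
    selected_columns: np.ndarray
    wavelength_ranges: list[tuple[float, float]] = field(default_factory=list)


def _score_columns(X, y, cols, max_components) -> tuple[float, int]:
    """(best RMSECV, best component count) for one column subset."""
    n = X.shape[0]
    cap = min(max_components, n - 2, len(cols))
    curve = pls1_loo_rmsecv(X[:, cols], y, cap)
    a = int(np.argmin(curve))
    return float(curve[a]), a + 1


def sipls_search(
    X_cal,
    y_cal,
    N_values=range(5, 16),
    combo_sizes=(2, 3, 4),
    max_components: int = 10,
    wavelengths=None,
) -> SiPLSResult:
    """Exhaustive synergy-interval search scored by leave-one-out RMSECV.

    For every interval count N and every combination of ``combo_sizes``
    intervals, a PLS1 model on the concatenated interval columns is scored by
    LOO RMSECV with its component count chosen by the inner LOO minimum
    (capped at ``max_components``).  The per-N winner enters the search table;
    the global minimum defines the retained columns.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    m = X_cal.shape[1]
    N_values = list(N_values)
    combo_sizes = sorted(set(int(s) for s in combo_sizes))
    if not N_values:
        raise ValueError("N_values must be non-empty")
    if any(s < 1 for s in combo_sizes):
        raise ValueError("combination sizes must be >= 1")

    rows = []
    best = None  # (rmsecv, N, intervals, ncomp, cols)
    for N in N_values:
        scheme = split_intervals(m, N)
        feasible = [s for s in combo_sizes if s <= N]
        if not feasible:
            raise ValueError(f"no combination size in {combo_sizes} feasible for N={N}")
        n_best = None
        for size in feasible:
            for combo in itertools.combinations(range(N), size):
                cols = np.concatenate([scheme.columns(i) for i in combo])
                rmsecv, ncomp = _score_columns(X_cal, y_cal, cols, max_components)
                if n_best is None or rmsecv < n_best[0]:
                    n_best = (rmsecv, combo, ncomp, cols)
        rmsecv, combo, ncomp, cols = n_best
        intervals_1based = tuple(i + 1 for i in combo)
        rows.append(
            {
                "n_intervals": N,
                "n_components": ncomp,
                "intervals": intervals_1based,
                "rmsecv": rmsecv,
            }
        )
        if best is None or rmsecv < best[0]:
            best = (rmsecv, N, intervals_1based, ncomp, cols)

    table = pd.DataFrame(rows)
    rmsecv, N, intervals, ncomp, cols = best
    ranges = []
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        scheme = split_intervals(m, N)
        ranges = [
            (float(wavelengths[s]), float(wavelengths[e - 1]))
            for s, e in (scheme.boundaries[i - 1] for i in intervals)
        ]
    return SiPLSResult(
        table=table,
        best_n_intervals=N,
        best_intervals=intervals,
        best_n_components=ncomp,
        best_rmsecv=rmsecv,
        selected_columns=np.sort(cols),
        wavelength_ranges=ranges,
    )


# SPA ------------------------------------------------------------------------


def spa_chain(X, start_column: int, n_max: int) -> list[int]:
    """Greedy minimum-collinearity chain of column indices.

    Columns are mean-centred internally.  The chain starts at
    ``start_column``; each later pick maximises the norm of the candidate
    column's projection onto the orthogonal complement of the span of the
    columns already in the chain.  Stops early if the remaining columns are
    (numerically) in that span, so the chain length is
    ``min(n_max, column rank)``.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 0 <= start_column < m:
        raise ValueError("start_column out of range")
    if not 1 <= n_max <= min(n - 1, m):
        raise ValueError(f"n_max must be in 1..min(n-1, m) = {min(n - 1, m)}")
    R = X - X.mean(axis=0)  # residual columns, progressively orthogonalised
    scale = np.linalg.norm(R, axis=0).max()
    tol = max(scale, 1.0) * 1e-10
    chain = [int(start_column)]
    for _ in range(n_max - 1):
        v = R[:, chain[-1]]
        nv2 = v @ v
        if nv2 < tol**2:
            chain.pop()  # last pick was numerically dependent; shouldn't happen
            break
        R = R - np.outer(v, v @ R) / nv2
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        k = int(np.argmax(norms))
        if norms[k] < tol:
            break
        chain.append(k)
    return chain


@dataclass
class SPAResult:
    """Winning SPA selection.

    ``rmse_curve`` is the validation RMSE versus number of variables for the
    winning start column; ``selected_columns`` is the chain prefix (in
    selection order) attaining the curve's minimum.
    """

    rmse_curve: np.ndarray
    n_selected: int
    start_column: int
    selected_columns: list[int]
    selected_wavelengths: list[float] = field(default_factory=list)


def _mlr_val_rmse(X_cal, y_cal, X_val, y_val, cols) -> float:
    A = np.column_stack([np.ones(X_cal.shape[0]), X_cal[:, cols]])
    coef, _, rank, _ = np.linalg.lstsq(A, y_cal, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("singular MLR design")
    pred = np.column_stack([np.ones(X_val.shape[0]), X_val[:, cols]]) @ coef
    return float(np.sqrt(np.mean((y_val - pred) ** 2)))


def spa_select(X_cal, y_cal, X_val, y_val, n_max: int, wavelengths=None) -> SPAResult:
    """Successive projections selection scored by validation-set MLR RMSE.

    Every column is tried as a chain start; every chain prefix of length
    k <= n_max is fitted by multiple linear regression on the calibration set
    and scored on the validation set.  The winner is the (start, k) with the
    smallest validation RMSE, ties broken toward fewer variables and then the
    lower start column.  Singular regressions are skipped with a warning.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if X_cal.shape[1] != X_val.shape[1]:
        raise ValueError("calibration and validation sets must share the same columns")
    m = X_cal.shape[1]
    best = None  # (rmse, k, start, chain, curve)
    for start in range(m):
        chain = spa_chain(X_cal, start, n_max)
        curve = np.full(n_max, np.nan)
        for k in range(1, len(chain) + 1):
            try:
                curve[k - 1] = _mlr_val_rmse(X_cal, y_cal, X_val, y_val, chain[:k])
            except np.linalg.LinAlgError:
                logger.warning("singular MLR for start=%d, k=%d; candidate skipped", start, k)
                continue
        if np.all(np.isnan(curve)):
            continue
        k_best = int(np.nanargmin(curve))  # lowest index on ties -> parsimony
        cand = (float(curve[k_best]), k_best + 1, start, chain, curve)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise RuntimeError("every SPA candidate regression was singular")
    rmse, k, start, chain, curve = best
    selected = chain[:k]
    wl = [] if wavelengths is None else [float(np.asarray(wavelengths)[j]) for j in selected]
    return SPAResult(
        rmse_curve=curve,
        n_selected=k,
        start_column=start,
        selected_columns=selected,
        selected_wavelengths=wl,
    )


def _mlr_loo_residuals(X, y, cols) -> np.ndarray:
    """Leave-one-out residuals of an MLR fit via the PRESS identity e_i / (1 - h_ii)."""
    A = np.column_stack([np.ones(X.shape[0]), X[:, cols]])
    n, p = A.shape
    if n <= p:
        raise np.linalg.LinAlgError("more coefficients than samples")
    Q, R = np.linalg.qr(A)
    if np.abs(np.diag(R)).min() < 1e-10 * np.abs(np.diag(R)).max():
        raise np.linalg.LinAlgError("singular MLR design")
    coef = np.linalg.solve(R, Q.T @ y)
    resid = y - A @ coef
    h = (Q * Q).sum(axis=1)
    if np.any(h >= 1.0 - 1e-12):
        raise np.linalg.LinAlgError("leverage-one sample: LOO residual undefined")
    return resid / (1.0 - h)


def spa_select_cv(X_cal, y_cal, n_max: int, wavelengths=None) -> SPAResult:
    """SPA scored by leave-one-out cross-validation instead of a held-out set.

    Same search as :func:`spa_select`, but each chain prefix is scored by the
    LOO RMSE of the MLR fit on the calibration set itself (PRESS form), so no
    separate validation samples are consumed.  The variable count follows the
    one-standard-error rule: the smallest k whose LOO MSE is within one
    standard error of the curve minimum (minimising a cross-validation curve
    over many chain prefixes otherwise overfits the criterion and inflates
    the variable count).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n, m = X_cal.shape
    best = None
    for start in range(m):
        chain = spa_chain(X_cal, start, n_max)
        curve = np.full(n_max, np.nan)
        mse = np.full(n_max, np.nan)
        se = np.full(n_max, np.nan)
        for k in range(1, len(chain) + 1):
            try:
                e = _mlr_loo_residuals(X_cal, y_cal, chain[:k])
            except np.linalg.LinAlgError:
                logger.warning("singular MLR for start=%d, k=%d; candidate skipped", start, k)
                continue
            mse[k - 1] = np.mean(e**2)
            se[k - 1] = np.std(e**2, ddof=1) / np.sqrt(n)
            curve[k - 1] = np.sqrt(mse[k - 1])
        if np.all(np.isnan(curve)):
            continue
        i_min = int(np.nanargmin(mse))
        threshold = mse[i_min] + se[i_min]
        k_1se = next(k for k in range(1, n_max + 1) if np.isfinite(mse[k - 1]) and mse[k - 1] <= threshold)
        cand = (float(curve[k_1se - 1]), k_1se, start, chain, curve)
        if best is None or cand[0] < best[0]:
            best = cand
    if best is None:
        raise RuntimeError("every SPA candidate regression was singular")
    rmse, k, start, chain, curve = best
    selected = chain[:k]
    wl = [] if wavelengths is None else [float(np.asarray(wavelengths)[j]) for j in selected]
    return SPAResult(
        rmse_curve=curve,
        n_selected=k,
        start_column=start,
        selected_columns=selected,
        selected_wavelengths=wl,
    )


# sklearn-style selector facades ---------------------------------------------


class SiPLSSelector(TransformerMixin, BaseEstimator):
    """Feature selector running the SiPLS search in ``fit``.

    Attributes after fit: ``result_`` (:class:`SiPLSResult`), ``support_``
    (boolean mask over columns), ``n_features_in_``.
    """

    def __init__(self, N_values=tuple(range(5, 16)), combo_sizes=(2, 3, 4), max_components: int = 10):
        self.N_values = N_values
        self.combo_sizes = combo_sizes
        self.max_components = max_components

    def fit(self, X, y, wavelengths=None):
        X = np.asarray(X, dtype=float)
        self.result_ = sipls_search(
            X, y, N_values=self.N_values, combo_sizes=self.combo_sizes,
            max_components=self.max_components, wavelengths=wavelengths,
        )
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.result_.selected_columns] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]


class SPASelector(TransformerMixin, BaseEstimator):
    """Feature selector running SPA in ``fit``.

    ``fit`` requires a validation set (``X_val``, ``y_val``) for the MLR
    scoring; the pipeline passes an inner Kennard-Stone split of the
    calibration data.
    """

    def __init__(self, n_max: int = 10):
        self.n_max = n_max

    def fit(self, X, y, X_val=None, y_val=None, wavelengths=None):
        X = np.asarray(X, dtype=float)
        if X_val is None or y_val is None:
            raise ValueError("SPASelector.fit requires X_val and y_val")
        self.result_ = spa_select(X, y, X_val, y_val, n_max=self.n_max, wavelengths=wavelengths)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.result_.selected_columns] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]
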