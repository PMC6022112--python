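"""Calibration models: PLS1 regression and a single-hidden-layer BPNN.

PLS1 is implemented directly (NIPALS on centred, unscaled data) because the
interval-search stage needs nested per-component predictions — one pass of
leave-one-out cross-validation scores every component count at once, which is
what makes an exhaustive synergy-interval search tractable.

The BPNN is the classic fully-connected net used in NIR calibration work: one
sigmoid hidden layer, linear output, trained by full-batch backpropagation
(gradient descent with momentum) on min-max-scaled inputs and target.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PLS1Regression",
    "PLSModel",
    "BPNNConfig",
    "BPNNRegressor",
    "pls_fit",
    "bpnn_train",
    "pls1_loo_rmsecv",
]

_EPS = 1e-12


class PLS1Regression(RegressorMixin, BaseEstimator):
    """PLS1 latent-variable regression (NIPALS, centred data, no scaling).

    Parameters
    ----------
    n_components : int
        Number of latent variables; must be <= min(n_samples - 1, n_features).

    Attributes
    ----------
    x_mean_, y_mean_ : centring vectors.
    coef_ : ndarray of shape (n_features,)
        Regression vector on the original (uncentred) scale.
    intercept_ : float
    fitted_values_ : ndarray
        Predictions on the training data.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per element of y")
        n, m = X.shape
        A = int(self.n_components)
        if not 1 <= A <= min(n - 1, m):
            raise ValueError(
                f"n_components={A} infeasible for {n} samples x {m} features"
            )
        if np.ptp(y) == 0:
            raise ValueError("y has zero variance")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        W = np.zeros((m, A))
        P = np.zeros((m, A))
        q = np.zeros(A)
        for a in range(A):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw < _EPS:  # residual y uncorrelated with residual X
                W, P, q = W[:, :a], P[:, :a], q[:a]
                A = a
                break
            w /= nw
            t = Xc @ w
            tt = t @ t
            if tt < _EPS:
                W, P, q = W[:, :a], P[:, :a], q[:a]
                A = a
                break
            p = Xc.T @ t / tt
            q_a = yc @ t / tt
            W[:, a], P[:, a], q[a] = w, p, q_a
            Xc -= np.outer(t, p)
            yc -= q_a * t
        if A == 0:
            raise ValueError("no usable PLS component (X uncorrelated with y)")
        self.n_components_ = A
        # B = W (P'W)^-1 q maps centred X to centred y
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        self.x_weights_, self.x_loadings_, self.y_loadings_ = W, P, q
        self.n_features_in_ = m
        self.fitted_values_ = X @ self.coef_ + self.intercept_
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


PLSModel = PLS1Regression  # domain alias


def pls_fit(X, y, n_components: int) -> PLS1Regression:
    """Fit a PLS1 calibration model (thin wrapper over :class:`PLS1Regression`)."""
    return PLS1Regression(n_components=n_components).fit(X, y)


def _pls1_loo_press_numpy(X, y, A: int) -> np.ndarray:
    n = X.shape[0]
    press = np.zeros(A)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xt, yt = X[tr], y[tr]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        Xc = Xt - xm
        yc = yt - ym
        x = X[i] - xm
        yhat = ym
        for a in range(A):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw >= _EPS:
                w /= nw
                t = Xc @ w
                tt = t @ t
                if tt >= _EPS:
                    p = Xc.T @ t / tt
                    q_a = yc @ t / tt
                    tau = x @ w
                    yhat = yhat + tau * q_a
                    x = x - tau * p
                    Xc -= np.outer(t, p)
                    yc -= q_a * t
            press[a] += (y[i] - yhat) ** 2
    return press


try:  # compiled kernel: the interval search runs tens of thousands of LOO fits
    from numba import njit

    @njit(cache=True)
    def _pls1_loo_press_jit(X, y, A):  # pragma: no cover - exercised via wrapper
        n, m = X.shape
        press = np.zeros(A)
        nt = n - 1
        for i in range(n):
            Xc = np.empty((nt, m))
            yt = np.empty(nt)
            k = 0
            for j in range(n):
                if j != i:
                    Xc[k, :] = X[j, :]
                    yt[k] = y[j]
                    k += 1
            xm = np.zeros(m)
            for r in range(nt):
                xm += Xc[r]
            xm /= nt
            ym = yt.sum() / nt
            for r in range(nt):
                Xc[r] -= xm
            yc = yt - ym
            x = X[i] - xm
            yhat = ym
            for a in range(A):
                w = Xc.T @ yc
                nw = np.sqrt((w * w).sum())
                if nw >= 1e-12:
                    w = w / nw
                    t = Xc @ w
                    tt = (t * t).sum()
                    if tt >= 1e-12:
                        p = (Xc.T @ t) / tt
                        q = (yc * t).sum() / tt
                        tau = (x * w).sum()
                        yhat += tau * q
                        x = x - tau * p
                        for r in range(nt):
                            Xc[r] -= t[r] * p
                        yc = yc - q * t
                press[a] += (y[i] - yhat) ** 2
        return press

    _pls1_loo_press = _pls1_loo_press_jit
except ImportError:  # pragma: no cover
    _pls1_loo_press = _pls1_loo_press_numpy


def pls1_loo_rmsecv(X, y, max_components: int) -> np.ndarray:
    """Leave-one-out RMSECV of PLS1 for every component count 1..max_components.

    One NIPALS pass per fold scores all component counts (latent variables are
    nested), so the full component search costs a single LOO sweep.  If the
    deflated data degenerate before ``max_components`` in some fold, the last
    attainable prediction carries over to the higher counts for that fold.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(np.asarray(y, dtype=float).ravel())
    n, m = X.shape
    A = int(max_components)
    if not 1 <= A <= min(n - 2, m):
        raise ValueError(f"max_components={A} infeasible for {n} samples x {m} features")
    return np.sqrt(_pls1_loo_press(X, y, A) / n)


# BPNN -----------------------------------------------------------------------


class BPNNConfig(dict):
    """Plain config mapping for :func:`bpnn_train` (keys mirror BPNNRegressor params)."""


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


class BPNNRegressor(RegressorMixin, BaseEstimator):
    """Single-hidden-layer backpropagation network for scalar calibration.

    Inputs and target are min-max scaled to [0, 1] before training; the net is
    sigmoid-hidden / linear-output, trained by full-batch backpropagation:
    gradient descent with momentum and an adaptive learning rate (grown by
    5% after an improving epoch, shrunk by 30% — with the step rejected and
    the momentum reset — after an epoch that raises the loss by more than
    4%).  Training stops at ``max_epochs`` or once ``patience`` consecutive
    epochs fail to improve the best training MSE by at least ``tol``.

    Hidden weights use Nguyen-Widrow initialisation (active sigmoid regions
    tiled over the scaled input cube), which makes small nets converge
    reliably from the modest initial rate.

    Parameters
    ----------
    hidden_units : int or None
        Hidden-layer width; None means ``2 * n_inputs + 1`` (11 for the five
        characteristic wavelengths).
    learning_rate : float, default 0.01
        Initial learning rate.
    momentum : float, default 0.9
    max_epochs : int, default 2000
    tol : float, default 1e-6
        Improvement tolerance on the scaled-space MSE.
    patience : int, default 100
        Epochs without a ``tol``-sized improvement before stopping (momentum
        makes single-epoch improvement tests spuriously trip).
    n_restarts : int, default 3
        Independent seeded initialisations; the net with the lowest final
        training MSE is kept (guards against poor local minima).
    random_state : int
        Seed for weight initialisation; required, so every fit is reproducible.
        Restart r uses seed ``random_state + r``.
    """

    _LR_GROW = 1.05
    _LR_SHRINK = 0.7
    _LR_MAX = 10.0
    _MAX_LOSS_RISE = 1.04

    def __init__(
        self,
        hidden_units: int | None = None,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        max_epochs: int = 2000,
        tol: float = 1e-6,
        patience: int = 100,
        n_restarts: int = 3,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per element of y")
        if self.random_state is None:
            raise ValueError("BPNNRegressor requires an integer random_state")
        if np.ptp(y) == 0:
            raise ValueError("y is constant; BPNN target scaling is undefined")
        n, d = X.shape
        h = self.hidden_units if self.hidden_units is not None else 2 * d + 1
        if h < 1:
            raise ValueError("need at least 1 hidden unit")

        self.x_min_ = X.min(axis=0)
        xr = X.max(axis=0) - self.x_min_
        self.x_range_ = np.where(xr > 0, xr, 1.0)  # constant columns map to 0
        self.y_min_ = float(y.min())
        self.y_range_ = float(np.ptp(y))
        Xs = (X - self.x_min_) / self.x_range_
        ys = (y - self.y_min_) / self.y_range_

        best = None
        for r in range(max(1, int(self.n_restarts))):
            fit = self._train_once(Xs, ys, d, h, int(self.random_state) + r)
            if best is None or fit[-2] < best[-2]:
                best = fit
        self.W1_, self.b1_, self.w2_, self.b2_, self.loss_, self.n_epochs_ = best
        self.n_features_in_ = d
        return self

    def _train_once(self, Xs, ys, d, h, seed):
        n = Xs.shape[0]
        rng = np.random.default_rng(seed)
        # Nguyen-Widrow: random directions scaled so the sigmoids' linear
        # regions tile the unit input cube
        W1 = rng.uniform(-1.0, 1.0, size=(d, h))
        norms = np.linalg.norm(W1, axis=0)
        norms[norms == 0] = 1.0
        beta = 0.7 * h ** (1.0 / d)
        W1 = beta * W1 / norms
        b1 = rng.uniform(-beta, beta, size=h)
        w2 = rng.uniform(-0.5, 0.5, size=h)
        b2 = rng.uniform(-0.5, 0.5)
        vW1 = np.zeros_like(W1)
        vb1 = np.zeros_like(b1)
        vw2 = np.zeros_like(w2)
        vb2 = 0.0

        lr, mu = float(self.learning_rate), self.momentum
        best_loss = np.inf
        prev_loss = np.inf
        loss = np.inf
        no_improve = 0
        for epoch in range(self.max_epochs):
            Z = _sigmoid(Xs @ W1 + b1)
            yhat = Z @ w2 + b2
            err = yhat - ys
            loss = float(err @ err) / n
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"BPNN training diverged (non-finite loss at epoch {epoch}); "
                    "lower the learning rate"
                )
            if loss > prev_loss * self._MAX_LOSS_RISE:
                # reject the step: restore weights, shrink the rate, reset momentum
                w2 -= vw2
                b2 -= vb2
                W1 -= vW1
                b1 -= vb1
                vW1[:] = 0.0
                vb1[:] = 0.0
                vw2[:] = 0.0
                vb2 = 0.0
                lr *= self._LR_SHRINK
                Z = _sigmoid(Xs @ W1 + b1)
                yhat = Z @ w2 + b2
                err = yhat - ys
                loss = float(err @ err) / n
            elif loss < prev_loss:
                lr = min(lr * self._LR_GROW, self._LR_MAX)
            prev_loss = loss
            if loss < best_loss - self.tol:
                best_loss = loss
                no_improve = 0
            else:
                no_improve += 1
                if no_improve >= self.patience:
                    break
            # backprop (full batch)
            g_out = 2.0 * err / n
            gw2 = Z.T @ g_out
            gb2 = g_out.sum()
            g_hidden = np.outer(g_out, w2) * Z * (1.0 - Z)
            gW1 = Xs.T @ g_hidden
            gb1 = g_hidden.sum(axis=0)
            vw2 = mu * vw2 - lr * gw2
            vb2 = mu * vb2 - lr * gb2
            vW1 = mu * vW1 - lr * gW1
            vb1 = mu * vb1 - lr * gb1
            w2 += vw2
            b2 += vb2
            W1 += vW1
            b1 += vb1

        return W1, b1, w2, b2, loss, epoch + 1

    def predict(self, X):
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_min_) / self.x_range_
        Z = _sigmoid(Xs @ self.W1_ + self.b1_)
        return (Z @ self.w2_ + self.b2_) * self.y_range_ + self.y_min_


def bpnn_train(X, y, config: dict | None = None) -> BPNNRegressor:
    """Train a BPNN calibration model from a config mapping (see BPNNRegressor)."""
    return BPNNRegressor(**(config or {})).fit(X, y)
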