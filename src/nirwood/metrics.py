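"""Model evaluation statistics for NIR calibration.

The metric suite is the standard chemometric set: Pearson correlation between
measured and predicted response (r_c on the calibration set, r_p on the
prediction set), root-mean-square errors (RMSEC / RMSEP), the standard error
of leave-one-out cross-validation (SECV), the prediction set's response
standard deviation (SD, n-1 denominator) and the ratio of performance to
deviation RPD = SD / RMSEP.  An RPD between 2.5 and 3 is conventionally read
as adequate for quantitative prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import stats
from sklearn.base import clone

__all__ = ["Metrics", "evaluate", "rmsecv_loo", "secv_loo", "rpd"]


@dataclass
class Metrics:
    """Evaluation record; fields not applicable to a given set stay None.

    Invariant: when both are present, ``rpd == sd / rmsep`` (before rounding).
    """

    r_c: float | None = None
    rmsec: float | None = None
    secv: float | None = None
    r_p: float | None = None
    rmsep: float | None = None
    sd: float | None = None
    rpd: float | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def rpd(sd: float, rmsep: float) -> float:
    """Ratio of performance to deviation: prediction-set SD over RMSEP."""
    if rmsep <= 0:
        raise ValueError("RMSEP must be > 0 to form an RPD")
    return sd / rmsep


def evaluate(y_true, y_pred, which_set: str = "calibration") -> Metrics:
    """Correlation/RMSE statistics of measured vs predicted values.

    ``which_set`` is 'calibration' or 'prediction'; SD and RPD are computed
    only for prediction sets.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    if np.ptp(y_true) == 0:
        raise ValueError("y_true is constant; correlation is undefined")
    if which_set not in ("calibration", "prediction"):
        raise ValueError("which_set must be 'calibration' or 'prediction'")
    r = float(stats.pearsonr(y_true, y_pred).statistic)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if which_set == "calibration":
        return Metrics(r_c=r, rmsec=rmse)
    sd = float(np.std(y_true, ddof=1))
    return Metrics(r_p=r, rmsep=rmse, sd=sd, rpd=rpd(sd, rmse) if rmse > 0 else np.inf)


def rmsecv_loo(X, y, n_components: int) -> float:
    """Leave-one-out RMSECV of a PLS1 model with exactly ``n_components``."""
    from .models import pls1_loo_rmsecv

    return float(pls1_loo_rmsecv(X, y, n_components)[n_components - 1])


def secv_loo(model_spec, X, y) -> float:
    """Standard error of the leave-one-out cross-validation residuals.

    ``model_spec`` is an unfitted sklearn-style estimator; it is cloned and
    refitted for every fold.  If the estimator is seeded (``random_state``),
    each fold uses a seed derived from it (base + fold index) so the whole
    sweep is reproducible.  SECV is the bias-corrected standard error
    ``sqrt(sum((e_i - mean(e))^2) / (n - 1))`` of the n held-out residuals.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("SECV needs at least 3 samples")
    resid = np.empty(n)
    idx = np.arange(n)
    base_seed = getattr(model_spec, "random_state", None)
    for i in range(n):
        est = clone(model_spec)
        if base_seed is not None:
            est.set_params(random_state=(int(base_seed) + i) % (2**31))
        tr = idx != i
        try:
            est.fit(X[tr], y[tr])
        except Exception as exc:
            raise RuntimeError(f"cross-validation fold {i} failed: {exc}") from exc
        resid[i] = y[i] - float(np.asarray(est.predict(X[i : i + 1])).ravel()[0])
    return float(np.sqrt(np.sum((resid - resid.mean()) ** 2) / (n - 1)))
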