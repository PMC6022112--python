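"""Spectral pretreatment: multiplicative scatter correction and Savitzky-Golay.

The pretreatment chain is MSC first, then an SG smoothing/derivative filter
(default window 11, polynomial order 3, first derivative).  Both steps are
exposed as sklearn-style transformers so they compose with pipelines; the
module-level :func:`msc`, :func:`sg_filter` and :func:`pretreat` functions are
thin wrappers operating on :class:`~nirwood.dataset.SpectraSet`.

MSC regresses every spectrum on a reference (by default the mean spectrum of
the *fit* data, so prediction-set spectra are always corrected against the
calibration-set mean) and replaces it by ``(s - a) / b``.  The SG derivative
is scaled by the grid spacing, so deriv=1 output is in absorbance per nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectraSet

__all__ = [
    "MSCCorrector",
    "SavitzkyGolay",
    "SGParams",
    "MSCResult",
    "msc",
    "sg_filter",
    "pretreat",
]

_SLOPE_FLOOR = 1e-8


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay filter settings: odd window >= 3, polyorder < window, deriv in {0, 1}."""

    window: int = 11
    polyorder: int = 3
    deriv: int = 1

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"SG window must be an odd integer >= 3, got {self.window}")
        if not 0 <= self.polyorder < self.window:
            raise ValueError(f"SG polyorder must satisfy 0 <= polyorder < window, got {self.polyorder}")
        if self.deriv not in (0, 1):
            raise ValueError("SG deriv must be 0 or 1")


@dataclass
class MSCResult:
    """Output of multiplicative scatter correction.

    ``corrected`` is the scatter-corrected set; ``reference`` the spectrum
    regressed against; ``slope``/``offset`` the per-sample affine fit that was
    removed.  Re-regressing any corrected spectrum on the reference gives
    slope 1, offset 0 (to numerical tolerance).
    """

    corrected: SpectraSet
    reference: np.ndarray
    slope: np.ndarray
    offset: np.ndarray


class MSCCorrector(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Parameters
    ----------
    reference : array-like of shape (m,), optional
        Reference spectrum.  When omitted, ``fit`` uses the column mean of the
        fitted data — so fitting on the calibration set and transforming the
        prediction set corrects the latter against the calibration mean.

    Attributes
    ----------
    reference_ : ndarray of shape (m,)
        The reference actually used.
    slope_, offset_ : ndarray of shape (n,)
        Affine fit of each spectrum of the last ``transform`` call.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_wavelengths)")
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float).ravel()
            if ref.size != X.shape[1]:
                raise ValueError(
                    f"reference length {ref.size} does not match {X.shape[1]} wavelengths"
                )
        else:
            if X.shape[0] < 2:
                raise ValueError("MSC needs at least 2 spectra to form a mean reference")
            ref = X.mean(axis=0)
        self.reference_ = ref
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.reference_.size:
            raise ValueError("X column count does not match the fitted reference")
        ref = self.reference_
        refc = ref - ref.mean()
        denom = refc @ refc
        if denom <= 0:
            raise ValueError("degenerate (constant) reference spectrum")
        xm = X.mean(axis=1)
        slope = (X - xm[:, None]) @ refc / denom
        if np.any(np.abs(slope) < _SLOPE_FLOOR):
            bad = int(np.argmin(np.abs(slope)))
            raise ValueError(
                f"MSC slope {slope[bad]:.3e} below floor {_SLOPE_FLOOR} for spectrum {bad}"
            )
        offset = xm - slope * ref.mean()
        self.slope_ = slope
        self.offset_ = offset
        return (X - offset[:, None]) / slope[:, None]


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay smoothing / first-derivative filter on a uniform grid.

    Edge columns use polynomial fits on asymmetric windows (scipy's ``interp``
    mode), so the output has the same number of columns as the input.  With
    ``deriv=1`` the output is divided by ``delta`` (the grid spacing, nm), so
    units are absorbance per nm.
    """

    def __init__(self, window: int = 11, polyorder: int = 3, deriv: int = 1, delta: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        SGParams(self.window, self.polyorder, self.deriv)  # validates
        if self.window > X.shape[1]:
            raise ValueError(f"SG window {self.window} exceeds {X.shape[1]} wavelengths")
        if self.delta <= 0:
            raise ValueError("delta (grid spacing) must be > 0")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = np.asarray(X, dtype=float)
        return savgol_filter(
            X,
            window_length=self.window,
            polyorder=self.polyorder,
            deriv=self.deriv,
            delta=self.delta,
            axis=1,
            mode="interp",
        )


# SpectraSet-level wrappers --------------------------------------------------


def msc(spectra: SpectraSet, reference: np.ndarray | None = None) -> MSCResult:
    """Apply MSC to a whole set; default reference is the set's mean spectrum."""
    corrector = MSCCorrector(reference=reference).fit(spectra.absorbance)
    corrected = corrector.transform(spectra.absorbance)
    out = spectra.with_absorbance(corrected, msc={"reference": "mean" if reference is None else "given"})
    return MSCResult(
        corrected=out,
        reference=corrector.reference_,
        slope=corrector.slope_,
        offset=corrector.offset_,
    )


def _grid_spacing(spectra: SpectraSet) -> float:
    steps = np.diff(spectra.grid)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
        raise ValueError("SG filtering requires a uniform wavelength grid")
    return float(steps[0])


def sg_filter(spectra: SpectraSet, params: SGParams = SGParams()) -> SpectraSet:
    """Savitzky-Golay filter over every spectrum; derivative scaled to per-nm units."""
    delta = _grid_spacing(spectra)
    sg = SavitzkyGolay(params.window, params.polyorder, params.deriv, delta=delta).fit(spectra.absorbance)
    return spectra.with_absorbance(
        sg.transform(spectra.absorbance),
        savitzky_golay={"window": params.window, "polyorder": params.polyorder, "deriv": params.deriv},
    )


def pretreat(
    spectra: SpectraSet,
    sg: SGParams = SGParams(),
    reference: np.ndarray | None = None,
) -> SpectraSet:
    """MSC followed by SG filtering, parameters recorded in the output metadata."""
    corrected = msc(spectra, reference=reference).corrected
    return sg_filter(corrected, sg)
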