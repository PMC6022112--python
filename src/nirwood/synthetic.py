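"""Synthetic NIR spectra with a planted wood-stiffness response.

The generator emulates the statistical structure that interval- and
wavelength-selection methods presume in diffuse-reflectance wood spectra:

* smooth, overlapping Gaussian absorption bands arising from a small number of
  latent "chemical components" (cellulose-, lignin-, hemicellulose-like pools
  plus nuisance absorbers);
* per-spectrum affine scatter (``b * s + a``) — exactly the distortion
  multiplicative scatter correction removes;
* slow polynomial baseline drift and high-frequency white noise;
* a response (modulus of elasticity, GPa) that is linear in the component
  concentrations with an optional mild quadratic term, so that only the
  wavelength regions where response-linked components absorb are informative.

Defaults produce 125 samples on the 907–1864 nm / 117-point grid with the
response-linked bands confined to roughly 4 of 10 equal wavelength intervals
and summary statistics (mean ~16 GPa, SD ~2.7 GPa) in the range typical of
oak structural timber.

Two auxiliary planted-signal constructors (:func:`planted_interval_dataset`,
:func:`planted_columns_dataset`) build small matrices with known informative
intervals/columns for validating the selection algorithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectraSet, make_wavelength_grid

__all__ = [
    "Band",
    "Component",
    "ComponentBank",
    "SyntheticConfig",
    "default_component_bank",
    "default_config",
    "generate_dataset",
    "planted_interval_dataset",
    "planted_columns_dataset",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: center (nm), sigma (nm), peak amplitude (AU)."""

    center_nm: float
    sigma_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0:
            raise ValueError("band width (sigma) must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")


@dataclass(frozen=True)
class Component:
    """A latent absorber: a named collection of Gaussian bands."""

    name: str
    bands: tuple[Band, ...]


@dataclass(frozen=True)
class ComponentBank:
    """The set of latent components whose mixtures form the spectra."""

    components: tuple[Component, ...]

    @property
    def n_components(self) -> int:
        return len(self.components)

    def band_matrix(self, grid: np.ndarray) -> np.ndarray:
        """K x m matrix of pure-component spectra evaluated on ``grid``.

        Warns if a component has a band whose center lies more than 4 sigma
        outside the grid range (it contributes essentially nothing).
        """
        grid = np.asarray(grid, dtype=float)
        lo, hi = grid[0], grid[-1]
        B = np.zeros((self.n_components, grid.size))
        for k, comp in enumerate(self.components):
            for band in comp.bands:
                if band.center_nm < lo - 4 * band.sigma_nm or band.center_nm > hi + 4 * band.sigma_nm:
                    warnings.warn(
                        f"band at {band.center_nm} nm of component {comp.name!r} lies "
                        f"entirely outside the {lo}-{hi} nm grid",
                        stacklevel=2,
                    )
                B[k] += band.amplitude * np.exp(-0.5 * ((grid - band.center_nm) / band.sigma_nm) ** 2)
        return B


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic dataset.

    All standard deviations are >= 0; ``seed`` fixes every random draw, so the
    same config always yields a bit-identical dataset.

    The response is ``intercept + u + w * ((u - mu_u)^2 - sigma_u^2) / sigma_u``
    plus noise, where ``u = coefficients . concentrations`` and ``mu_u``,
    ``sigma_u`` are its configured moments: a mostly linear response with a
    mild convex distortion (stiffness saturating in overall composition)
    whose weight ``w = nonlinearity_weight`` is dimensionless; 0 gives a
    purely linear response.
    """

    n_samples: int = 125
    grid_start_nm: float = 907.0
    grid_end_nm: float = 1864.0
    grid_points: int = 117
    bank: ComponentBank = None  # type: ignore[assignment]
    concentration_mean: np.ndarray = None  # type: ignore[assignment]
    concentration_cov: np.ndarray = None  # type: ignore[assignment]
    response_coefficients: np.ndarray = None  # type: ignore[assignment]
    response_intercept: float = 11.0
    nonlinearity_weight: float = 0.4
    scatter_slope_sd: float = 0.08
    scatter_offset_sd: float = 0.03
    drift_degree: int = 2
    drift_amplitude: float = 0.03
    noise_sd: float = 0.003
    response_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bank is None:
            self.bank = default_component_bank()
        K = self.bank.n_components
        if self.concentration_mean is None:
            self.concentration_mean = np.ones(K)
        if self.concentration_cov is None:
            sds = np.full(K, 0.3)
            if self.bank.components[-1].name == "matrix_background":
                sds[-1] = 0.02  # the bulk matrix barely varies between specimens
            self.concentration_cov = np.diag(sds**2)
        if self.response_coefficients is None:
            coefs = np.zeros(K)
            coefs[: min(3, K)] = [6.0, -5.0, 4.0][: min(3, K)]
            self.response_coefficients = coefs
        self.concentration_mean = np.asarray(self.concentration_mean, dtype=float)
        self.concentration_cov = np.asarray(self.concentration_cov, dtype=float)
        self.response_coefficients = np.asarray(self.response_coefficients, dtype=float)
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "drift_amplitude", "noise_sd", "response_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.concentration_mean.shape == (K,) and self.concentration_cov.shape == (K, K)):
            raise ValueError("concentration mean/cov shapes must match the component bank")
        if self.response_coefficients.shape != (K,):
            raise ValueError("response_coefficients length must match the component bank")
        if self.drift_degree < 0:
            raise ValueError("drift_degree must be >= 0")

    # serialisation ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "grid": {"start_nm": self.grid_start_nm, "end_nm": self.grid_end_nm, "points": self.grid_points},
            "components": [
                {
                    "name": c.name,
                    "bands": [
                        {"center_nm": b.center_nm, "sigma_nm": b.sigma_nm, "amplitude": b.amplitude}
                        for b in c.bands
                    ],
                }
                for c in self.bank.components
            ],
            "concentration_mean": self.concentration_mean.tolist(),
            "concentration_cov": self.concentration_cov.tolist(),
            "response": {
                "coefficients": self.response_coefficients.tolist(),
                "intercept": self.response_intercept,
                "nonlinearity_weight": self.nonlinearity_weight,
                "noise_sd": self.response_noise_sd,
            },
            "scatter": {"slope_sd": self.scatter_slope_sd, "offset_sd": self.scatter_offset_sd},
            "drift": {"degree": self.drift_degree, "amplitude": self.drift_amplitude},
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        bank = ComponentBank(
            tuple(
                Component(
                    c["name"],
                    tuple(Band(b["center_nm"], b["sigma_nm"], b["amplitude"]) for b in c["bands"]),
                )
                for c in d["components"]
            )
        )
        resp = d["response"]
        return cls(
            n_samples=d["n_samples"],
            grid_start_nm=d["grid"]["start_nm"],
            grid_end_nm=d["grid"]["end_nm"],
            grid_points=d["grid"]["points"],
            bank=bank,
            concentration_mean=np.array(d["concentration_mean"]),
            concentration_cov=np.array(d["concentration_cov"]),
            response_coefficients=np.array(resp["coefficients"]),
            response_intercept=resp["intercept"],
            nonlinearity_weight=resp["nonlinearity_weight"],
            response_noise_sd=resp["noise_sd"],
            scatter_slope_sd=d["scatter"]["slope_sd"],
            scatter_offset_sd=d["scatter"]["offset_sd"],
            drift_degree=d["drift"]["degree"],
            drift_amplitude=d["drift"]["amplitude"],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
        )


def default_component_bank() -> ComponentBank:
    """Six latent absorbers on the 907–1864 nm range.

    The first three are response-linked; their bands sit near 960, 1345, 1540
    and 1725 nm, i.e. inside intervals 1, 5, 7 and 9 of a 10-way equal split
    of the grid.  Two nuisance absorbers occupy the remaining regions, and a
    broad near-constant matrix background (scattering continuum plus bulk
    absorption) dominates the overall spectrum level, as in real wood spectra
    — which keeps the multiplicative-scatter fit from coupling the response
    into every wavelength.
    """
    return ComponentBank(
        (
            Component("cellulose_like", (Band(960.0, 16.0, 0.45), Band(1345.0, 16.0, 0.50))),
            Component("lignin_like", (Band(1540.0, 16.0, 0.50),)),
            Component("hemicellulose_like", (Band(1725.0, 16.0, 0.45),)),
            Component("water_like", (Band(1150.0, 20.0, 0.50), Band(1620.0, 20.0, 0.40))),
            Component("extractives_like", (Band(1050.0, 20.0, 0.40), Band(1440.0, 20.0, 0.45))),
            Component("matrix_background", (Band(1250.0, 450.0, 1.6), Band(1900.0, 300.0, 0.8))),
        )
    )


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The package's reference study conditions (125 samples, 907–1864 nm, 117 points)."""
    return SyntheticConfig(seed=seed, **overrides)


def generate_dataset(config: SyntheticConfig) -> SpectraSet:
    """Draw one dataset from the generative model.

    The draw order is fixed (concentrations, scatter slopes, scatter offsets,
    drift coefficients, spectral noise, response noise) so a given seed is
    fully reproducible.

    Returns
    -------
    SpectraSet
        ``n_samples`` spectra with the response vector attached and the config
        seed recorded in ``meta``.
    """
    rng = np.random.default_rng(config.seed)
    grid = make_wavelength_grid(config.grid_start_nm, config.grid_end_nm, config.grid_points)
    B = config.bank.band_matrix(grid)
    n, m = config.n_samples, grid.size

    try:
        conc = rng.multivariate_normal(
            config.concentration_mean, config.concentration_cov, size=n, method="cholesky"
        )
    except np.linalg.LinAlgError:  # singular covariance (e.g. frozen components)
        rng = np.random.default_rng(config.seed)
        conc = rng.multivariate_normal(
            config.concentration_mean, config.concentration_cov, size=n, method="eigh"
        )
    conc = np.clip(conc, 0.0, None)

    mix = conc @ B

    slopes = 1.0 + rng.normal(0.0, config.scatter_slope_sd, size=n)
    offsets = rng.normal(0.0, config.scatter_offset_sd, size=n)

    u = np.linspace(-1.0, 1.0, m)
    drift = np.zeros((n, m))
    if config.drift_degree > 0 and config.drift_amplitude > 0:
        coeffs = rng.normal(0.0, config.drift_amplitude, size=(n, config.drift_degree))
        for d in range(1, config.drift_degree + 1):
            drift += coeffs[:, d - 1 : d] * u**d

    noise = rng.normal(0.0, config.noise_sd, size=(n, m)) if config.noise_sd > 0 else 0.0

    absorbance = slopes[:, None] * mix + offsets[:, None] + drift + noise

    u = conc @ config.response_coefficients
    mu_u = config.concentration_mean @ config.response_coefficients
    var_u = config.response_coefficients @ config.concentration_cov @ config.response_coefficients
    if config.nonlinearity_weight != 0 and var_u > 0:
        quad = ((u - mu_u) ** 2 - var_u) / np.sqrt(var_u)
    else:
        quad = 0.0
    response = (
        config.response_intercept
        + u
        + config.nonlinearity_weight * quad
        + (rng.normal(0.0, config.response_noise_sd, size=n) if config.response_noise_sd > 0 else 0.0)
    )

    width = max(3, len(str(n)))
    ids = [f"s{i + 1:0{width}d}" for i in range(n)]
    return SpectraSet(
        sample_ids=ids,
        grid=grid,
        absorbance=absorbance,
        response=response,
        meta={"generator_seed": config.seed},
    )


# planted-signal constructors ------------------------------------------------


def planted_interval_dataset(
    n_samples: int = 40,
    n_intervals: int = 8,
    interval_size: int = 8,
    informative: tuple[int, ...] = (2, 5),
    factor_sd: float = 1.0,
    column_noise_sd: float = 0.2,
    response_noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix with a known set of informative contiguous intervals.

    Each informative interval (1-based indices) carries one latent factor
    spread over its columns with a smooth positive loading profile; the
    response is the sum of those factors.  All other columns are pure
    standard-normal noise, so an interval-selection search has an unambiguous
    ground truth.

    Returns ``(X, y)`` with ``X`` of shape ``(n_samples, n_intervals * interval_size)``.
    """
    if any(j < 1 or j > n_intervals for j in informative):
        raise ValueError("informative interval indices must be in 1..n_intervals")
    rng = np.random.default_rng(seed)
    m = n_intervals * interval_size
    X = rng.normal(0.0, 1.0, size=(n_samples, m))
    y = np.zeros(n_samples)
    t = np.linspace(0, 1, interval_size)
    loading = 0.6 + 0.8 * np.exp(-0.5 * ((t - 0.5) / 0.25) ** 2)  # smooth band-like profile
    for j in informative:
        factor = rng.normal(0.0, factor_sd, size=n_samples)
        cols = slice((j - 1) * interval_size, j * interval_size)
        X[:, cols] = np.outer(factor, loading) + rng.normal(0.0, column_noise_sd, size=(n_samples, interval_size))
        y += factor
    y += rng.normal(0.0, response_noise_sd, size=n_samples)
    return X, y


def planted_columns_dataset(
    n_samples: int = 60,
    n_columns: int = 20,
    informative: tuple[int, ...] = (3, 9, 15),
    informative_sd: float = 1.4,
    response_noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix with a known set of informative single columns (0-based).

    Informative columns have larger variance than the unit-variance nuisance
    columns — as signal-bearing wavelengths do — and the response is their sum
    plus noise, giving a variable-selection search an unambiguous target.
    """
    if any(j < 0 or j >= n_columns for j in informative):
        raise ValueError("informative column indices must be in 0..n_columns-1")
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n_samples, n_columns))
    for j in informative:
        X[:, j] = rng.normal(0.0, informative_sd, size=n_samples)
    y = X[:, list(informative)].sum(axis=1) + rng.normal(0.0, response_noise_sd, size=n_samples)
    return X, y
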