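"""Core spectra container and the plain-CSV dialect used throughout the package.

A :class:`SpectraSet` holds an ``n x m`` absorbance matrix aligned to a strictly
increasing wavelength grid (nm), together with sample identifiers and an
optional response vector (modulus of elasticity, GPa).

The on-disk format is deliberately simple: a header row ``id,<wl1>,<wl2>,...``
followed by one row per sample; responses live in a companion two-column CSV
``id,moe_gpa``.  Round trips preserve values to better than 12 significant
digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "make_wavelength_grid",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_response_csv",
    "write_response_csv",
]


def make_wavelength_grid(start_nm: float, end_nm: float, n_points: int) -> np.ndarray:
    """Uniform wavelength grid from ``start_nm`` to ``end_nm`` inclusive.

    Parameters
    ----------
    start_nm, end_nm : float
        First and last wavelength in nanometres; ``start_nm < end_nm``.
    n_points : int
        Number of grid points, at least 2.

    Returns
    -------
    numpy.ndarray
        Strictly increasing vector of length ``n_points`` whose first element
        is ``start_nm`` and last is ``end_nm``.
    """
    if n_points < 2:
        raise ValueError(f"grid needs at least 2 points, got {n_points}")
    if not start_nm < end_nm:
        raise ValueError(f"start_nm ({start_nm}) must be < end_nm ({end_nm})")
    return np.linspace(float(start_nm), float(end_nm), int(n_points))


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavelength grid must be a 1-D array of length >= 2")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return grid


@dataclass
class SpectraSet:
    """Absorbance spectra for a set of samples on a shared wavelength grid.

    Attributes
    ----------
    sample_ids : list of str
        Unique identifiers, one per row of ``absorbance``.
    grid : numpy.ndarray
        Strictly increasing wavelengths in nm, length ``m``.
    absorbance : numpy.ndarray
        ``n x m`` matrix of absorbance values; all finite.
    response : numpy.ndarray or None
        Optional length-``n`` response vector (MOE, GPa).
    meta : dict
        Free-form provenance (pretreatment parameters, seeds, ...).
    """

    sample_ids: list[str]
    grid: np.ndarray
    absorbance: np.ndarray
    response: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = _validate_grid(self.grid)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, m = self.absorbance.shape
        if m != self.grid.size:
            raise ValueError(
                f"absorbance has {m} columns but the grid has {self.grid.size} wavelengths"
            )
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match the number of spectra")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if self.response.shape != (n,):
                raise ValueError("response length must match the number of spectra")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices) -> "SpectraSet":
        """Row subset (new object; grid and meta are shared semantics, copied refs)."""
        indices = np.asarray(indices, dtype=int)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in indices],
            grid=self.grid,
            absorbance=self.absorbance[indices],
            response=None if self.response is None else self.response[indices],
            meta=dict(self.meta),
        )

    def with_absorbance(self, matrix: np.ndarray, **meta_updates) -> "SpectraSet":
        """Same samples/grid with a replaced absorbance matrix (e.g. after pretreatment)."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return SpectraSet(
            sample_ids=list(self.sample_ids),
            grid=self.grid,
            absorbance=matrix,
            response=None if self.response is None else self.response.copy(),
            meta=meta,
        )


# CSV dialect ---------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless for float64, comfortably beyond 12 significant digits


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write the ``id,<wl1>,<wl2>,...`` dialect."""
    df = pd.DataFrame(spectra.absorbance, columns=[_FLOAT_FMT % w for w in spectra.grid])
    df.insert(0, "id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read the spectra dialect, rejecting malformed files.

    Raises
    ------
    ValueError
        On duplicate sample IDs (with the offending row number), a
        non-increasing wavelength header, ragged rows or non-numeric cells.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first header column must be 'id'")
    ids = df["id"].tolist()
    seen: dict[str, int] = {}
    for row, sid in enumerate(ids, start=2):  # header is line 1
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample ID {sid!r} at row {row} (first at row {seen[sid]})")
        seen[sid] = row
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavelength in header: {exc}") from exc
    if grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValueError(f"{path}: wavelength header must be strictly increasing")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite or non-numeric absorbance values")
    return SpectraSet(sample_ids=ids, grid=grid, absorbance=values)


def write_response_csv(spectra: SpectraSet, path: str | Path) -> None:
    if spectra.response is None:
        raise ValueError("SpectraSet has no response to write")
    pd.DataFrame({"id": spectra.sample_ids, "moe_gpa": spectra.response}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_response_csv(path: str | Path) -> dict[str, float]:
    """Read ``id,moe_gpa`` into an id -> value mapping."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if list(df.columns[:2]) != ["id", "moe_gpa"]:
        raise ValueError(f"{path}: response CSV must have header 'id,moe_gpa'")
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    return dict(zip(df["id"], df["moe_gpa"].astype(float)))
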