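"""Calibration / prediction partitioning with the normalized Kennard-Stone rule.

Pairwise Euclidean distances are divided by the maximum pairwise distance so
that the largest entry is exactly 1 (the "normalized Euclidean distance");
Kennard-Stone then seeds the calibration set with the two most distant samples
and repeatedly adds the sample whose minimum distance to the already-chosen
set is largest, until the calibration set reaches ``ceil(n * r / (r + 1))``
samples for a target ratio ``r : 1``.  The remainder is the prediction set.
The procedure is fully deterministic: ties are broken toward the lowest
sample index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .dataset import SpectraSet

__all__ = [
    "Partition",
    "normalized_distances",
    "partition_sizes",
    "KennardStoneSplitter",
    "ks_partition",
    "write_partition_csv",
]


@dataclass
class Partition:
    """A calibration/prediction split.

    ``calibration_ids`` are in Kennard-Stone selection order; the two sets are
    disjoint and together cover every sample.  ``max_raw_distance`` is the
    normalizing constant (the largest raw pairwise Euclidean distance).
    """

    calibration_ids: list[str]
    prediction_ids: list[str]
    ratio: float
    max_raw_distance: float

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.prediction_ids):
            raise ValueError("calibration and prediction sets must be disjoint")


def normalized_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances scaled so the maximum entry is exactly 1.

    Raises
    ------
    ValueError
        If all samples are identical (zero maximum distance) or X has
        missing values.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")
    D = squareform(pdist(X, metric="euclidean"))
    dmax = D.max()
    if dmax == 0:
        raise ValueError("all samples are identical: maximum pairwise distance is zero")
    return D / dmax


def partition_sizes(n: int, ratio: float) -> tuple[int, int]:
    """Calibration/prediction sizes for an ``n``-sample set at ratio ``ratio : 1``.

    ``n_cal = ceil(n * ratio / (ratio + 1))``; e.g. 125 samples at 2:1 give
    (84, 41).
    """
    if n < 3:
        raise ValueError("need at least 3 samples to partition")
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    n_cal = math.ceil(n * ratio / (ratio + 1.0))
    n_pred = n - n_cal
    if n_pred < 1 or n_cal < 2:
        raise ValueError(f"ratio {ratio} leaves an empty set for n={n}")
    return n_cal, n_pred


def _ks_select(D: np.ndarray, n_cal: int) -> list[int]:
    """Kennard-Stone max-min selection on a distance matrix; lowest-index ties."""
    n = D.shape[0]
    # seed: the pair at maximum distance; np.argmax returns the first (row-major)
    # maximum, i.e. the lexicographically smallest index pair.
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(min(i, j)), int(max(i, j))]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    # min distance of every sample to the current calibration set
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_cal:
        min_dist_masked = np.where(in_set, -np.inf, min_dist)
        k = int(np.argmax(min_dist_masked))  # argmax takes the lowest index on ties
        selected.append(k)
        in_set[k] = True
        min_dist = np.minimum(min_dist, D[k])
    return selected


class KennardStoneSplitter(BaseEstimator):
    """Deterministic Kennard-Stone splitter over normalized spectral distances.

    Parameters
    ----------
    ratio : float, default=2.0
        Target calibration:prediction ratio (2.0 means 2:1).

    Attributes
    ----------
    max_raw_distance_ : float
        Largest raw pairwise Euclidean distance of the last ``split``.
    """

    def __init__(self, ratio: float = 2.0):
        self.ratio = ratio

    def split(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(calibration_indices, prediction_indices)``.

        Calibration indices come in selection order; prediction indices are
        ascending.
        """
        X = np.asarray(X, dtype=float)
        n_cal, _ = partition_sizes(X.shape[0], self.ratio)
        raw = squareform(pdist(X, metric="euclidean"))
        dmax = raw.max()
        if dmax == 0:
            raise ValueError("all samples are identical: Kennard-Stone is undefined")
        self.max_raw_distance_ = float(dmax)
        cal = _ks_select(raw / dmax, n_cal)
        mask = np.ones(X.shape[0], dtype=bool)
        mask[cal] = False
        return np.array(cal, dtype=int), np.flatnonzero(mask)


def ks_partition(spectra: SpectraSet, ratio: float = 2.0) -> Partition:
    """Partition a spectra set 2:1 (or ``ratio``:1) with improved Kennard-Stone."""
    splitter = KennardStoneSplitter(ratio=ratio)
    cal_idx, pred_idx = splitter.split(spectra.absorbance)
    return Partition(
        calibration_ids=[spectra.sample_ids[i] for i in cal_idx],
        prediction_ids=[spectra.sample_ids[i] for i in pred_idx],
        ratio=ratio,
        max_raw_distance=splitter.max_raw_distance_,
    )


def write_partition_csv(partition: Partition, path: str | Path) -> None:
    """Write the ``id,set`` table (set is 'calibration' or 'prediction')."""
    rows = [(sid, "calibration") for sid in partition.calibration_ids] + [
        (sid, "prediction") for sid in partition.prediction_ids
    ]
    pd.DataFrame(rows, columns=["id", "set"]).to_csv(path, index=False)
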