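"""Refined nearest-neighbor spatial statistics for a train/test split.

For a split, three cumulative curves over Tanimoto distance t in [0, 1]
summarize the geometry of the test set:

* G(t)  — fraction of test compounds whose nearest neighbor *in the test set*
          is at distance < t (clustering/clumping of the test set);
* F'(t) — fraction of test compounds whose nearest neighbor *in the training
          set* is at distance < t (how well the training set covers the test
          set);
* S'(t) = G(t) - F'(t).

Each curve is summed over a 100-point grid on [0, 1] (both endpoints
included, spacing 1/99); the sums (0..99, by the strict ``< t`` convention)
are compact summaries: sum G > sum F' means test compounds sit closer to each
other than to the training set, as in real temporal splits.

Distances are 1 - Tanimoto on radius-2 Morgan fingerprints (2048 bits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AssayDataset, Split
from .fingerprints import morgan_fingerprints, tanimoto_matrix

__all__ = [
    "GRID",
    "CdfCurve",
    "SpatialSummary",
    "nn_distances",
    "cdf_sum",
    "spatial_summary",
    "spatial_summary_from_matrix",
]

#: The t grid: 100 evenly spaced points on [0, 1], both endpoints included.
GRID = np.linspace(0.0, 1.0, 100)


@dataclass(frozen=True)
class CdfCurve:
    """An empirical CDF evaluated on the t grid."""

    grid: np.ndarray
    values: np.ndarray

    @property
    def sum(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class SpatialSummary:
    """Grid sums of the G, F' and S' curves, plus the curves themselves."""

    sum_G: float
    sum_Fprime: float
    G: CdfCurve
    Fprime: CdfCurve

    @property
    def sum_Sprime(self) -> float:
        return self.sum_G - self.sum_Fprime


def nn_distances(
    query_fps, reference_fps, *, exclude_self: bool = False
) -> np.ndarray:
    """Nearest-neighbor Tanimoto distance from each query to the reference set.

    With ``exclude_self`` the query and reference sequences must be the same
    set in the same order; each compound's self-match is skipped.
    """
    if exclude_self and len(reference_fps) < 2:
        raise ValueError("exclude_self needs a reference set of at least 2")
    if len(reference_fps) == 0:
        raise ValueError("empty reference set")
    sim = tanimoto_matrix(query_fps, reference_fps)
    dist = 1.0 - sim
    if exclude_self:
        np.fill_diagonal(dist, np.inf)
    return dist.min(axis=1)


def cdf_sum(distances: np.ndarray, grid: np.ndarray = GRID) -> tuple[CdfCurve, float]:
    """Empirical CDF of distances on the grid (strict ``< t``) and its sum."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("no distances given")
    if np.any((distances < 0) | (distances > 1)):
        raise ValueError("distances must lie in [0, 1]")
    values = (distances[None, :] < grid[:, None]).mean(axis=1)
    curve = CdfCurve(grid, values)
    return curve, curve.sum


def _masked_summary(dist: np.ndarray, test_idx: np.ndarray, train_idx: np.ndarray) -> SpatialSummary:
    sub = dist[np.ix_(test_idx, test_idx)].copy()
    np.fill_diagonal(sub, np.inf)
    g_dist = sub.min(axis=1)
    f_dist = dist[np.ix_(test_idx, train_idx)].min(axis=1)
    g_curve, g_sum = cdf_sum(g_dist)
    f_curve, f_sum = cdf_sum(f_dist)
    return SpatialSummary(g_sum, f_sum, g_curve, f_curve)


def spatial_summary(split: Split, dataset: AssayDataset) -> SpatialSummary:
    """G / F' / S' grid sums for a split of a dataset."""
    test_idx = split.test_index(dataset)
    train_idx = split.train_index(dataset)
    if len(test_idx) < 2 or len(train_idx) < 1:
        raise ValueError("need |test| >= 2 and |train| >= 1")
    fps = morgan_fingerprints(dataset.smiles, radius=2)
    dist = 1.0 - tanimoto_matrix(fps)
    return _masked_summary(dist, test_idx, train_idx)


def spatial_summary_from_matrix(
    dist: np.ndarray, test_idx: np.ndarray, train_idx: np.ndarray
) -> SpatialSummary:
    """As :func:`spatial_summary` but on a precomputed full distance matrix.

    Used by the GA, which evaluates thousands of candidate splits of one
    dataset and computes the n x n Tanimoto distance matrix once.
    """
    if len(test_idx) < 2 or len(train_idx) < 1:
        raise ValueError("need |test| >= 2 and |train| >= 1")
    return _masked_summary(dist, np.asarray(test_idx), np.asarray(train_idx))
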