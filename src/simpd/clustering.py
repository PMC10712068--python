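"""Taylor-Butina clustering, small-cluster merging and test-set cluster entropy.

Exclusion-sphere (Taylor-Butina) clustering picks the compound with the most
neighbors at Tanimoto >= threshold as a cluster centroid, assigns the
centroid plus its unassigned neighbors to a new cluster and repeats on the
remainder, with neighbor counts refreshed after every round (the "reordering"
variant). For the simulated-time-split GA the clustering uses radius-3 Morgan
fingerprints at a 0.35 similarity threshold; singletons and clusters smaller
than 2 % of the dataset are then merged into their closest large cluster.

The relative cluster-population entropy of a test set — Shannon entropy of
its cluster histogram divided by log2(number of clusters) — is the GA's
diversity constraint: 0 means one cluster holds every test compound, 1 means
a perfectly even spread.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data import AssayDataset
from .fingerprints import morgan_fingerprints, tanimoto_matrix

__all__ = [
    "Clustering",
    "taylor_butina",
    "taylor_butina_from_matrix",
    "merge_small_clusters",
    "cluster_dataset",
    "relative_entropy",
]

CLUSTER_FP_RADIUS = 3
CLUSTER_SIM_THRESHOLD = 0.35
SMALL_CLUSTER_FRAC = 0.02


@dataclass(frozen=True)
class Clustering:
    """A partition of dataset positions into clusters.

    ``assignment[i]`` is the cluster id of compound position ``i``; ids are
    contiguous ``0 .. n_clusters-1`` in centroid-discovery order.
    """

    assignment: np.ndarray
    n_clusters: int

    def __post_init__(self):
        a = np.asarray(self.assignment)
        if a.size and (a.min() < 0 or a.max() >= self.n_clusters):
            raise ValueError("cluster ids out of range")
        present = np.unique(a)
        if len(present) != self.n_clusters:
            raise ValueError("empty cluster id in assignment")

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignment) == cluster_id)

    def sizes(self) -> np.ndarray:
        return np.bincount(np.asarray(self.assignment), minlength=self.n_clusters)


def taylor_butina_from_matrix(sim: np.ndarray, similarity_threshold: float = CLUSTER_SIM_THRESHOLD) -> Clustering:
    """Exclusion-sphere clustering on a precomputed similarity matrix.

    Ties on neighbor count are broken by the lowest compound index.
    """
    n = sim.shape[0]
    neighbor = np.asarray(sim) >= similarity_threshold
    np.fill_diagonal(neighbor, False)

    unassigned = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=np.intp)
    cluster_id = 0
    while unassigned.any():
        # count unassigned neighbors among unassigned compounds only
        counts = np.where(unassigned, neighbor[:, unassigned].sum(axis=1), -1)
        centroid = int(np.argmax(counts))  # argmax returns the lowest index on ties
        members = np.flatnonzero(neighbor[centroid] & unassigned)
        assignment[centroid] = cluster_id
        assignment[members] = cluster_id
        unassigned[centroid] = False
        unassigned[members] = False
        cluster_id += 1
    return Clustering(assignment, cluster_id)


def taylor_butina(
    dataset: AssayDataset,
    similarity_threshold: float = CLUSTER_SIM_THRESHOLD,
    fp_radius: int = CLUSTER_FP_RADIUS,
) -> Clustering:
    """Taylor-Butina clustering of a dataset (radius-3 fingerprints by default)."""
    fps = morgan_fingerprints(dataset.smiles, radius=fp_radius)
    return taylor_butina_from_matrix(tanimoto_matrix(fps), similarity_threshold)


def merge_small_clusters(
    clustering: Clustering,
    sim: np.ndarray,
    min_frac: float = SMALL_CLUSTER_FRAC,
) -> Clustering:
    """Absorb small clusters (size < ``min_frac`` * n) into large ones.

    Each compound of a small cluster moves, individually, to the large
    cluster containing its most similar compound (single linkage on the same
    fingerprints used for clustering); ties go to the lowest cluster id.
    Cluster ids are re-compacted afterwards. If no cluster reaches the size
    floor the clustering is returned unchanged with a warning.
    """
    n = len(clustering.assignment)
    sizes = clustering.sizes()
    large = np.flatnonzero(sizes >= min_frac * n)
    small = np.flatnonzero(sizes < min_frac * n)
    if len(small) == 0:
        return clustering
    if len(large) == 0:
        warnings.warn(
            "no cluster reaches the size floor; skipping small-cluster merging",
            stacklevel=2,
        )
        return clustering

    assignment = np.asarray(clustering.assignment).copy()
    large_members = {int(c): clustering.members(int(c)) for c in large}
    for c in small:
        for i in clustering.members(int(c)):
            best, best_sim = None, -1.0
            for lc in large:  # ascending cluster id, so ties keep the lowest
                s = float(sim[i, large_members[int(lc)]].max())
                if s > best_sim:
                    best, best_sim = int(lc), s
            assignment[i] = best

    # re-compact ids, preserving the order of the surviving clusters
    remap = {int(c): k for k, c in enumerate(sorted(large))}
    assignment = np.array([remap[int(c)] for c in assignment], dtype=np.intp)
    return Clustering(assignment, len(large))


def cluster_dataset(
    dataset: AssayDataset,
    similarity_threshold: float = CLUSTER_SIM_THRESHOLD,
    fp_radius: int = CLUSTER_FP_RADIUS,
    min_frac: float = SMALL_CLUSTER_FRAC,
) -> Clustering:
    """Taylor-Butina clustering followed by small-cluster merging."""
    fps = morgan_fingerprints(dataset.smiles, radius=fp_radius)
    sim = tanimoto_matrix(fps)
    return merge_small_clusters(taylor_butina_from_matrix(sim, similarity_threshold), sim, min_frac)


def relative_entropy(test_idx: Iterable[int], clustering: Clustering) -> float:
    """Shannon entropy of the test set's cluster histogram / log2(n_clusters).

    0.0 when all test compounds share one cluster; 1.0 when they spread
    evenly over all clusters. Defined as 0.0 for a single-cluster clustering.
    """
    test_idx = np.asarray(list(test_idx), dtype=np.intp)
    if test_idx.size == 0:
        raise ValueError("empty test set")
    if clustering.n_clusters == 1:
        return 0.0
    counts = np.bincount(
        np.asarray(clustering.assignment)[test_idx], minlength=clustering.n_clusters
    )
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return entropy / math.log2(clustering.n_clusters) + 0.0  # normalize -0.0
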