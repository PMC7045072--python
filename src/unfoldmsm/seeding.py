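"""Clustering of biased ensembles and seeding of unbiased runs.

Metadynamics trajectories span the unfolding pathway but their frame
statistics are biased.  This module converts them into representative
conformations — average-linkage hierarchical clustering with a distance
cutoff, one medoid per cluster — and launches fresh unbiased Langevin runs
from those medoids with new Maxwell–Boltzmann velocities.  The seeded pool
deliberately misrepresents equilibrium populations; only the downstream
Markov-state-model reweighting (:mod:`unfoldmsm.msm`) removes that bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .langevin import LangevinParams, Trajectory, _derive_seed, integrate_langevin
from .potentials import InvalidInputError, PotentialSpec


@dataclass
class ClusterResult:
    """Flat clustering of frames from an average-linkage dendrogram cut."""

    assignments: np.ndarray       # 0-based cluster label per frame
    representatives: np.ndarray   # frame index of each cluster's medoid
    linkage: np.ndarray           # scipy linkage matrix (merge history)
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


@dataclass
class SeedSet:
    """Starting structures for unbiased seeded runs, one per cluster."""

    seeds: np.ndarray             # (n_seeds, ndim) medoid coordinates
    source_clusters: np.ndarray   # cluster id per seed
    run_length: int
    rng_seeds: np.ndarray         # pairwise-distinct per-seed RNG seeds


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two (n_atoms, 3) frames over rigid motions."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def pairwise_distance_matrix(frames, metric: str = "euclidean") -> np.ndarray:
    """Symmetric all-vs-all distance matrix between frames.

    ``euclidean`` works on flattened coordinates; ``aligned_rmsd``
    optimally superimposes each pair (Kabsch) before computing the RMSD,
    so the result is invariant under global rotations and translations.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim < 2 or frames.shape[0] < 2:
        raise InvalidInputError("need >= 2 frames of equal shape")
    if metric == "euclidean":
        flat = frames.reshape(frames.shape[0], -1)
        return squareform(pdist(flat, metric="euclidean"))
    if metric == "aligned_rmsd":
        if frames.ndim == 2:
            if frames.shape[1] % 3:
                raise InvalidInputError("aligned_rmsd needs (n, n_atoms, 3) frames")
            frames = frames.reshape(frames.shape[0], -1, 3)
        n = frames.shape[0]
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = _kabsch_rmsd(frames[i], frames[j])
        return out
    raise InvalidInputError(f"unknown metric {metric!r}")


def cluster_conformations(frames, cutoff: float,
                          metric: str = "euclidean") -> ClusterResult:
    """Average-linkage agglomerative clustering cut at ``cutoff``.

    Representatives are medoids: the member with the smallest mean distance
    to its co-members (ties broken by lowest frame index).  Deterministic
    given the input order.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0:
        raise InvalidInputError("empty input")
    n = frames.shape[0]
    if n == 1:
        return ClusterResult(np.zeros(1, dtype=int), np.zeros(1, dtype=int),
                             np.empty((0, 4)), cutoff)
    dmat = pairwise_distance_matrix(frames, metric)
    z = linkage(squareform(dmat, checks=False), method="average")
    labels = fcluster(z, t=cutoff, criterion="distance") - 1
    # relabel clusters by order of first appearance for determinism
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels], dtype=int)
    reps = np.empty(labels.max() + 1, dtype=int)
    for c in range(labels.max() + 1):
        members = np.flatnonzero(labels == c)
        sub = dmat[np.ix_(members, members)]
        reps[c] = members[int(np.argmin(sub.mean(axis=1)))]
    return ClusterResult(labels, reps, z, cutoff)


def subsample_frames(frames, max_frames: int = 5000) -> np.ndarray:
    """Uniform-stride subsampling indices keeping at most ``max_frames``."""
    n = np.asarray(frames).shape[0]
    stride = max(1, int(np.ceil(n / max_frames)))
    return np.arange(0, n, stride)


def build_seed_set(clusters: ClusterResult, frames, run_length: int,
                   rng_base_seed: int) -> SeedSet:
    """One seed per cluster at the medoid, with derived distinct RNG seeds.

    Velocities are *not* inherited: the integrator draws fresh
    Maxwell–Boltzmann velocities for every seeded run.
    """
    frames = np.asarray(frames, dtype=float)
    if clusters.n_clusters == 0:
        raise InvalidInputError("empty cluster result")
    seeds = frames[clusters.representatives].reshape(clusters.n_clusters, -1)
    rng_seeds = np.array(
        [_derive_seed(rng_base_seed, 2000 + c) for c in range(clusters.n_clusters)],
        dtype=np.int64)
    return SeedSet(seeds=seeds,
                   source_clusters=np.arange(clusters.n_clusters),
                   run_length=int(run_length), rng_seeds=rng_seeds)


def run_seeded(seed_set: SeedSet, spec: PotentialSpec,
               lparams: LangevinParams) -> list[Trajectory]:
    """Unbiased runs from every seed, tagged with their source cluster."""
    out = []
    for k in range(seed_set.seeds.shape[0]):
        p = replace(lparams, n_steps=seed_set.run_length,
                    seed=int(seed_set.rng_seeds[k]))
        traj = integrate_langevin(spec, p, seed_set.seeds[k])
        traj.provenance.update(source_cluster=int(seed_set.source_clusters[k]),
                               bias_applied=False)
        out.append(traj)
    return out
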