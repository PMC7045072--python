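"""Folded-state flexibility descriptors.

Metrics used to compare the native-state ensembles of graded-stability
variants: per-frame native-contact counts and the Shannon entropy of their
distribution, per-particle RMSF after rigid-body alignment, all-vs-all
2D-RMSD, principal component analysis on the pooled multi-variant data,
and free-energy surfaces over the leading two PCs (uniform or
MSM-stationary frame weights).

Entropies are reported in J/(mol K): the Shannon entropy of the discrete
contact-count distribution in nats, multiplied by the gas constant R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .potentials import InvalidInputError
from .seeding import pairwise_distance_matrix

R_GAS = 8.31446261815324  # J / (mol K)


class NoNativeContactsError(ValueError):
    """Raised when no candidate pair is formed in the reference frame."""


class UndefinedFluctuationError(ValueError):
    """Raised when RMSF is requested for fewer than two frames."""


class InvalidWeightsError(ValueError):
    """Raised for negative or all-zero frame weights."""


@dataclass(frozen=True)
class ContactDefinition:
    """Candidate donor–acceptor pairs and the formation cutoff.

    A pair is *formed* when its distance is strictly below ``cutoff``
    (boundary-equal distances are not contacts); it is *native* when it is
    formed in the reference frame.
    """

    pair_list: tuple
    cutoff: float
    strict_less_than: bool = True

    def __post_init__(self):
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")
        pairs = [tuple(p) for p in self.pair_list]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pairs in pair_list")


@dataclass
class ContactSeries:
    """Per-frame formed-native-contact counts out of ``n_total`` pairs."""

    counts: np.ndarray
    n_total: int


@dataclass
class EntropyResult:
    """Shannon entropy of a contact-count distribution."""

    S: float                      # J / (mol K)
    probabilities: np.ndarray     # over integer counts 0..n_total
    support: np.ndarray


@dataclass
class PCAProjection:
    eigenvectors: np.ndarray      # (n_features, n_components), columns PC1..
    eigenvalues: np.ndarray       # descending, all components
    mean: np.ndarray
    projections: dict             # label -> (n_frames, n_components)


@dataclass
class FESurface2D:
    """Free energy over a 2D bin grid; unoccupied bins are NaN-flagged."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    weights_source: str = "uniform"


def _pair_distances(frames: np.ndarray, pairs) -> np.ndarray:
    i = np.array([p[0] for p in pairs])
    j = np.array([p[1] for p in pairs])
    d = frames[:, i, :] - frames[:, j, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def native_contacts(frames, definition: ContactDefinition,
                    reference) -> ContactSeries:
    """Per-frame count of formed native contacts.

    The reference frame filters the candidate list: only pairs formed in
    the reference are native and counted; ``n_total`` is the size of that
    filtered list.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames.reshape(frames.shape[0], -1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    pairs = [tuple(p) for p in definition.pair_list]
    for i, j in pairs:
        if not (0 <= i < reference.shape[0] and 0 <= j < reference.shape[0]):
            raise InvalidInputError(f"pair ({i}, {j}) out of range")
    ref_d = _pair_distances(reference[None], pairs)[0]
    native = ref_d < definition.cutoff if definition.strict_less_than \
        else ref_d <= definition.cutoff
    native_pairs = [p for p, ok in zip(pairs, native) if ok]
    if not native_pairs:
        raise NoNativeContactsError(
            "no candidate pair is formed in the reference frame")
    d = _pair_distances(frames, native_pairs)
    formed = d < definition.cutoff if definition.strict_less_than \
        else d <= definition.cutoff
    return ContactSeries(counts=formed.sum(axis=1).astype(int),
                         n_total=len(native_pairs))


def shannon_entropy(series: ContactSeries) -> EntropyResult:
    """S = -R sum_k p_k ln p_k over integer contact-count bins."""
    counts = np.asarray(series.counts)
    if counts.size == 0:
        raise InvalidInputError("empty contact series")
    support = np.arange(series.n_total + 1)
    hist = np.bincount(counts, minlength=series.n_total + 1).astype(float)
    p = hist / hist.sum()
    nz = p > 0
    s_nats = -np.sum(p[nz] * np.log(p[nz]))
    return EntropyResult(S=float(R_GAS * s_nats), probabilities=p,
                         support=support)


def _align_to(frame: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigid-body superposition of one (n, 3) frame onto ``ref``."""
    mu_f, mu_r = frame.mean(axis=0), ref.mean(axis=0)
    fc, rc = frame - mu_f, ref - mu_r
    h = fc.T @ rc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return fc @ rot.T + mu_r


def rmsf(frames, align_reference=None, align: bool = True) -> np.ndarray:
    """Per-particle root-mean-square fluctuation about the mean structure.

    Frames are rigid-body aligned to ``align_reference`` (default: first
    frame) before the fluctuations are measured, so global rotation and
    translation do not register as flexibility.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        if frames.shape[1] % 3:
            # 1D / feature coordinates: treat each column as a particle
            frames = frames[:, :, None]
        else:
            frames = frames.reshape(frames.shape[0], -1, 3)
    if frames.shape[0] < 2:
        raise UndefinedFluctuationError("RMSF needs >= 2 frames")
    if align and frames.shape[-1] == 3:
        ref = (np.asarray(align_reference, dtype=float).reshape(-1, 3)
               if align_reference is not None else frames[0])
        frames = np.stack([_align_to(f, ref) for f in frames])
    mean = frames.mean(axis=0)
    dev = frames - mean
    return np.sqrt(np.mean(np.sum(dev * dev, axis=-1), axis=0))


def rmsd_matrix(frames) -> np.ndarray:
    """All-vs-all pairwise RMSD after optimal superposition (2D-RMSD)."""
    return pairwise_distance_matrix(frames, metric="aligned_rmsd")


def combined_pca(feature_sets: dict, n_components: int = 2) -> PCAProjection:
    """PCA on the pooled per-variant feature matrices.

    The eigenbasis is fitted on the concatenation of all variants (so the
    projections share one coordinate system) and each variant's frames are
    projected separately.
    """
    labels = list(feature_sets)
    mats = [np.asarray(feature_sets[k], dtype=float) for k in labels]
    dims = {m.shape[1] for m in mats}
    if len(dims) != 1:
        raise InvalidInputError("inconsistent feature dimensionality")
    pooled = np.concatenate(mats, axis=0)
    if pooled.shape[0] < n_components:
        raise InvalidInputError("fewer pooled frames than components")
    mean = pooled.mean(axis=0)
    cov = np.cov(pooled - mean, rowvar=False, bias=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for k in range(evecs.shape[1]):
        imax = np.argmax(np.abs(evecs[:, k]))
        if evecs[imax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    comp = evecs[:, :n_components]
    projections = {k: (m - mean) @ comp for k, m in zip(labels, mats)}
    return PCAProjection(eigenvectors=comp, eigenvalues=evals, mean=mean,
                         projections=projections)


def free_energy_surface(coords, weights=None, kT: float = 1.0,
                        bins: int = 40, ranges=None,
                        weights_source: str = "uniform") -> FESurface2D:
    """2D free-energy surface F = -kT ln(weighted bin density), min-shifted.

    ``coords`` is an (n, 2) array (e.g. PC1/PC2 projections).  Uniform
    weights give the plain-histogram surface; MSM stationary weights give
    the bias-corrected surface.  Unoccupied bins are NaN, not zero.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InvalidInputError("coords must be (n, 2)")
    if weights is None:
        weights = np.ones(coords.shape[0])
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != coords.shape[0]:
        raise InvalidWeightsError("one weight per frame required")
    if np.any(weights < 0) or not np.any(weights > 0):
        raise InvalidWeightsError("weights must be nonnegative and not all zero")
    hist, xe, ye = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins,
                                  range=ranges, weights=weights)
    with np.errstate(divide="ignore"):
        F = -kT * np.log(hist / weights.sum())
    F[~np.isfinite(F)] = np.nan
    F = F - np.nanmin(F)
    return FESurface2D(x_edges=xe, y_edges=ye, F=F,
                       weights_source=weights_source)
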