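"""Markov-state-model estimation, validation and kinetic analysis.

The pipeline this module serves pools many short, unbiased seeded
trajectories whose raw frame statistics misrepresent equilibrium (the
seeding bias).  A reversible Markov state model removes that bias: local
transition statistics between microstates are stitched into a global
stationary distribution, from which state populations, relaxation
timescales, mean first-passage times, committors and reactive fluxes
follow.

Estimation chain: tICA featurization -> k-means microstates -> sliding
window transition counts at a lag -> largest strongly connected set ->
reversible maximum-likelihood transition matrix -> PCCA+ macrostates.
Validation: implied timescales vs lag, Chapman-Kolmogorov test, and a
per-row Dirichlet posterior sampler for uncertainties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


class ConnectivityError(ValueError):
    pass


class RankError(ValueError):
    pass


class DegenerateClusteringError(ValueError):
    pass


class EstimatorMismatchError(ValueError):
    pass


class InvalidSetsError(ValueError):
    pass


class ReferenceLostError(ValueError):
    pass


class InvalidRequestError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tICA
# ---------------------------------------------------------------------------

@dataclass
class TICAModel:
    """Solution of the time-lagged generalized eigenproblem Ct v = l C0 v."""

    lag: int
    mean: np.ndarray
    C0: np.ndarray
    Ct: np.ndarray                # symmetrized
    eigenvalues: np.ndarray       # descending
    components: np.ndarray        # columns, C0-orthonormal
    epsilon: float


def _as_traj_list(features) -> list[np.ndarray]:
    if isinstance(features, np.ndarray) and features.ndim == 2:
        return [features]
    return [np.atleast_2d(np.asarray(f, dtype=float)) for f in features]


def tica_fit(features, lag: int, epsilon_scale: float = 1e-6) -> TICAModel:
    """Fit time-lagged independent components at integer lag (in frames).

    Covariances are symmetrized, ``C0`` is regularized by
    ``epsilon_scale * largest C0 eigenvalue`` on the diagonal, and the
    eigenproblem is solved in the whitened basis.  Components are scaled
    C0-orthonormal; eigenvalues are autocorrelations of the components.
    """
    trajs = [t for t in _as_traj_list(features) if t.shape[0] >= lag + 2]
    if not trajs:
        raise InsufficientDataError("no trajectory longer than lag + 1")
    if any(not np.all(np.isfinite(t)) for t in trajs):
        raise InsufficientDataError("non-finite features")
    d = trajs[0].shape[1]
    mean = np.zeros(d)
    n = 0
    for t in trajs:
        mean += t.sum(axis=0)
        n += t.shape[0]
    mean /= n
    C0 = np.zeros((d, d))
    Ct = np.zeros((d, d))
    npairs = 0
    for t in trajs:
        x = t - mean
        a = x[:-lag] if lag > 0 else x
        b = x[lag:] if lag > 0 else x
        C0 += 0.5 * (a.T @ a + b.T @ b)
        Ct += 0.5 * (a.T @ b + b.T @ a)
        npairs += a.shape[0]
    C0 /= npairs
    Ct /= npairs
    ev0 = np.linalg.eigvalsh(C0)
    eps = epsilon_scale * max(ev0.max(), 0.0)
    C0r = C0 + eps * np.eye(d)
    ev0r, U = np.linalg.eigh(C0r)
    if ev0r.min() <= 0 or ev0r.min() / ev0r.max() < 1e-14:
        raise RankError("C0 is singular after regularization")
    W = U @ np.diag(ev0r ** -0.5) @ U.T          # C0^{-1/2}
    M = W @ Ct @ W
    M = 0.5 * (M + M.T)
    lam, V = np.linalg.eigh(M)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    comp = W @ V
    for k in range(comp.shape[1]):               # deterministic sign
        imax = np.argmax(np.abs(comp[:, k]))
        if comp[imax, k] < 0:
            comp[:, k] = -comp[:, k]
    return TICAModel(lag=lag, mean=mean, C0=C0, Ct=Ct, eigenvalues=lam,
                     components=comp, epsilon=eps)


def tica_transform(model: TICAModel, features) -> list[np.ndarray] | np.ndarray:
    single = isinstance(features, np.ndarray) and features.ndim == 2
    out = [(np.asarray(t, dtype=float) - model.mean) @ model.components
           for t in _as_traj_list(features)]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    centers: np.ndarray
    dtrajs: list
    seed: int


def default_n_microstates(n_frames: int, k_max: int = 100) -> int:
    """The protocol's 100 microstates, scaled down for small data sets."""
    return int(max(2, min(k_max, n_frames // 50)))


def kmeans_discretize(projected, k: int, seed: int = 0,
                      max_fit_frames: int = 200_000) -> Discretization:
    """k-means microstates in the projected (tICA) space; deterministic.

    Centers are fitted on at most ``max_fit_frames`` uniformly strided
    frames (k-means cost, not assignment, dominates); every frame is then
    assigned to its nearest center.
    """
    trajs = _as_traj_list(projected)
    pooled = np.concatenate(trajs, axis=0)
    n_distinct = np.unique(pooled, axis=0).shape[0]
    if k > n_distinct:
        raise DegenerateClusteringError(
            f"k={k} exceeds {n_distinct} distinct points")
    stride = max(1, int(np.ceil(pooled.shape[0] / max_fit_frames)))
    km = KMeans(n_clusters=k, random_state=int(seed), n_init=4)
    km.fit(pooled[::stride])
    labels = km.predict(pooled)
    dtrajs, at = [], 0
    for t in trajs:
        dtrajs.append(labels[at:at + t.shape[0]].astype(np.int64))
        at += t.shape[0]
    return Discretization(centers=km.cluster_centers_, dtrajs=dtrajs,
                          seed=int(seed))


# ---------------------------------------------------------------------------
# counting and estimation
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    lag: int
    counts: np.ndarray            # full (n_states, n_states) sliding-window
    active_set: np.ndarray        # original labels in the largest SCC
    trimmed: bool

    @property
    def active_counts(self) -> np.ndarray:
        return self.counts[np.ix_(self.active_set, self.active_set)]


def count_transitions(dtrajs, lag: int) -> CountMatrix:
    """Sliding-window transition counts and the largest strongly
    connected set of the count graph; states outside it are trimmed."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in
              (dtrajs if not isinstance(dtrajs, np.ndarray) else [dtrajs])]
    usable = [d for d in dtrajs if d.shape[0] > lag]
    if not usable:
        raise InsufficientDataError(f"all trajectories shorter than lag {lag}")
    n = int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((n, n), dtype=np.int64)
    for d in usable:
        np.add.at(C, (d[:-lag], d[lag:]), 1)
    adj = csr_matrix((C > 0).astype(np.int8))
    ncomp, labels = connected_components(adj, directed=True, connection="strong")
    # ignore states never visited at this lag
    visited = (C.sum(axis=0) + C.sum(axis=1)) > 0
    best, best_key = None, None
    for c in range(ncomp):
        members = np.flatnonzero((labels == c) & visited)
        if members.size == 0:
            continue
        key = (members.size, int(C[np.ix_(members, members)].sum()))
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best is None:
        raise InsufficientDataError("no transitions observed")
    trimmed = best.size < int(visited.sum())
    if trimmed:
        logger.info("trimmed %d of %d visited states outside the largest "
                    "strongly connected set", int(visited.sum()) - best.size,
                    int(visited.sum()))
    return CountMatrix(lag=lag, counts=C, active_set=best, trimmed=trimmed)


def reversible_mle(C: np.ndarray, tol: float = 1e-12,
                   maxiter: int = 100000) -> tuple[np.ndarray, np.ndarray]:
    """Reversible maximum-likelihood transition matrix.

    Fixed-point iteration on the unnormalized reversible flux x_ij:
    ``x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)``, converged when the
    stationary distribution stops changing.  Returns (T, pi).
    """
    C = np.asarray(C, dtype=float)
    cs = C + C.T
    ci = C.sum(axis=1)
    x = cs / cs.sum()
    mask = cs > 0
    for _ in range(maxiter):
        xi = x.sum(axis=1)
        q = ci / xi
        denom = q[:, None] + q[None, :]
        x_new = np.where(mask, cs / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        pi_old, pi_new = xi, x_new.sum(axis=1)
        x = x_new
        if np.max(np.abs(pi_new - pi_old / pi_old.sum())) < tol:
            break
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    return T, xi / xi.sum()


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix on the active set, with spectrum."""

    T: np.ndarray
    pi: np.ndarray
    lag: int
    estimator: str
    active_set: np.ndarray
    dt_per_frame: float = 1.0
    posterior_samples: Optional[np.ndarray] = None   # (n_samples, n, n)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self, k: Optional[int] = None) -> np.ndarray:
        lam = _sorted_eigenvalues(self.T, self.pi, self.estimator)
        return lam if k is None else lam[:k]

    def timescales(self, k: Optional[int] = None) -> np.ndarray:
        """Implied timescales -lag*dt/ln|l_i| for i >= 2."""
        lam = self.eigenvalues(None if k is None else k + 1)[1:]
        out = np.full(lam.shape, np.inf)
        good = np.abs(lam) < 1.0 - 1e-12
        with np.errstate(divide="ignore"):
            out[good] = -self.lag * self.dt_per_frame / np.log(np.abs(lam[good]))
        return out


def _sorted_eigenvalues(T, pi, estimator):
    if estimator == "reversible_mle":
        d = np.sqrt(pi)
        S = (d[:, None] * T) / d[None, :]
        lam = np.linalg.eigvalsh(0.5 * (S + S.T))
        return lam[::-1]
    lam = np.linalg.eigvals(T)
    return lam[np.argsort(-np.abs(lam))]


def estimate_transition_matrix(counts: CountMatrix,
                               estimator: str = "reversible_mle",
                               dt_per_frame: float = 1.0) -> TransitionModel:
    """Estimate T on the largest connected set.

    ``nonreversible`` row-normalizes the counts; ``reversible_mle``
    maximizes the reversible likelihood (detailed balance holds exactly).
    """
    C = counts.active_counts.astype(float)
    if C.size == 0:
        raise ConnectivityError("empty connected set")
    if estimator == "nonreversible":
        rows = C.sum(axis=1)
        if np.any(rows == 0):
            raise ConnectivityError("state with no outgoing counts")
        T = C / rows[:, None]
        pi = stationary_distribution_matrix(T)
    elif estimator == "reversible_mle":
        T, pi = reversible_mle(C)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return TransitionModel(T=T, pi=pi, lag=counts.lag, estimator=estimator,
                           active_set=counts.active_set,
                           dt_per_frame=dt_per_frame)


def stationary_distribution_matrix(T: np.ndarray) -> np.ndarray:
    """Left unit eigenvector of a row-stochastic matrix, normalized."""
    T = np.asarray(T, dtype=float)
    lam, V = np.linalg.eig(T.T)
    near1 = np.abs(lam - 1.0) < 1e-8
    if near1.sum() == 0:
        raise ConnectivityError("no unit eigenvalue")
    if near1.sum() > 1:
        raise ConnectivityError("unit eigenvalue is not simple (reducible T)")
    v = np.real(V[:, np.argmax(near1)])
    v = np.abs(v)
    return v / v.sum()


def stationary_distribution(model: TransitionModel) -> np.ndarray:
    return stationary_distribution_matrix(model.T)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def implied_timescales(dtrajs, lags: Sequence[int], n_timescales: int = 3,
                       dt_per_frame: float = 1.0,
                       estimator: str = "reversible_mle") -> pd.DataFrame:
    """Implied timescales t_i(tau) per candidate lag, in physical time.

    Lags with insufficient data are kept in the table and flagged rather
    than silently dropped.
    """
    rows = []
    for lag in lags:
        row = {"lag": lag, "flagged": False}
        try:
            cm = count_transitions(dtrajs, lag)
            model = estimate_transition_matrix(cm, estimator,
                                               dt_per_frame=dt_per_frame)
            ts = model.timescales(n_timescales)
            for i in range(n_timescales):
                row[f"t{i + 2}"] = ts[i] if i < ts.size else np.nan
        except (InsufficientDataError, ConnectivityError):
            row["flagged"] = True
            for i in range(n_timescales):
                row[f"t{i + 2}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def bayesian_samples(counts: CountMatrix, n_samples: int,
                     seed: int = 0) -> np.ndarray:
    """Posterior transition-matrix samples from per-row Dirichlet laws.

    Each row of the count matrix gets an independent Dirichlet posterior
    over its observed transitions (zero-count entries stay zero).  Sliding
    window counts at lag tau overlap, so the Dirichlet concentration uses
    the effective counts ``C / lag``; without this correction the posterior
    is overconfident by roughly a factor sqrt(lag).  Simple, reproducible,
    and adequate for interval estimates; the reversible MLE remains the
    point estimate.
    """
    if n_samples < 2:
        raise InvalidRequestError("n_samples must be >= 2")
    C = counts.active_counts.astype(float) / max(1, counts.lag)
    rng = np.random.default_rng(seed)
    n = C.shape[0]
    out = np.zeros((n_samples, n, n))
    for i in range(n):
        nz = np.flatnonzero(C[i] > 0)
        g = rng.gamma(shape=C[i, nz], size=(n_samples, nz.size))
        out[:, i, nz] = g / g.sum(axis=1, keepdims=True)
    return out


def sample_stationary_distributions(samples: np.ndarray) -> np.ndarray:
    """Stationary distribution of every posterior sample."""
    out = np.empty((samples.shape[0], samples.shape[1]))
    for k in range(samples.shape[0]):
        out[k] = stationary_distribution_matrix(samples[k])
    return out


def _setset_prob(T: np.ndarray, pi: np.ndarray, A, B) -> float:
    """pi-weighted probability of being in B after one application of T,
    starting from the stationary distribution restricted to A."""
    pa = pi[A] / pi[A].sum()
    return float(pa @ T[np.ix_(A, B)].sum(axis=1))


def chapman_kolmogorov_test(dtrajs, model: TransitionModel, macro,
                            factors: Sequence[int] = (1, 2, 4),
                            n_samples: int = 100, seed: int = 0,
                            level: float = 0.95) -> pd.DataFrame:
    """Chapman-Kolmogorov test on macrostate sets.

    Compares the propagated model ``T(tau)^k`` against a re-estimated
    ``T(k tau)`` for every (macro pair, factor), with a Bayesian band from
    posterior samples of the base model.  Returns one row per cell with a
    ``within_band`` verdict; factors with insufficient data are flagged.
    """
    sets = [np.flatnonzero(macro.crisp_assignment == m)
            for m in range(macro.n_macrostates)]
    alpha = 0.5 * (1.0 - level)
    rows = []
    for k in factors:
        Tk = np.linalg.matrix_power(model.T, k)
        try:
            cm_k = count_transitions(dtrajs, k * model.lag)
            mk = estimate_transition_matrix(cm_k, model.estimator)
            samples_k = bayesian_samples(cm_k, n_samples, seed)
        except (InsufficientDataError, ConnectivityError):
            cm_k = None
        for a in range(len(sets)):
            for b in range(len(sets)):
                pred = _setset_prob(Tk, model.pi, sets[a], sets[b])
                row = {"factor": k, "from": a, "to": b, "predicted": pred,
                       "flagged": cm_k is None}
                mapped = (None if cm_k is None else
                          _map_sets(model, cm_k, sets[a], sets[b]))
                if mapped is None:
                    row.update(estimated=np.nan, lo=np.nan, hi=np.nan,
                               within_band=False, flagged=True)
                else:
                    A_k, B_k, pi_k = mapped
                    est = _setset_prob(mk.T, pi_k, A_k, B_k)
                    band = np.array([_setset_prob(s, pi_k, A_k, B_k)
                                     for s in samples_k])
                    lo, hi = np.quantile(band, [alpha, 1.0 - alpha])
                    pad = 1e-9
                    row.update(estimated=est, lo=lo, hi=hi,
                               within_band=bool(lo - pad <= pred <= hi + pad))
                rows.append(row)
    return pd.DataFrame(rows)


def _map_sets(model: TransitionModel, cm_k: CountMatrix, A, B):
    """Map base-model macrostate sets onto the active set of the model
    re-estimated at a longer lag, carrying the base stationary weights."""
    base_labels = model.active_set
    pos = {s: i for i, s in enumerate(cm_k.active_set)}
    A_k = [pos[base_labels[i]] for i in A if base_labels[i] in pos]
    B_k = [pos[base_labels[i]] for i in B if base_labels[i] in pos]
    if not A_k or not B_k:
        return None
    pi_k = np.zeros(cm_k.active_set.size)
    for i_base, lab in enumerate(base_labels):
        if lab in pos:
            pi_k[pos[lab]] = model.pi[i_base]
    return (np.array(A_k, dtype=int), np.array(B_k, dtype=int), pi_k)


# ---------------------------------------------------------------------------
# coarse graining (PCCA+) and kinetics
# ---------------------------------------------------------------------------

@dataclass
class MacroModel:
    n_macrostates: int
    memberships: np.ndarray           # (n_micro, n_macro), rows sum to 1
    crisp_assignment: np.ndarray      # argmax membership per microstate
    populations: np.ndarray           # crisp stationary populations
    populations_weighted: np.ndarray  # membership-weighted populations
    population_sd: Optional[np.ndarray] = None
    folded_state: Optional[int] = None
    timescales: Optional[np.ndarray] = None
    mfpt_matrix: Optional[np.ndarray] = None


def pcca_plus(model: TransitionModel, n_macrostates: int) -> MacroModel:
    """PCCA+ fuzzy memberships from the dominant eigenvector simplex.

    Uses the inner-simplex vertex construction on the first
    ``n_macrostates`` right eigenvectors of a reversible transition
    matrix; memberships are clipped to [0, 1] and row-normalized.
    """
    n = model.n_states
    m = n_macrostates
    if m < 1 or m > n:
        raise InvalidRequestError("1 <= n_macrostates <= n_states required")
    if m == 1:
        memb = np.ones((n, 1))
    else:
        d = np.sqrt(model.pi)
        S = (d[:, None] * model.T) / d[None, :]
        S = 0.5 * (S + S.T)
        lam, psi = np.linalg.eigh(S)
        if model.estimator != "reversible_mle" and not np.allclose(
                S, S.T, atol=1e-8):
            raise EstimatorMismatchError("PCCA+ requires a reversible model")
        order = np.argsort(lam)[::-1]
        psi = psi[:, order[:m]]
        X = psi / d[:, None]
        X[:, 0] = 1.0
        idx = _inner_simplex_vertices(X)
        A = np.linalg.inv(X[idx])
        memb = X @ A
        memb = np.clip(memb, 0.0, 1.0)
        memb /= memb.sum(axis=1, keepdims=True)
    crisp = np.argmax(memb, axis=1)
    if len(np.unique(crisp)) < m:
        raise EstimatorMismatchError(
            "degenerate PCCA+ memberships: a macrostate has no crisp member")
    pops = np.array([model.pi[crisp == k].sum() for k in range(m)])
    pops_w = memb.T @ model.pi
    sd = None
    if model.posterior_samples is not None:
        pis = sample_stationary_distributions(model.posterior_samples)
        macro_pops = np.stack([[p[crisp == k].sum() for k in range(m)]
                               for p in pis])
        sd = macro_pops.std(axis=0, ddof=1)
    ts = model.timescales(min(m, model.n_states - 1))
    return MacroModel(n_macrostates=m, memberships=memb, crisp_assignment=crisp,
                      populations=pops, populations_weighted=pops_w,
                      population_sd=sd, timescales=ts)


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Greedy vertex search: rows of X spanning the largest simplex."""
    n, m = X.shape
    idx = np.zeros(m, dtype=int)
    # first vertex: farthest from the centroid
    c = X.mean(axis=0)
    idx[0] = int(np.argmax(np.linalg.norm(X - c, axis=1)))
    basis = np.zeros((m, m))
    v0 = X[idx[0]]
    for k in range(1, m):
        # orthogonalize against span of chosen vertex differences
        D = X - v0
        for j in range(1, k):
            b = basis[j]
            D = D - np.outer(D @ b, b)
        dist = np.linalg.norm(D, axis=1)
        idx[k] = int(np.argmax(dist))
        b = D[idx[k]]
        nrm = np.linalg.norm(b)
        basis[k] = b / nrm if nrm > 0 else b
    return idx


def mfpt(model: TransitionModel, from_set, to_set) -> float:
    """Mean first-passage time (in lag*dt units) between microstate sets.

    Solves ``(I - T) m = lag*dt`` with ``m = 0`` on the target and averages
    over ``from_set`` weighted by the stationary distribution.
    """
    A = np.atleast_1d(np.asarray(from_set, dtype=int))
    B = np.atleast_1d(np.asarray(to_set, dtype=int))
    if A.size == 0 or B.size == 0:
        raise InvalidSetsError("empty set")
    if set(A) == set(B):
        return 0.0
    if set(A) & set(B):
        raise InvalidSetsError("overlapping sets")
    n = model.n_states
    keep = np.setdiff1d(np.arange(n), B)
    M = np.eye(keep.size) - model.T[np.ix_(keep, keep)]
    rhs = np.full(keep.size, model.lag * model.dt_per_frame)
    m_keep = np.linalg.solve(M, rhs)
    m = np.zeros(n)
    m[keep] = m_keep
    w = model.pi[A] / model.pi[A].sum()
    return float(w @ m[A])


def transition_timescale(model: TransitionModel) -> float:
    """Slowest relaxation time -lag*dt/ln l_2 in physical units."""
    return float(model.timescales(1)[0])


@dataclass
class ReactiveFlux:
    q_forward: np.ndarray
    q_backward: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    pathways: list                # [(state path, flux carried), ...]


def reactive_flux(model: TransitionModel, source_set, sink_set,
                  max_pathways: int = 10) -> ReactiveFlux:
    """Transition-path-theory committors, net flux and dominant pathways.

    The forward committor solves the committor linear system (0 on the
    source, 1 on the sink); for reversible dynamics the backward committor
    is its complement.  Net flux ``F_ij = max(0, f_ij - f_ji)`` with
    ``f_ij = pi_i q-_i T_ij q+_j``; pathways are peeled off by iterative
    bottleneck (widest-path) decomposition.
    """
    A = np.atleast_1d(np.asarray(source_set, dtype=int))
    B = np.atleast_1d(np.asarray(sink_set, dtype=int))
    if A.size == 0 or B.size == 0:
        raise InvalidSetsError("empty source or sink")
    if set(A) & set(B):
        raise InvalidSetsError("source and sink overlap")
    n = model.n_states
    qp = np.zeros(n)
    qp[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if inter.size:
        M = np.eye(inter.size) - model.T[np.ix_(inter, inter)]
        rhs = model.T[np.ix_(inter, B)].sum(axis=1)
        qp[inter] = np.linalg.solve(M, rhs)
    qm = 1.0 - qp
    f = (model.pi * qm)[:, None] * model.T * qp[None, :]
    np.fill_diagonal(f, 0.0)
    F = np.maximum(0.0, f - f.T)
    total = float(F[A, :].sum() - F[:, A].sum())
    paths = _bottleneck_pathways(F.copy(), A, B, max_pathways)
    return ReactiveFlux(q_forward=qp, q_backward=qm, net_flux=F,
                        total_flux=total, pathways=paths)


def _widest_path(F: np.ndarray, A, B):
    """Path from A to B maximizing the minimum edge flux (Dijkstra-like)."""
    n = F.shape[0]
    width = np.full(n, -np.inf)
    prev = np.full(n, -1, dtype=int)
    width[A] = np.inf
    visited = np.zeros(n, dtype=bool)
    while True:
        cand = np.where(~visited, width, -np.inf)
        u = int(np.argmax(cand))
        if cand[u] == -np.inf:
            return None, 0.0
        if u in set(B.tolist()):
            path = [u]
            while prev[path[-1]] >= 0:
                path.append(prev[path[-1]])
            # path may start anywhere in A
            return path[::-1], float(width[u])
        visited[u] = True
        for v in np.flatnonzero(F[u] > 0):
            w = min(width[u], F[u, v])
            if w > width[v]:
                width[v] = w
                prev[v] = u
    # unreachable


def _bottleneck_pathways(F, A, B, max_pathways):
    paths = []
    for _ in range(max_pathways):
        path, w = _widest_path(F, A, B)
        if path is None or w <= 1e-15:
            break
        for u, v in zip(path[:-1], path[1:]):
            F[u, v] -= w
        paths.append((path, w))
    return paths


def folded_population(macro: MacroModel, reference_microstate: int,
                      model: TransitionModel) -> tuple[float, float]:
    """Stationary population of the macrostate holding the reference
    (native) microstate, with its Bayesian standard deviation.

    ``reference_microstate`` is an original (pre-trimming) state label; if
    it was trimmed from the connected set the model cannot speak about it.
    """
    where = np.flatnonzero(model.active_set == reference_microstate)
    if where.size == 0:
        raise ReferenceLostError(
            f"reference microstate {reference_microstate} is not in the "
            "connected set")
    macro_id = int(macro.crisp_assignment[where[0]])
    macro.folded_state = macro_id
    p = float(macro.populations[macro_id])
    sd = (float(macro.population_sd[macro_id])
          if macro.population_sd is not None else float("nan"))
    return p, sd
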