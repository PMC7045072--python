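"""Model energy landscapes and their analytic equilibrium properties.

These toy systems stand in for all-atom simulations of a protein that
fluctuates between a dominant folded state and a rare, partially unfolded
state separated by a barrier along a scalar collective variable (CV).
Everything is expressed in reduced units with ``kB = 1`` and a reference
temperature of 1, so energies are in units of kT and the analytic
quadrature oracles stay simple; :mod:`unfoldmsm.units` converts to
kcal/mol and Kelvin for display.

Three landscape kinds are supported:

``double_well_1d`` / ``tilted_double_well_1d``
    A quartic double well ``U(x) = B ((x/a)^2 - 1)^2 + (t/2)(x/a)`` with
    minima near ``x = -a`` (folded, low CV) and ``x = +a`` (partially
    unfolded), barrier height ``B`` and well-to-well energy offset ``t``
    (the "asymmetry").  The CV is ``x`` itself.

``bead_chain``
    A chain of beads with harmonic (Gaussian-chain) bonds plus the same
    double-well potential applied to the end-to-end distance, the toy
    analogue of the Cα–Cα distance across an initial protease cleavage
    site.  The end-to-end marginal density has a closed form, which gives
    an exact free-energy profile along the CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar


class InvalidInputError(ValueError):
    """Raised for non-finite or structurally invalid inputs."""


class ConfigurationError(ValueError):
    """Raised when supplied parameters violate a documented contract."""


class DomainError(ValueError):
    """Raised when a grid or dividing surface does not cover the support."""


_KINDS = ("double_well_1d", "tilted_double_well_1d", "bead_chain")


@dataclass(frozen=True)
class PotentialSpec:
    """Definition of a model energy landscape.

    Parameters
    ----------
    kind : str
        One of ``double_well_1d``, ``tilted_double_well_1d``, ``bead_chain``.
    barrier_height : float
        Barrier of the symmetric double well, in kT at the reference
        temperature.
    asymmetry : float
        Energy offset between the two wells (positive values stabilize the
        folded, low-CV well), in kT.
    well_separation : float
        Distance between the two minima along the CV.
    n_beads, bond_stiffness : int, float
        Chain geometry for ``bead_chain``; bonds are harmonic with zero
        rest length (Gaussian chain) and stiffness ``bond_stiffness``.
    native_pair_list : sequence of (int, int)
        Bead pairs used as native-contact candidates by the descriptor
        layer.  Purely geometric; they carry no energy term.
    contact_cutoff : float
        Distance below which a native pair counts as formed.
    """

    kind: str
    barrier_height: float = 7.0
    asymmetry: float = 0.0
    well_separation: float = 2.0
    n_beads: int = 8
    bond_stiffness: float = 30.0
    native_pair_list: tuple = ()
    contact_cutoff: float = 1.8

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ConfigurationError(f"unknown potential kind {self.kind!r}")
        if not self.barrier_height > 0:
            raise ConfigurationError("barrier_height must be > 0")
        if not self.well_separation > 0:
            raise ConfigurationError("well_separation must be > 0")
        if self.kind == "bead_chain":
            if self.n_beads < 2:
                raise ConfigurationError("bead_chain needs >= 2 beads")
            pairs = [tuple(p) for p in self.native_pair_list]
            if len(set(pairs)) != len(pairs):
                raise ConfigurationError("native_pair_list contains duplicates")
            for i, j in pairs:
                if not (0 <= i < self.n_beads and 0 <= j < self.n_beads) or i == j:
                    raise ConfigurationError(f"invalid native pair ({i}, {j})")

    @property
    def half_separation(self) -> float:
        return 0.5 * self.well_separation

    @property
    def ndim(self) -> int:
        """Flattened coordinate dimensionality."""
        return 1 if self.kind != "bead_chain" else 3 * self.n_beads

    # -- folded-state geometry -------------------------------------------
    def folded_minimum(self) -> float:
        """CV value of the folded (low-CV) minimum of U along the CV."""
        a = self.half_separation
        lo = -1.8 * a if self.kind != "bead_chain" else max(1e-3, 0.05 * a)
        hi = 0.0 if self.kind != "bead_chain" else a * 1.3
        if self.kind == "bead_chain":
            # bead-chain CV is a distance: folded well sits at +a of the
            # shifted double well (see _cv_potential)
            res = minimize_scalar(lambda s: self.cv_potential(s),
                                  bounds=(lo, hi), method="bounded")
        else:
            res = minimize_scalar(lambda s: self.cv_potential(s),
                                  bounds=(lo, hi), method="bounded")
        return float(res.x)

    def unfolded_minimum(self) -> float:
        a = self.half_separation
        if self.kind == "bead_chain":
            res = minimize_scalar(lambda s: self.cv_potential(s),
                                  bounds=(a * 1.3, a * 3.6), method="bounded")
        else:
            res = minimize_scalar(lambda s: self.cv_potential(s),
                                  bounds=(0.0, 1.8 * a), method="bounded")
        return float(res.x)

    def barrier_top(self) -> float:
        """CV value of the barrier top between the two minima."""
        lo, hi = self.folded_minimum(), self.unfolded_minimum()
        res = minimize_scalar(lambda s: -self.cv_potential(s),
                              bounds=(lo, hi), method="bounded")
        return float(res.x)

    # -- energies ---------------------------------------------------------
    def cv_potential(self, s):
        """Double-well potential evaluated on the CV value ``s``.

        For 1D kinds this is the full potential; for ``bead_chain`` it is
        the CV-dependent term only (bonds excluded).
        """
        a = self.half_separation
        if self.kind == "bead_chain":
            # place wells at s = a and s = 3a so the folded well sits at a
            # positive, chain-reachable end-to-end distance
            u = (np.asarray(s, dtype=float) - 2.0 * a) / a
        else:
            u = np.asarray(s, dtype=float) / a
        return (self.barrier_height * (u * u - 1.0) ** 2
                + 0.5 * self.asymmetry * u)

    def cv_potential_grad(self, s):
        a = self.half_separation
        if self.kind == "bead_chain":
            u = (np.asarray(s, dtype=float) - 2.0 * a) / a
        else:
            u = np.asarray(s, dtype=float) / a
        return (4.0 * self.barrier_height * u * (u * u - 1.0)
                + 0.5 * self.asymmetry) / a


def cv_value(spec: PotentialSpec, x) -> np.ndarray:
    """Collective variable of one frame or an array of frames.

    For 1D kinds the CV is the coordinate itself; for ``bead_chain`` it is
    the Euclidean distance between the first and last bead (the canonical
    end-to-end CV).
    """
    x = np.asarray(x, dtype=float)
    if spec.kind != "bead_chain":
        return x.reshape(x.shape[:-1]) if x.shape and x.shape[-1] == 1 else x
    frames = x.reshape(x.shape[:-2] + (spec.n_beads, 3)) if x.ndim >= 2 else x
    d = frames[..., -1, :] - frames[..., 0, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def potential_energy(spec: PotentialSpec, x) -> float:
    """Total potential energy U(x) of a single configuration."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite coordinates")
    if spec.kind != "bead_chain":
        return float(spec.cv_potential(np.ravel(x)[0]))
    r = x.reshape(spec.n_beads, 3)
    bonds = np.diff(r, axis=0)
    e_bond = 0.5 * spec.bond_stiffness * float(np.sum(bonds * bonds))
    s = float(cv_value(spec, r))
    return e_bond + float(spec.cv_potential(s))


def force(spec: PotentialSpec, x) -> np.ndarray:
    """Force ``-∇U`` at configuration ``x`` (same shape as ``x``)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite coordinates")
    if spec.kind != "bead_chain":
        g = spec.cv_potential_grad(np.ravel(x)[0])
        return np.full_like(x, -g) if x.shape else np.asarray(-g)
    r = x.reshape(spec.n_beads, 3)
    f = np.zeros_like(r)
    bonds = np.diff(r, axis=0)                     # r[i+1] - r[i]
    f[:-1] += spec.bond_stiffness * bonds
    f[1:] -= spec.bond_stiffness * bonds
    d = r[-1] - r[0]
    s = float(np.linalg.norm(d))
    if s > 1e-12:
        g = float(spec.cv_potential_grad(s))
        unit = d / s
        f[-1] -= g * unit
        f[0] += g * unit
    return f.reshape(x.shape)


# ---------------------------------------------------------------------------
# analytic equilibrium properties (ground-truth oracles)
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyProfile:
    """Free energy F(s) along the CV, min-shifted to zero."""

    cv_grid: np.ndarray
    F: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self):
        self.cv_grid = np.asarray(self.cv_grid, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - np.min(self.F[finite])

    def interp(self, s):
        return np.interp(s, self.cv_grid, self.F)


def _log_chain_density(spec: PotentialSpec, s):
    """log of the unbiased (bond-only) end-to-end density of the chain.

    For a Gaussian chain of N-1 bonds with stiffness k at temperature T=1,
    the end-to-end vector is normal with per-axis variance (N-1)/k, so the
    scalar distance density is ∝ s^2 exp(-k s^2 / (2 (N-1))).
    """
    var = (spec.n_beads - 1) / spec.bond_stiffness
    s = np.asarray(s, dtype=float)
    with np.errstate(divide="ignore"):
        return 2.0 * np.log(s) - s * s / (2.0 * var)


def cv_log_weight(spec: PotentialSpec, s, temperature: float = 1.0):
    """Unnormalized log equilibrium density of the CV at ``temperature``."""
    lw = -np.asarray(spec.cv_potential(s)) / temperature
    if spec.kind == "bead_chain":
        lw = lw + _log_chain_density(spec, s)
    return lw


def analytic_free_energy(spec: PotentialSpec, cv_grid,
                         temperature: float = 1.0) -> FreeEnergyProfile:
    """Exact free-energy profile F(s) = -kT ln p(s), min-shifted.

    For 1D kinds where the CV is the coordinate itself this reduces to
    U(s) up to the additive constant.  For the bead chain the chain-entropy
    contribution of the Gaussian-chain end-to-end density is included in
    closed form.
    """
    grid = np.asarray(cv_grid, dtype=float)
    if grid.size < 2:
        raise DomainError("cv_grid must contain at least 2 points")
    lo, hi = spec.folded_minimum(), spec.unfolded_minimum()
    if grid.min() > lo or grid.max() < hi:
        raise DomainError("cv_grid does not cover both wells")
    F = -temperature * cv_log_weight(spec, grid, temperature)
    return FreeEnergyProfile(grid, F)


def analytic_populations(spec: PotentialSpec, dividing_surface: float | None = None,
                         temperature: float = 1.0) -> tuple[float, float]:
    """Boltzmann-weighted folded/unfolded populations by quadrature.

    The folded state is the low-CV side of ``dividing_surface`` (default:
    the barrier top of the analytic profile).  Returns ``(p_folded,
    p_unfolded)`` with the two summing to one exactly.
    """
    if dividing_surface is None:
        dividing_surface = spec.barrier_top()
    lo_min, hi_min = spec.folded_minimum(), spec.unfolded_minimum()
    if not (lo_min < dividing_surface < hi_min):
        raise DomainError("dividing surface must lie between the two wells")
    a = spec.half_separation
    if spec.kind == "bead_chain":
        lo, hi = 1e-9, 2.0 * a + 4.0 * a
    else:
        lo, hi = -a * 6.0, a * 6.0
    ref = float(cv_log_weight(spec, lo_min, temperature))

    def w(s):
        return np.exp(cv_log_weight(spec, s, temperature) - ref)

    zf, _ = quad(w, lo, dividing_surface, limit=200)
    zu, _ = quad(w, dividing_surface, hi, limit=200)
    p_folded = zf / (zf + zu)
    return p_folded, 1.0 - p_folded


# ---------------------------------------------------------------------------
# variant suite
# ---------------------------------------------------------------------------

VARIANT_LABELS = ("stabilized", "wildtype", "destabilized")

#: Default (barrier, asymmetry) pairs in kT for the graded-stability series.
#: The ordering mimics a stabilized point mutant, the wild-type protein and
#: a destabilized natural isoform: folded populations near 0.95 / 0.88 / 0.69
#: and folded-side escape barriers decreasing across the series.
DEFAULT_VARIANT_PARAMS = {
    "stabilized": (7.0, 3.0),
    "wildtype": (6.0, 2.0),
    "destabilized": (5.0, 0.8),
}


@dataclass
class VariantSuite:
    """Three graded-stability parameterizations of the same landscape."""

    specs: dict[str, PotentialSpec]
    design_folded_population: dict[str, float] = field(default_factory=dict)

    @property
    def labels(self):
        return VARIANT_LABELS


def make_variant_suite(params: dict | None = None, kind: str = "tilted_double_well_1d",
                       temperature: float = 1.0, **spec_kwargs) -> VariantSuite:
    """Build the three-variant suite with analytic design populations.

    ``params`` maps each label in ``{stabilized, wildtype, destabilized}``
    to a ``(barrier_height, asymmetry)`` pair.  Populations are computed by
    quadrature (never hand-set) and must come out strictly ordered
    stabilized > wildtype > destabilized.
    """
    params = dict(DEFAULT_VARIANT_PARAMS if params is None else params)
    if set(params) != set(VARIANT_LABELS):
        raise ConfigurationError(f"params must define exactly {VARIANT_LABELS}")
    specs, pops = {}, {}
    for label in VARIANT_LABELS:
        b, t = params[label]
        specs[label] = PotentialSpec(kind=kind, barrier_height=float(b),
                                     asymmetry=float(t), **spec_kwargs)
        pops[label], _ = analytic_populations(specs[label], temperature=temperature)
    if not (pops["stabilized"] > pops["wildtype"] > pops["destabilized"]):
        raise ConfigurationError(
            "supplied parameters do not produce strictly ordered folded "
            f"populations: {pops}")
    return VariantSuite(specs=specs, design_folded_population=pops)


def default_bead_pairs(n_beads: int) -> tuple:
    """Native-contact candidate pairs between the two chain ends.

    Mimics backbone donor–acceptor pairs bridging the two helices that
    flank a cleavage site: every pair couples one of the first three beads
    to one of the last two, so formed-contact counts track the end-to-end
    CV.
    """
    pairs = []
    for i in range(min(3, n_beads - 1)):
        for j in (n_beads - 2, n_beads - 1):
            if j > i:
                pairs.append((i, j))
    return tuple(sorted(set(pairs)))
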