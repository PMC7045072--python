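"""BAOAB Langevin dynamics on the toy landscapes.

The integrator uses the BAOAB splitting (kick / drift / Ornstein-Uhlenbeck
/ drift / kick), which samples configurations accurately at practical
timesteps.  Particle mass is 1 in reduced units.  A run is fully
determined by its parameters and seed: identical seeds give bit-identical
trajectories.

An optional bias force on the collective variable supports metadynamics:
fast paths accept a grid-tabulated bias (linear interpolation inside a
numba kernel); an arbitrary Python callback ``bias(cv, step) -> force``
falls back to a pure-Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numba import njit

from .potentials import PotentialSpec, cv_value, force, InvalidInputError


class IntegrationDivergedError(RuntimeError):
    """Raised when a coordinate becomes non-finite during integration."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"integration diverged at step {step}")


@dataclass(frozen=True)
class LangevinParams:
    """Integrator settings in reduced units (kB = 1, mass = 1)."""

    timestep: float = 0.004
    friction: float = 1.0
    temperature: float = 1.0
    n_steps: int = 10000
    save_stride: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.timestep > 0:
            raise ValueError("timestep must be > 0")
        if not self.friction > 0:
            raise ValueError("friction must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")

    @property
    def dt_per_frame(self) -> float:
        return self.timestep * self.save_stride


@dataclass
class Trajectory:
    """Saved frames plus the CV series and provenance of one run."""

    frames: np.ndarray          # (n_frames, ndim)
    cv_series: np.ndarray       # (n_frames,)
    dt_per_frame: float
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return self.frames.shape[0]


def _derive_seed(seed: int, *streams: int) -> int:
    """Deterministic 31-bit child seed for a named stream."""
    ss = np.random.SeedSequence([int(seed)] + [int(s) for s in streams])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@njit(cache=True)
def _interp_force(x, grid_x0, grid_dx, fgrid):
    n = fgrid.size
    if n == 0:
        return 0.0
    u = (x - grid_x0) / grid_dx
    if u <= 0.0:
        return fgrid[0]
    if u >= n - 1:
        return fgrid[n - 1]
    i = int(u)
    w = u - i
    return fgrid[i] * (1.0 - w) + fgrid[i + 1] * w


@njit(cache=True)
def _force_dw(x, B, a, t):
    u = x / a
    return -(4.0 * B * u * (u * u - 1.0) + 0.5 * t) / a


@njit(cache=True)
def _baoab_1d(x0, v0, n_steps, dt, gamma, kT, B, a, t,
              grid_x0, grid_dx, bias_fgrid,
              save_stride, start_step, out):
    """BAOAB on a 1D double well with optional grid bias force.

    Frames are recorded at global steps divisible by ``save_stride``
    (excluding the initial step, which the caller records).  Returns
    (n_saved, x_end, v_end, diverged_step); diverged_step is -1 when the
    run stayed finite.
    """
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    x = x0
    v = v0
    nsave = 0
    for k in range(1, n_steps + 1):
        f = _force_dw(x, B, a, t) + _interp_force(x, grid_x0, grid_dx, bias_fgrid)
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.normal()
        x += 0.5 * dt * v
        f = _force_dw(x, B, a, t) + _interp_force(x, grid_x0, grid_dx, bias_fgrid)
        v += 0.5 * dt * f
        if not np.isfinite(x):
            return nsave, x, v, start_step + k
        if (start_step + k) % save_stride == 0:
            out[nsave] = x
            nsave += 1
    return nsave, x, v, -1


@njit(cache=True)
def _chain_force(r, kb, B, a, t, two_a, fout):
    n = r.shape[0]
    for i in range(n):
        for d in range(3):
            fout[i, d] = 0.0
    for i in range(n - 1):
        for d in range(3):
            b = r[i + 1, d] - r[i, d]
            fout[i, d] += kb * b
            fout[i + 1, d] -= kb * b
    s2 = 0.0
    for d in range(3):
        dd = r[n - 1, d] - r[0, d]
        s2 += dd * dd
    s = np.sqrt(s2)
    if s > 1e-12:
        u = (s - two_a) / a
        g = (4.0 * B * u * (u * u - 1.0) + 0.5 * t) / a
        for d in range(3):
            unit = (r[n - 1, d] - r[0, d]) / s
            fout[n - 1, d] -= g * unit
            fout[0, d] += g * unit
    return s


@njit(cache=True)
def _baoab_chain(r0, v0, n_steps, dt, gamma, kT, kb, B, a, t,
                 grid_x0, grid_dx, bias_fgrid,
                 save_stride, start_step, out, out_cv):
    n = r0.shape[0]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    r = r0.copy()
    v = v0.copy()
    f = np.zeros((n, 3))
    s = _chain_force(r, kb, B, a, t, 2.0 * a, f)
    nsave = 0
    for k in range(1, n_steps + 1):
        fb = _interp_force(s, grid_x0, grid_dx, bias_fgrid)
        if s > 1e-12 and fb != 0.0:
            for d in range(3):
                unit = (r[n - 1, d] - r[0, d]) / s
                f[n - 1, d] += fb * unit
                f[0, d] -= fb * unit
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d]
                r[i, d] += 0.5 * dt * v[i, d]
        for i in range(n):
            for d in range(3):
                v[i, d] = c1 * v[i, d] + c2 * np.random.normal()
                r[i, d] += 0.5 * dt * v[i, d]
        s = _chain_force(r, kb, B, a, t, 2.0 * a, f)
        fb = _interp_force(s, grid_x0, grid_dx, bias_fgrid)
        if s > 1e-12 and fb != 0.0:
            for d in range(3):
                unit = (r[n - 1, d] - r[0, d]) / s
                f[n - 1, d] += fb * unit
                f[0, d] -= fb * unit
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d]
        if not np.isfinite(s):
            return nsave, r, v, start_step + k
        if (start_step + k) % save_stride == 0:
            for i in range(n):
                for d in range(3):
                    out[nsave, i, d] = r[i, d]
            out_cv[nsave] = s
            nsave += 1
    return nsave, r, v, -1


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


def maxwell_boltzmann_velocities(ndim: int, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Fresh velocities at ``temperature`` (mass 1)."""
    return rng.normal(0.0, np.sqrt(temperature), size=ndim)


_EMPTY = np.empty(0, dtype=np.float64)


def integrate_langevin(spec: PotentialSpec, params: LangevinParams, start,
                       external_bias: Optional[Callable[[float, int], float]] = None,
                       _grid_bias: tuple | None = None,
                       _start_state: tuple | None = None) -> Trajectory:
    """Run Langevin dynamics from ``start`` and return the saved trajectory.

    ``external_bias`` is an optional callback ``bias(cv_value, step) ->
    force_on_cv`` evaluated every step (slow path).  Grid-tabulated biases
    used internally by the metadynamics engine take the fast numba path.

    The trajectory contains ``floor(n_steps / save_stride) + 1`` frames
    (the initial configuration plus every ``save_stride``-th step).
    """
    start = np.asarray(start, dtype=float).ravel()
    if start.size != spec.ndim:
        raise InvalidInputError(
            f"start has {start.size} coordinates, expected {spec.ndim}")
    if not np.all(np.isfinite(start)):
        raise InvalidInputError("non-finite start coordinates")

    rng = np.random.default_rng(_derive_seed(params.seed, 0))
    if _start_state is not None:
        x0, v0 = _start_state
        x0 = np.asarray(x0, dtype=float).ravel().copy()
        v0 = np.asarray(v0, dtype=float).ravel().copy()
    else:
        x0 = start.copy()
        v0 = maxwell_boltzmann_velocities(spec.ndim, params.temperature, rng)

    if external_bias is not None and not callable(external_bias):
        raise InvalidInputError("external_bias must be callable")

    if external_bias is None:
        frames, cvs, x_end, v_end = _run_fast(spec, params, x0, v0, _grid_bias, 0)
    else:
        frames, cvs, x_end, v_end = _run_python(spec, params, x0, v0, external_bias)

    traj = Trajectory(
        frames=frames, cv_series=cvs, dt_per_frame=params.dt_per_frame,
        provenance={"params": params, "seed": params.seed,
                    "bias_applied": external_bias is not None or _grid_bias is not None},
    )
    traj._end_state = (x_end, v_end)  # internal: lets callers continue runs
    return traj


def _dw_params(spec: PotentialSpec):
    return spec.barrier_height, spec.half_separation, spec.asymmetry


def _run_fast(spec, params, x0, v0, grid_bias, start_step, numba_seed=None):
    """Numba path.  The initial frame is recorded only for start_step == 0,
    so chunked callers (metadynamics) can stitch chunks without duplicates."""
    if grid_bias is None:
        gx0, gdx, fgrid = 0.0, 1.0, _EMPTY
    else:
        gx0, gdx, fgrid = grid_bias
    n_alloc = params.n_steps // params.save_stride + 2
    if numba_seed is None:
        numba_seed = _derive_seed(params.seed, 1)
    _seed_numba(numba_seed)
    B, a, t = _dw_params(spec)
    first = start_step == 0
    if spec.kind != "bead_chain":
        out = np.empty(n_alloc, dtype=np.float64)
        nsave, x_end, v_end, bad = _baoab_1d(
            float(x0[0]), float(v0[0]), params.n_steps, params.timestep,
            params.friction, params.temperature, B, a, t,
            gx0, gdx, fgrid, params.save_stride, start_step, out)
        if bad >= 0:
            raise IntegrationDivergedError(bad)
        head = [x0[0]] if first else []
        frames = np.concatenate([head, out[:nsave]])[:, None]
        cvs = frames[:, 0].copy()
        return frames, cvs, np.array([x_end]), np.array([v_end])
    r0 = x0.reshape(spec.n_beads, 3)
    out = np.empty((n_alloc, spec.n_beads, 3), dtype=np.float64)
    out_cv = np.empty(n_alloc, dtype=np.float64)
    nsave, r_end, v_end, bad = _baoab_chain(
        r0, v0.reshape(spec.n_beads, 3), params.n_steps, params.timestep,
        params.friction, params.temperature, spec.bond_stiffness, B, a, t,
        gx0, gdx, fgrid, params.save_stride, start_step, out, out_cv)
    if bad >= 0:
        raise IntegrationDivergedError(bad)
    if first:
        frames = np.concatenate([r0[None], out[:nsave]]).reshape(nsave + 1, -1)
        cvs = np.concatenate([[float(cv_value(spec, r0))], out_cv[:nsave]])
    else:
        frames = out[:nsave].reshape(nsave, -1)
        cvs = out_cv[:nsave].copy()
    return frames, cvs, r_end.ravel(), v_end.ravel()


def _run_python(spec, params, x0, v0, bias):
    """Reference-path integrator accepting an arbitrary bias callback."""
    dt, gamma, kT = params.timestep, params.friction, params.temperature
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    rng = np.random.default_rng(_derive_seed(params.seed, 1))
    x, v = x0.copy(), v0.copy()
    frames = [x.copy()]
    cvs = [float(cv_value(spec, x if spec.kind != "bead_chain"
                          else x.reshape(spec.n_beads, 3)))]

    def total_force(xx, step):
        f = force(spec, xx)
        s = float(cv_value(spec, xx if spec.kind != "bead_chain"
                           else xx.reshape(spec.n_beads, 3)))
        fb = float(bias(s, step))
        if fb != 0.0:
            if spec.kind != "bead_chain":
                f = f + fb
            else:
                r = xx.reshape(spec.n_beads, 3)
                d = r[-1] - r[0]
                if s > 1e-12:
                    fr = f.reshape(spec.n_beads, 3).copy()
                    fr[-1] += fb * d / s
                    fr[0] -= fb * d / s
                    f = fr.ravel()
        return f

    f = total_force(x, 0)
    for k in range(1, params.n_steps + 1):
        v = v + 0.5 * dt * f
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * rng.normal(size=x.size)
        x = x + 0.5 * dt * v
        f = total_force(x, k)
        v = v + 0.5 * dt * f
        if not np.all(np.isfinite(x)):
            raise IntegrationDivergedError(k)
        if k % params.save_stride == 0:
            frames.append(x.copy())
            cvs.append(float(cv_value(spec, x if spec.kind != "bead_chain"
                                      else x.reshape(spec.n_beads, 3))))
    return np.asarray(frames), np.asarray(cvs), x, v
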