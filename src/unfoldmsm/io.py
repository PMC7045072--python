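"""Serialization of trajectories, bias states, models and reports.

HDF5 (via h5py) for array-heavy artifacts, delimited text for tables and
profiles, XYZ for bead-chain frames.  Every writer records enough
provenance (seeds, parameters) to regenerate the artifact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .langevin import LangevinParams, Trajectory
from .metad import BiasState
from .potentials import FreeEnergyProfile
from .seeding import ClusterResult, SeedSet


def _params_json(params) -> str:
    if dataclasses.is_dataclass(params):
        d = {k: v for k, v in dataclasses.asdict(params).items()
             if not isinstance(v, np.ndarray)}
        return json.dumps(d, default=str)
    return json.dumps(str(params))


def save_trajectory(path, traj: Trajectory):
    with h5py.File(path, "w") as f:
        f.create_dataset("coordinates", data=traj.frames)
        f.create_dataset("cv", data=traj.cv_series)
        f.create_dataset("time", data=np.arange(len(traj)) * traj.dt_per_frame)
        f.attrs["dt_per_frame"] = traj.dt_per_frame
        f.attrs["seed"] = int(traj.provenance.get("seed", -1))
        f.attrs["bias_applied"] = bool(traj.provenance.get("bias_applied", False))
        p = traj.provenance.get("params")
        if p is not None:
            f.attrs["params"] = _params_json(p)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        frames = f["coordinates"][...]
        cv = f["cv"][...]
        prov = {"seed": int(f.attrs.get("seed", -1)),
                "bias_applied": bool(f.attrs.get("bias_applied", False))}
        if "params" in f.attrs:
            prov["params"] = LangevinParams(**{
                k: v for k, v in json.loads(f.attrs["params"]).items()})
        return Trajectory(frames=frames, cv_series=cv,
                          dt_per_frame=float(f.attrs["dt_per_frame"]),
                          provenance=prov)


def save_trajectory_text(path, traj: Trajectory):
    """One frame per row: time, cv, flattened coordinates."""
    t = np.arange(len(traj)) * traj.dt_per_frame
    data = np.column_stack([t, traj.cv_series, traj.frames])
    np.savetxt(path, data, header="time cv coordinates...")


def save_bias_state(path, state: BiasState):
    with h5py.File(path, "w") as f:
        f.create_dataset("centers", data=np.asarray(state.centers))
        f.create_dataset("heights", data=np.asarray(state.heights))
        f.create_dataset("deposit_steps", data=np.asarray(state.deposit_steps))
        f.create_dataset("grid", data=state.grid)
        f.create_dataset("V", data=state.V)
        f.attrs["sigma"] = state.sigma


def load_bias_state(path) -> BiasState:
    with h5py.File(path, "r") as f:
        state = BiasState(grid=f["grid"][...], sigma=float(f.attrs["sigma"]),
                          centers=list(f["centers"][...]),
                          heights=list(f["heights"][...]),
                          deposit_steps=[int(s) for s in f["deposit_steps"][...]],
                          V=f["V"][...])
    state.Fb = None
    state.__post_init__()
    # rebuild force cache from the history
    from .metad import _add_gaussian_to_cache
    state.V[:] = 0.0
    for c, h in zip(state.centers, state.heights):
        _add_gaussian_to_cache(state, c, h, state.sigma)
    return state


def save_fes_text(path, profile: FreeEnergyProfile):
    np.savetxt(path, np.column_stack([profile.cv_grid, profile.F]),
               header="cv F")


def load_fes_text(path) -> FreeEnergyProfile:
    data = np.loadtxt(path)
    return FreeEnergyProfile(data[:, 0], data[:, 1])


def save_clusters_text(path, clusters: ClusterResult):
    rep = np.zeros(len(clusters.assignments), dtype=int)
    rep[clusters.representatives] = 1
    df = pd.DataFrame({"frame": np.arange(len(clusters.assignments)),
                       "cluster": clusters.assignments,
                       "is_representative": rep})
    df.to_csv(path, sep="\t", index=False)


def save_seed_set(path, seeds: SeedSet):
    with h5py.File(path, "w") as f:
        f.create_dataset("seeds", data=seeds.seeds)
        f.create_dataset("source_clusters", data=seeds.source_clusters)
        f.create_dataset("rng_seeds", data=seeds.rng_seeds)
        f.attrs["run_length"] = seeds.run_length


def load_seed_set(path) -> SeedSet:
    with h5py.File(path, "r") as f:
        return SeedSet(seeds=f["seeds"][...],
                       source_clusters=f["source_clusters"][...],
                       run_length=int(f.attrs["run_length"]),
                       rng_seeds=f["rng_seeds"][...])


def save_msm(path, model, macro=None):
    with h5py.File(path, "w") as f:
        f.create_dataset("T", data=model.T)
        f.create_dataset("pi", data=model.pi)
        f.create_dataset("active_set", data=model.active_set)
        f.attrs["lag"] = model.lag
        f.attrs["estimator"] = model.estimator
        f.attrs["dt_per_frame"] = model.dt_per_frame
        if macro is not None:
            f.create_dataset("memberships", data=macro.memberships)
            f.create_dataset("crisp_assignment", data=macro.crisp_assignment)
            f.create_dataset("macro_populations", data=macro.populations)
            if macro.population_sd is not None:
                f.create_dataset("macro_population_sd", data=macro.population_sd)


def write_xyz(path, frames, element: str = "C", comment: str = ""):
    """Bead-chain frames as a plain multi-frame XYZ file."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames.reshape(frames.shape[0], -1, 3)
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.shape[0]}\n{comment}\n")
            for atom in frame:
                fh.write(f"{element} {atom[0]:.6f} {atom[1]:.6f} {atom[2]:.6f}\n")
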