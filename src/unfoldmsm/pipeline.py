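"""End-to-end orchestration of the local-unfolding workflow.

One configured run per variant: well-tempered metadynamics along the CV ->
average-linkage clustering of the biased ensemble -> unbiased seeded runs
from the cluster medoids -> reversible MSM with PCCA+ coarse-graining ->
folded-state population, unfolding timescale and (on the bead-chain
analogue) the native-contact entropy.  All randomness derives from one
configured master seed; rerunning a config reproduces the report body
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptors import ContactDefinition, native_contacts, shannon_entropy
from .langevin import LangevinParams, _derive_seed, integrate_langevin
from .metad import MetadParams, PAPER_UNITS_PRESET, run_metad
from .msm import (chapman_kolmogorov_test, bayesian_samples, count_transitions,
                  default_n_microstates, estimate_transition_matrix,
                  folded_population, kmeans_discretize, mfpt, pcca_plus,
                  tica_fit, tica_transform, transition_timescale)
from .potentials import (ConfigurationError, PotentialSpec, VariantSuite,
                         analytic_populations, default_bead_pairs,
                         make_variant_suite)
from .seeding import (build_seed_set, cluster_conformations, run_seeded,
                      subsample_frames)
from .units import metad_preset_reduced

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Schema violation in a pipeline configuration."""


@dataclass(frozen=True)
class SeedingConfig:
    metad_stage_cutoff: float = 0.06   # CV-space cutoff for pathway clustering
    folded_stage_cutoff: float = 0.35  # aligned-RMSD cutoff, folded-state stage
    max_cluster_frames: int = 2000
    run_length: int = 20000            # steps per seeded run
    timestep: float = 0.008            # seeded runs are overdamped-leaning:
    friction: float = 4.0              # better CV Markovianity than the
    save_stride: int = 15              # gamma=1 metadynamics stage
    n_rounds: int = 24                 # rounds per medoid (every seed)
    barrier_boost_rounds: int = 168    # extra rounds for barrier-zone seeds
    barrier_window_kT: float = 2.5     # zone: FES within this of the top


@dataclass(frozen=True)
class MSMConfig:
    lag: int = 25                      # frames
    n_microstates: int | None = None   # None -> min(100, n_frames // 50)
    n_macrostates: int = 2
    n_boot: int = 60
    ck_factors: tuple = (2, 3)


@dataclass(frozen=True)
class EntropyConfig:
    n_beads: int = 8
    bond_stiffness: float = 30.0
    contact_cutoff: float = 1.1
    n_steps: int = 60000
    save_stride: int = 10


@dataclass(frozen=True)
class PipelineConfig:
    """Validated settings for a full variant-suite run."""

    seed: int = 0
    variants: dict = field(default_factory=dict)   # label -> (barrier, asym)
    langevin: LangevinParams = field(
        default_factory=lambda: LangevinParams(timestep=0.004, friction=1.0,
                                               temperature=1.0, n_steps=40000,
                                               save_stride=10))
    metad: MetadParams = field(
        default_factory=lambda: MetadParams(w0=1.2, sigma=0.2, biasfactor=12.0,
                                            pace=200))
    n_metad_replicas: int = 6
    seeding: SeedingConfig = field(default_factory=SeedingConfig)
    msm: MSMConfig = field(default_factory=MSMConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    output_dir: str | None = None
    log_level: str = "INFO"


@dataclass
class RunReport:
    """Machine-readable summary of a full run."""

    per_variant: dict                 # label -> result dict
    provenance: dict

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label, r in self.per_variant.items():
            rows.append({"variant": label, **r})
        return pd.DataFrame(rows)

    def body_text(self) -> str:
        """Deterministic report body (no timestamps)."""
        df = self.to_dataframe()
        prov = {k: v for k, v in self.provenance.items() if k != "wall_time_s"}
        return (df.to_csv(index=False, float_format="%.6g")
                + "\n" + json.dumps(prov, sort_keys=True, default=str))


def _build_dataclass(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid {where}: {e}") from e


def validate_config(path) -> PipelineConfig:
    """Parse, default and cross-validate a YAML pipeline config.

    Unknown keys are rejected with the offending key named.  The metad
    section accepts ``preset: paper-units`` to load the published
    metadynamics protocol (height 10.0 kcal/mol, width 0.35, biasfactor 30,
    pace 1000) converted to reduced units.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} at top level")
    kw = {}
    if "seed" in raw:
        kw["seed"] = int(raw["seed"])
    if "variants" in raw:
        v = raw["variants"]
        if not isinstance(v, dict):
            raise ConfigError("variants must map label -> [barrier, asymmetry]")
        kw["variants"] = {k: tuple(map(float, pair)) for k, pair in v.items()}
    if "langevin" in raw:
        kw["langevin"] = _build_dataclass(LangevinParams, raw["langevin"],
                                          "langevin section")
    if "metad" in raw:
        m = dict(raw["metad"])
        preset = m.pop("preset", None)
        if preset is not None:
            if preset != "paper-units":
                raise ConfigError(f"unknown metad preset {preset!r}")
            m = {**metad_preset_reduced(PAPER_UNITS_PRESET), **m}
        kw["metad"] = _build_dataclass(MetadParams, m, "metad section")
    if "n_metad_replicas" in raw:
        kw["n_metad_replicas"] = int(raw["n_metad_replicas"])
    for key, cls in (("seeding", SeedingConfig), ("msm", MSMConfig),
                     ("entropy", EntropyConfig)):
        if key in raw:
            kw[key] = _build_dataclass(cls, raw[key], f"{key} section")
    for key in ("output_dir", "log_level"):
        if key in raw:
            kw[key] = raw[key]
    return PipelineConfig(**kw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _barrier_window(metad_runs, config: PipelineConfig):
    """CV interval around the barrier top, read off the averaged
    well-tempered-limit free-energy estimate of the metadynamics stage."""
    from .metad import well_tempered_limit_fes
    grid = metad_runs[0][1].grid
    F = np.mean([well_tempered_limit_fes(state, grid, config.metad).F
                 for _, state in metad_runs], axis=0)
    F = F - F.min()
    # two deepest separated minima bracket the barrier
    interior = slice(1, -1)
    is_min = np.zeros_like(F, dtype=bool)
    is_min[interior] = (F[1:-1] <= F[:-2]) & (F[1:-1] <= F[2:])
    mins = np.flatnonzero(is_min)
    if mins.size < 2:
        return None
    best = sorted(mins, key=lambda i: F[i])[:2]
    lo, hi = sorted(best)
    top = lo + int(np.argmax(F[lo:hi + 1]))
    thresh = F[top] - config.seeding.barrier_window_kT
    left = top
    while left > lo and F[left] >= thresh:
        left -= 1
    right = top
    while right < hi and F[right] >= thresh:
        right += 1
    return grid[left], grid[right]


def estimate_variant(spec: PotentialSpec, config: PipelineConfig,
                     variant_seed: int) -> dict:
    """Metadynamics -> seeding -> seeded runs -> MSM for one variant.

    Seeded sampling is allocated adaptively: every cluster medoid gets
    ``n_rounds`` independent unbiased runs, and medoids inside the barrier
    window (where transition statistics, not well statistics, limit the
    precision of the stitched populations) get ``barrier_boost_rounds``
    extra rounds.
    """
    lp = dataclasses.replace(config.langevin, seed=variant_seed)
    metad_runs = run_metad(spec, lp, config.metad,
                           n_replicas=config.n_metad_replicas)
    pooled = np.concatenate([t.frames for t, _ in metad_runs], axis=0)
    keep = subsample_frames(pooled, config.seeding.max_cluster_frames)
    clusters = cluster_conformations(pooled[keep],
                                     config.seeding.metad_stage_cutoff,
                                     metric="euclidean")
    seed_set = build_seed_set(clusters, pooled[keep],
                              run_length=config.seeding.run_length,
                              rng_base_seed=_derive_seed(variant_seed, 7))
    window = _barrier_window(metad_runs, config)
    seed_cv = seed_set.seeds[:, 0] if spec.kind != "bead_chain" else np.array(
        [float(np.linalg.norm(s.reshape(-1, 3)[-1] - s.reshape(-1, 3)[0]))
         for s in seed_set.seeds])
    boosted = (np.zeros(seed_set.seeds.shape[0], dtype=bool) if window is None
               else (seed_cv >= window[0]) & (seed_cv <= window[1]))
    lp_seed = dataclasses.replace(
        lp, timestep=config.seeding.timestep,
        friction=config.seeding.friction,
        save_stride=config.seeding.save_stride)
    total_rounds = config.seeding.n_rounds + config.seeding.barrier_boost_rounds
    seeded = []
    for round_id in range(total_rounds):
        active = (np.arange(seed_set.seeds.shape[0])
                  if round_id < config.seeding.n_rounds
                  else np.flatnonzero(boosted))
        if active.size == 0:
            continue
        ss = dataclasses.replace(
            seed_set,
            seeds=seed_set.seeds[active],
            source_clusters=seed_set.source_clusters[active],
            rng_seeds=np.array([_derive_seed(variant_seed, 7, round_id, int(k))
                                for k in active]))
        seeded.extend(run_seeded(ss, spec, lp_seed))

    dt = lp_seed.dt_per_frame
    features = [t.cv_series[:, None] for t in seeded]
    tica = tica_fit(features, lag=config.msm.lag)
    projected = tica_transform(tica, features)
    n_frames = sum(len(f) for f in features)
    k = (config.msm.n_microstates if config.msm.n_microstates is not None
         else default_n_microstates(n_frames))
    disc = kmeans_discretize(projected, k, seed=_derive_seed(variant_seed, 8))
    cm = count_transitions(disc.dtrajs, config.msm.lag)
    model = estimate_transition_matrix(cm, "reversible_mle", dt_per_frame=dt)
    model.posterior_samples = bayesian_samples(
        cm, config.msm.n_boot, seed=_derive_seed(variant_seed, 9))
    macro = pcca_plus(model, config.msm.n_macrostates)

    ref_feature = np.array([[spec.folded_minimum()]])
    ref_proj = tica_transform(tica, ref_feature)
    # nearest microstate to the native conformation, restricted to the
    # connected set so sparse runs cannot lose the reference
    active_centers = disc.centers[cm.active_set]
    ref_micro = int(cm.active_set[np.argmin(
        np.linalg.norm(active_centers - ref_proj[0], axis=1))])
    p_folded, sd = folded_population(macro, ref_micro, model)
    folded_id = macro.folded_state
    folded_set = np.flatnonzero(macro.crisp_assignment == folded_id)
    unfolded_set = np.flatnonzero(macro.crisp_assignment != folded_id)
    unfolding_mfpt = mfpt(model, folded_set, unfolded_set)
    timescale = transition_timescale(model)

    ck = chapman_kolmogorov_test(disc.dtrajs, model, macro,
                                 factors=config.msm.ck_factors,
                                 seed=_derive_seed(variant_seed, 10))
    active_frames = np.mean([np.isin(d, model.active_set).mean()
                             for d in disc.dtrajs])
    return {
        "p_folded": p_folded, "p_folded_sd": sd,
        "unfolding_mfpt": unfolding_mfpt,
        "relaxation_timescale": timescale,
        "n_seeds": int(seed_set.seeds.shape[0]),
        "connected_fraction": float(active_frames),
        "ck_pass_fraction": float(ck["within_band"].mean()),
        "_model": model, "_macro": macro, "_clusters": clusters,
    }


def contact_entropy_for_variant(barrier: float, asymmetry: float,
                                config: PipelineConfig, seed: int) -> tuple:
    """Folded-state descriptors of the variant's bead-chain analogue.

    Runs a matched-length folded-state trajectory and returns the Shannon
    entropy of the native-contact counts together with the number of
    conformational clusters at the folded-stage cutoff (aligned RMSD)."""
    ec = config.entropy
    spec = PotentialSpec(
        kind="bead_chain", barrier_height=barrier, asymmetry=asymmetry,
        n_beads=ec.n_beads, bond_stiffness=ec.bond_stiffness,
        native_pair_list=default_bead_pairs(ec.n_beads),
        contact_cutoff=ec.contact_cutoff)
    lp = LangevinParams(timestep=config.langevin.timestep,
                        friction=config.langevin.friction,
                        temperature=config.langevin.temperature,
                        n_steps=ec.n_steps, save_stride=ec.save_stride,
                        seed=seed)
    s0 = spec.folded_minimum()
    start = np.zeros((ec.n_beads, 3))
    start[:, 0] = np.linspace(0.0, s0, ec.n_beads)
    traj = integrate_langevin(spec, lp, start.ravel())
    frames = traj.frames.reshape(len(traj), ec.n_beads, 3)
    ref_idx = int(np.argmin(np.abs(traj.cv_series - s0)))
    cdef = ContactDefinition(pair_list=spec.native_pair_list,
                             cutoff=spec.contact_cutoff)
    series = native_contacts(frames, cdef, frames[ref_idx])
    keep = subsample_frames(frames, 200)
    clusters = cluster_conformations(frames[keep],
                                     config.seeding.folded_stage_cutoff,
                                     metric="aligned_rmsd")
    return shannon_entropy(series).S, clusters.n_clusters


def full_run(config: PipelineConfig) -> RunReport:
    """Execute the whole workflow on the three-variant suite."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    suite = make_variant_suite(config.variants or None)
    per_variant = {}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    for i, label in enumerate(suite.labels):
        spec = suite.specs[label]
        vseed = _derive_seed(config.seed, 100 + i)
        logger.info("variant %s: starting estimation", label)
        try:
            res = estimate_variant(spec, config, vseed)
        except Exception as e:
            raise RuntimeError(f"stage failure in variant {label!r}") from e
        b, t = spec.barrier_height, spec.asymmetry
        # matched noise across variants (common random numbers) so the
        # entropy comparison is paired, not confounded by seed-to-seed spread
        entropy_S, n_folded_clusters = contact_entropy_for_variant(
            b, t, config, _derive_seed(config.seed, 200))
        res["contact_entropy_J_per_molK"] = entropy_S
        res["n_folded_clusters"] = n_folded_clusters
        res["design_p_folded"] = suite.design_folded_population[label]
        model = res.pop("_model")
        macro = res.pop("_macro")
        res.pop("_clusters")
        if outdir is not None:
            from .io import save_msm
            save_msm(outdir / f"msm_{label}.h5", model, macro)
        per_variant[label] = res
    report = RunReport(
        per_variant=per_variant,
        provenance={"config_hash": config_hash(config),
                    "version": __version__, "seed": config.seed})
    if outdir is not None:
        (outdir / "report.csv").write_text(report.body_text())
    return report
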