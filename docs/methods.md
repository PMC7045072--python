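# Methods

## The model problem

A protein that fluctuates between a dominant folded state and a rare,
partially unfolded state is represented by a particle on a low-dimensional
energy landscape.  All computation uses reduced units: `kB = 1`, reference
temperature `T = 1` (so energies are in kT), unit mass, and a
dimensionless collective variable (CV).  `unfoldmsm.units` converts
energies to kcal/mol and temperatures to Kelvin for display only; nothing
downstream depends on physical units.

Two landscape families are provided.

**Quartic double well** `U(x) = B((x/a)² − 1)² + (t/2)(x/a)` with half
separation `a = well_separation/2`.  `B` is the barrier of the symmetric
well; the tilt `t` is, to a very good approximation, the free-energy
offset between the wells.  The folded state is the low-CV well at
`x ≈ −a`.  The CV is `x` itself, so the exact free-energy profile is
`U(x)` up to a constant and exact state populations follow from
one-dimensional quadrature of `exp(−U/kT)` on either side of the barrier
top.  These quadratures are the ground-truth oracles for every
population-recovery test.

**Bead chain** — a Gaussian chain (harmonic bonds with zero rest length,
stiffness `k`) of `n` beads, plus the same double well applied to the
end-to-end distance `s = |r_n − r_1|`, the toy analogue of the Cα–Cα
distance across an initial protease cleavage site.  With bond-only
end-to-end density `p0(s) ∝ s² exp(−k s²/(2(n−1)kT))` in closed form, the
exact CV free energy is `F(s) = U_cv(s) − kT ln p0(s)`; a Monte-Carlo
integration over the Gaussian-chain ensemble serves as the independent
oracle in tests.  Native-contact candidate pairs connect the first three
to the last two beads, mimicking backbone donor–acceptor pairs bridging
the two helices that flank a cleavage site; they are analysis-layer
geometry, not energy terms.

**Variant suite.**  Three parameterizations mimic a graded-stability
series: stabilized `(B, t) = (7, 3)`, wildtype `(6, 2)`, destabilized
`(5, 0.8)` kT, chosen once so that the analytic folded populations come
out near 0.95 / 0.87 / 0.68 — the qualitative pattern of a stabilized
point mutant, a wild-type allergen and a destabilized natural isoform —
and so that the folded-side escape barriers (≈ 8.5 / 7 / 5.4 kT) order
the unfolding times the same way.  The populations stored in the suite
are always computed by quadrature at run time, never hard-coded.

## Integrator

BAOAB splitting of underdamped Langevin dynamics (kick / drift /
Ornstein–Uhlenbeck / drift / kick), mass 1.  BAOAB has very small
configurational sampling error at practical timesteps; with `dt = 0.004`
(well frequencies ω ≲ 8) the sampled CV density matches analytic
quadrature to KL < 0.001 at 10⁶ frames.  Runs are bit-reproducible:
every stochastic stream is derived from a named seed via
`numpy.random.SeedSequence`, and the core loops are numba-compiled with
their own seeded generator.  Divergence (non-finite coordinate) raises an
error naming the step.  Temperature 0 with a start at a stationary point
reproduces the start exactly.

## Well-tempered metadynamics

Gaussians of width σ are deposited every `pace` steps at the current CV
value with the well-tempered height `h = w0·exp(−V(s)/((γ−1)kT))`.  The
bias and its force are cached on a grid of spacing σ/25 (linear
interpolation error < 10⁻³ of a hill height; exact summation remains
available for arbitrary points) with hills truncated at 6σ.  Two
estimators recover the unbiased profile:

* the asymptotic well-tempered limit `F(s) = −γ/(γ−1)·V(s, t_end)`, and
* Tiwary–Parrinello reweighting: frame weights
  `∝ exp((V(s_t, t) − c(t))/kT)`, with
  `c(t) = kT ln[∫e^{γV/((γ−1)kT)}ds / ∫e^{V/((γ−1)kT)}ds]`
  recomputed on the bias grid after every deposition; frames between
  depositions use the latest `c(t)`.  With zero bias the estimator reduces
  exactly to `−kT ln(histogram)`.

On a tilted double well (barrier 5 kT, tilt 2 kT), a single 600k-step run
(3,000 hills, `w0 = 0.5`, σ = 0.15, γ = 10) reweights to ≈ 0.1 kT RMSE
against quadrature within the region 4 kT above the minimum; the
well-tempered limit agrees to ≈ 0.2–0.35 kT.  A pairwise-RMSE diagnostic
across replicas quantifies the well-known spread of single-replica
estimates on rough landscapes.

The published all-atom protocol (hill height 10.0 kcal/mol, width 0.35,
biasfactor 30, deposition every 1,000 steps) ships as the `paper-units`
config preset, converted to reduced units at 310 K; the reduced-unit
defaults used in tests are scaled equivalents.

**Barrier-crossing demonstration.**  To contrast biased and unbiased
sampling at an 8 kT barrier the package uses friction γ = 48 and runs of
48 time units.  These values come from a Kramers-rate analysis: the
spontaneous crossing rate (ω₀ω_b/2πγ)·e^(−8) ≈ 5·10⁻⁵ per time unit makes
an unbiased crossing in ten such runs a ≲3% event, while the biased
replicas (hills of 2 kT every 0.2 time units, γ_bias = 40) fill the well
and cross with a ≳2× time margin — in a 400-run pilot sweep every biased
replica crossed and no unbiased run did.  The check is nevertheless
stochastic, not a certainty.

## Seeding

Biased frames are pooled, uniformly subsampled to ≤ 2,000 frames (the
O(n²) distance matrix, not information, is the constraint), and clustered
by average-linkage hierarchical clustering cut at a distance cutoff
(scipy's implementation; its deterministic merge order is the package's
tie-break convention).  The representative of each cluster is its medoid —
a real member, never an average structure.  Seeds inherit positions only;
every seeded run draws fresh Maxwell–Boltzmann velocities.  For 1D
landscapes the metric is euclidean; for bead chains it is RMSD after
optimal (Kabsch) superposition.

**Adaptive round allocation.**  The precision of MSM populations is
limited by transition statistics near the barrier, not by well sampling.
Each medoid therefore receives a base number of independent seeded rounds
(default 24), and medoids inside the *barrier window* — the CV interval
within 2.5 kT of the barrier top of the averaged well-tempered-limit FES
from the metadynamics stage (an estimate the pipeline already owns; the
analytic oracle is never consulted) — receive 168 extra rounds.  Seeded
runs use `dt = 0.008` and friction 4: more strongly overdamped than the
metadynamics stage, which makes the CV-projected dynamics more nearly
Markovian at the MSM lag while keeping barrier diffusion fast.  In
repeated pilot runs this design recovers the stabilized variant's folded
population with a standard deviation of ≈ 0.006–0.01, comfortably inside
the ±0.03 target of the headline check.

## Markov state model

* **tICA** on the CV features: symmetrized instantaneous and time-lagged
  covariances, `C0` regularized by `1e−6 ×` its largest eigenvalue on the
  diagonal, generalized eigenproblem solved in the whitened basis;
  components are C0-orthonormal with a deterministic sign convention.
* **Microstates**: k-means, `k = min(100, n_frames/50)` by default
  (honoring the 100-microstate protocol at scale while avoiding empty
  states on small data).  Centers are fitted on ≤ 200k strided frames and
  all frames are assigned; fixed `random_state` makes it deterministic.
* **Counts**: sliding-window at lag τ (default 25 frames ≈ 3 reduced time
  units); states outside the largest strongly connected component of the
  count graph are trimmed with a logged report.
* **Estimator**: reversible maximum likelihood by the standard fixed-point
  iteration on the symmetric flux
  `x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j)`, iterated until the
  stationary distribution moves < 10⁻¹²; detailed balance then holds to
  ≲ 10⁻⁸ and rows sum to 1 to 10⁻¹⁰.  A nonreversible (row-normalized)
  estimator is available for comparison.
* **Uncertainty**: per-row Dirichlet posterior over observed transitions.
  Sliding-window counts at lag τ overlap, so the Dirichlet concentration
  uses effective counts `C/τ`; without this the posterior (and the
  Chapman–Kolmogorov bands) are overconfident by roughly √τ.  Summaries
  are mean ± sd over sampled stationary distributions.
* **PCCA+**: memberships from the inner-simplex vertex construction on the
  dominant right eigenvectors of the reversible matrix, clipped to [0, 1]
  and row-normalized; crisp states by argmax.  Default 2 macrostates
  (folded / partially unfolded).  Both crisp and membership-weighted
  macro populations are reported.
* **Kinetics**: implied timescales `t_i = −τ/ln|λ_i|` (flagged lags rather
  than silently dropped; near-unit eigenvalues report ∞), mean
  first-passage times by linear solve (π-weighted over the source set),
  forward/backward committors, net reactive flux
  `F_ij = max(0, f_ij − f_ji)` with `f_ij = π_i q⁻_i T_ij q⁺_j`, and
  pathway decomposition by iterative widest-path (bottleneck) peeling.
* **Validation**: Chapman–Kolmogorov compares the propagated base model
  `T(τ)^k` against a re-estimation at lag `kτ` on macrostate sets, with
  bands from the posterior of the re-estimated model; implied-timescale
  flatness on Markovian data; the CK test demonstrably fails on a
  hidden-state (lumped, non-Markovian) counterexample.

The folded-state population is the stationary weight of the macrostate
containing the reference (native) microstate — the connected microstate
nearest to the folded minimum in tICA space.  The reported "unfolding
timescale" is the MFPT from the folded to the unfolded macrostate, whose
ordering across variants is governed by the folded-side barrier and is
much more robust at finite statistics than the global relaxation time t₂
(also reported).

## Descriptors

Native contacts: a candidate pair is *native* if formed in the reference
frame and *formed* when its distance is strictly below the cutoff
(boundary-equal distances are not contacts).  The Shannon entropy of the
per-frame count distribution uses one bin per integer count (any coarser
binning changes S) and is reported as `S = −R Σ p ln p` in J/(mol·K).
In the pipeline the three variants' entropies come from matched-length
folded-state bead-chain runs driven by common random numbers (the same
noise stream for all three variants), so the comparison is paired and the
ordering destabilized > wildtype > stabilized is resolved at run lengths
of 6,000 frames.  The folded-state ensemble is also clustered at a finer
aligned-RMSD cutoff (default 0.35) and the resulting cluster count is
reported per variant; on the bead chain this count is dominated by
variant-independent bond fluctuations and is a provenance descriptor, not
a stability ranking.  RMSF and 2D-RMSD use optimal rigid-body superposition
on all particles and are invariant under global rotation/translation to
10⁻⁸.  Combined PCA is fitted on the pooled multi-variant data and
projects each variant separately; free-energy surfaces over (PC1, PC2)
use `−kT ln` of the weighted bin density with unoccupied bins flagged as
NaN, and accept MSM stationary weights to produce bias-corrected
surfaces.

## Problem sizes

Defaults were chosen so a full three-variant pipeline runs in about one
minute on a single CPU while leaving the headline population errors
statistics-dominated at ≈ 0.01: per variant, 6 metadynamics replicas ×
40k steps; ~40 seeds; 24 base + 168 barrier-boosted seeded rounds × 20k
steps at `dt = 0.008`; `k = 100` microstates; lag 25 frames; 60 posterior
samples.  The seeding-bias demonstration uses 640 half-and-half seeded
runs of 30k steps on a (5, 2) kT landscape.

## Known limitations

* The toy layer has no solvent, no explicit secondary structure, and a
  one-dimensional reaction coordinate by construction; passing tests show
  the *estimators* are correct and the *workflow* removes seeding bias on
  landscapes where the CV is a good reaction coordinate.  They cannot
  show that an end-to-end distance is a sufficient CV for a real protein
  — the motivating study itself found single-replica reweighted profiles
  unreliable for exactly that reason, which is why the seeding + MSM
  stage exists.
* Reversible-MLE populations acquire a bias when trajectories are much
  shorter than the local relaxation they must stitch across (observed
  here in controlled experiments with trajectory length ≲ the basin
  exchange time); the pipeline's seeded-run lengths are chosen so each
  run is long relative to within-basin relaxation.
* The Dirichlet sampler is a nonreversible posterior around a reversible
  point estimate — adequate for interval estimates at this scale, but not
  a full reversible Bayesian MSM.
* The Chapman–Kolmogorov pass criterion is band-based; with extremely
  large data sets even excellent models can fail a naive band test, which
  is why effective counts enter the bands.
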