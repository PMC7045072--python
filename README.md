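# unfoldmsm

Thermodynamics and kinetics of **local (partial) protein unfolding** from
enhanced-sampling simulation data, reconstructed with Markov state models.

Proteases cannot cleave a site buried in stable secondary structure: the
protein must unfold locally before the first cut.  The equilibrium
probability of that rare, partially unfolded state — far below the
detection limit of structural experiments — therefore controls proteolytic
susceptibility.  This package implements, as a tested and reusable
pipeline, the simulation strategy used to estimate such probabilities for
graded-stability variants of the birch pollen allergen fold:

1. **Well-tempered metadynamics** along a scalar collective variable
   (an end-to-end distance across the cleavage site) drives the system
   over the unfolding barrier.  Gaussian hills of height
   `h = w0 · exp(−V(s)/((γ−1)kT))` are deposited every `pace` steps;
   the unbiased profile is recovered both from the well-tempered limit
   `F(s) = −γ/(γ−1)·V(s)` and by Tiwary–Parrinello time-dependent
   reweighting with the running offset `c(t)`.
2. **Clustering-based seeding**: the biased ensemble is clustered
   (average-linkage hierarchical clustering with a distance cutoff), and
   each cluster medoid starts a swarm of *unbiased* Langevin runs with
   fresh Maxwell–Boltzmann velocities.
3. **Markov state model**: tICA → k-means microstates → sliding-window
   counts at a lag → largest strongly connected set → reversible
   maximum-likelihood transition matrix → PCCA+ macrostates.  The
   stationary distribution π removes the seeding bias and yields the
   folded-state population `p_folded = Σ_{i∈folded} π_i`, with
   uncertainties from a per-row Dirichlet posterior; implied timescales,
   a Chapman–Kolmogorov test, mean first-passage times, committors and
   net reactive flux complete the kinetic picture.

Because the original all-atom trajectories are not public, the package
ships a first-class **toy-physics layer**: BAOAB Langevin dynamics on
double-well landscapes and on a bead chain whose end-to-end distance plays
the role of the cleavage-site CV.  Every stage is exercised against
analytic ground truth (quadrature free energies and populations), and a
three-member variant suite (stabilized / wildtype / destabilized) mimics a
stability series with design folded populations ≈ 0.95 / 0.87 / 0.68.

Folded-state flexibility descriptors are included: native-contact counts,
the Shannon entropy of the contact-count distribution (in J/(mol·K)),
RMSF, 2D-RMSD, and combined-ensemble PCA free-energy surfaces.

## Worked example

```python
from unfoldmsm.pipeline import PipelineConfig, full_run

report = full_run(PipelineConfig(seed=1, log_level="WARNING"))
for label, r in report.per_variant.items():
    print(f"{label:12s} p_folded = {r['p_folded']:.3f} ± {r['p_folded_sd']:.3f}"
          f"  (design {r['design_p_folded']:.3f})"
          f"  unfolding MFPT = {r['unfolding_mfpt']:.0f}"
          f"  S_contact = {r['contact_entropy_J_per_molK']:.2f} J/(mol K)")
```

prints (reduced time units; ~1 minute on one CPU):

```
stabilized   p_folded = 0.963 ± 0.005  (design 0.948)  unfolding MFPT = 9189  S_contact = 7.50 J/(mol K)
wildtype     p_folded = 0.869 ± 0.009  (design 0.872)  unfolding MFPT = 1445  S_contact = 7.99 J/(mol K)
destabilized p_folded = 0.688 ± 0.012  (design 0.681)  unfolding MFPT = 362   S_contact = 8.44 J/(mol K)
```

Each folded population is recovered within ±0.02 of the analytic
Boltzmann value of its landscape, the populations and unfolding mean
first-passage times are strictly ordered stabilized > wildtype >
destabilized, and the contact entropies are ordered the other way —
the destabilized variant is the most flexible.  The same workflow is
available stage by stage from the shell via the `unfoldmsm` command
(`simulate`, `metad`, `seed`, `run-seeded`, `descriptors`, `msm`,
`full-run`, `report`).

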