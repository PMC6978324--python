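# Methods

## Scope and design

The package implements the analysis chain by which a sodium-dependent
population shift between two metastable protease conformations (active E,
inactive E\*) is inferred from conformational ensembles: geometric
featurization → TICA → k-means microstates → reversible MSM → PCCA+
two-state lumping → stationary probabilities, MFPTs, weighted feature
distributions and dihedral entropies. Because microsecond-scale MD data
for such a system is not shippable, a synthetic-dynamics module generates
ground-truth trajectories with the same statistical structure, and every
stage is validated against independent oracles (enumeration, brute-force
agglomeration, generic constrained optimization, Monte-Carlo first
passages, grid quadrature).

## Synthetic double well

The latent system is 2-D overdamped Langevin dynamics (Euler–Maruyama,
unit friction, `x' = x − ∇U dt + sqrt(2 kT dt) ξ`) on

```
U(x) = −A_E exp(−|x−c_E|²/2s²) − A_* exp(−|x−c_*|²/2s²) + (κ/2)|x−mid|²
```

* Centers `c_E = (1.2, 0.5)`, `c_* = (−1.2, −0.5)` (reduced length units).
  Separating the wells along both latent coordinates makes the fast
  coordinate's marginals differ between states, as real activation
  descriptors do.
* Well depths `(A_E, A_*) = (2.6, 3.0)` kT: without sodium the inactive
  state is favoured (E ≈ 0.45), mirroring the sodium-free regime of the
  modelled protease.
* `sodium_coupling = 1.2` kT is added to the E depth when the sodium
  state is on, shifting E to ≈ 0.61 — a population reversal of the same
  character (not magnitude) as the modelled system.
* The Gaussian width `s` is not free: it is solved (Brent) so the saddle
  along the inter-well segment sits `barrier_height = 2.0` kT above the
  deeper well. A 2 kT barrier separates timescales enough for two-state
  kinetics while keeping well exchange observable in short trajectories.
* Confinement `κ = 1.0` kT/unit² about the midpoint. A weaker confinement
  lets trajectories make long excursions into flat outer regions; those
  excursions then compete with well exchange for the slowest MSM mode and
  the two-state analysis becomes ill-posed at desk scale. κ = 1 bounds the
  accessible area without distorting the wells (well curvature ≈ 10–12).
* Stability: Euler–Maruyama on a harmonic mode of stiffness k requires
  `dt < 2/k`; the stiffest curvature is ≈ max depth / s², so the default
  `dt = 1e-3` (and the `5e-3` used in pipeline runs) are far inside the
  bound, which is checked and reported at call time.

The targeted sampler adds a one-sided harmonic `½ k (d − target)²` on the
Euclidean deviation `d` from a reference point, active only while
`d > target`, with the target ramped linearly and then held — the latent
analogue of an RMSD-ramped targeted-MD protocol (the structural Kabsch
RMSD lives in `structures_features`; in 2-D latent space no rotation fit
is needed). The force constant is chosen for toy-system stiffness
(tens of kT per squared length unit), not mapped to any physical value.

## Reference solutions (oracles)

Populations come from Boltzmann quadrature on a regular grid (default
120² over the well bounding box padded by 3.5 units, convergence checked
against 2× refinement); the E/E\* split is the perpendicular-bisector
half-plane. Kinetics come from the discretized Smoluchowski generator
with detailed-balance hopping rates `q_ij = (kT/h²) exp(−(U_j−U_i)/2kT)`:
the slowest relaxation time is −1/λ₂ of the π-symmetrized generator, and
MFPTs solve `L m = −1` with the opposite well core (radius `s` around the
centre) as target — targeting the dividing ridge alone would undercount
by the committor factor. With the core convention the two-state identity
mfpt(E→E\*)/mfpt(E\*→E) = π_E/π_E\* holds within ~1–2 % whenever the
barrier is ≳ 2 kT.

## Embedding

A smooth deterministic map places a minimal chymotrypsin-numbered
topology (catalytic triad Cα trio; W215 with three heavy atoms; the
17-residue loop V213–T229 including the 221a insertion and without a
residue 218; anchor backbone oxygens on R221a and K224; an optional Na⁺
particle) such that latent coordinate 1 drives PhiD monotonically through
its sign change (E basin → PhiD > 0) and RCT, latent coordinate 2 drives
WCT and GG, and the sodium state parks the ion ≈ 2.3 Å from both anchor
oxygens (bound) or 40 Å away (unbound). Every loop Cα also drifts
smoothly with both coordinates so the residue-COM features embed the full
2-D latent manifold. The PhiD sign convention (E positive) is this
package's own and is used consistently throughout; the literature on the
modelled system is not internally consistent on this sign.

## Featurization conventions

* Centres of mass are unweighted (geometric) means of heavy atoms; a
  mass-weighted toggle exists. Distances in Å, dihedrals in degrees on
  (−180°, 180°] with the IUPAC sign convention.
* Residue-COM features are computed after global Cα superposition onto a
  reference frame (first frame by default) — Cartesian features are
  meaningless under rigid-body diffusion.
* The sodium coordinate is 1 iff one Na⁺ is simultaneously within the
  cutoff (3.8 Å, boundary inclusive) of both anchor oxygens.
* The catalytic triad defaults to the Cα of residues 57, 102, 195 and is
  configurable.

## Estimators

* **TICA**: reversible (symmetrized) estimator with a common mean over
  leading and lagged halves, so `C(0) ± C(τ)` are positive semidefinite
  and all eigenvalues lie in [−1, 1] up to the regularization shift.
  `C(0)` is shrunk by `1e-6 · mean diagonal · I` to keep near-constant
  columns (the binary sodium flag) well posed. Lagged pairs never cross
  trajectory boundaries. Four components retained by default.
* **k-means**: k-means++ seeding (fixed default seed), Lloyd iterations
  with inertia verified non-increasing each sweep; an emptied cluster is
  re-seeded from the point farthest from its centre. Tie-breaks go to the
  lowest centre index.
* **Average linkage**: UPGMA via the pairwise-distance merge tree; the
  flat cut takes the first n−k merges, guaranteeing exactly k clusters;
  representatives are medoids (an existing frame, not a coordinate mean).
* **Reversible MSM**: sliding-window counts, trim to the largest strongly
  connected component, then the self-consistent fixed-point iteration for
  the detailed-balance-constrained MLE (relative tolerance 1e-10, up to
  1e6 sweeps, non-convergence is an error). The spectrum is computed via
  the π-symmetrized matrix, so eigenvalues are real.
* **PCCA+**: inner-simplex vertex search on the dominant right
  eigenvectors ordered by eigenvalue *value* (a strongly negative
  eigenvalue can exceed slow modes in modulus but carries no
  metastability); memberships are clipped to [0, 1] and row-normalized;
  a vanishing spectral gap at the requested state count is an error.
* **MFPT**: linear system at the model lag; set-to-set values average the
  source states under the stationary distribution restricted to the
  source. Physical units via lag × frame timestep.
* **Uncertainty**: trajectory bootstrap (resample trajectories with
  replacement, re-run estimate → PCCA → MFPT, percentile intervals).
  This is deliberately prior-free and reproducible; a posterior-sampling
  ("Bayesian MSM") scheme would need prior and sampler choices the
  analysis does not otherwise depend on. Metastable identities are
  matched across resamples by microstate-membership overlap with the
  point estimate; ambiguous matches are skipped, and more than 50 %
  skipped resamples is an error. Percentile intervals need O(100+)
  resamples before the 2.5/97.5 quantiles stabilize; coverage
  experiments in the test suite use 150.
* **Frame weights**: `π_i / N_i` per frame in microstate `i`, excluding
  microstates whose largest metastable membership is ≤ 0.90 and
  renormalizing. This (rather than weighting by the metastable-state
  probability) reproduces stationary expectations exactly, which the
  tests assert as an identity.
* **Dihedral entropy**: von Mises kernel density (κ = 50 by default,
  bandwidth → κ via the reciprocal-squared rule) on a 360-point grid,
  entropy by quadrature over the circle in radian measure. The circular
  KDE avoids binning artifacts and has closed-form test cases
  (uniform → ln 2π; von Mises → ln(2πI₀(κ)) − κI₁(κ)/I₀(κ)).
* **Histograms**: Freedman–Diaconis bins on the pooled retained data,
  shared across states for comparability; per-state areas sum to one.

## Desk-scale study conditions

Pipeline validation runs use 8 trajectories × 30 000 steps at dt 5e-3 per
sodium condition (recovery against quadrature references, trajectory
bootstrap with 30 resamples), a 5-point sodium-coupling scan at 6 × 20 000,
and 5-seed condition comparisons at 4 × 10 000. These sizes give roughly
20–60 well transitions per trajectory — comfortably in the regime where a
two-state MSM is identifiable — while the whole suite stays desk-sized.
TICA lag and MSM lag are 50–100 steps (0.25–0.5 reduced time units),
inside the implied-timescale plateau of the synthetic system; production
defaults in the CLI mirror the published protocol instead (4 TICs, 400
microstates, an 80 ns lag = 8000 frames at a 10 ps stride, 0.90
membership cutoff).

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analysis
assumes: slow two-state exchange modulated by a binary control parameter,
fast intra-well dynamics, geometric features driven monotonically by the
latent coordinates, and a sodium flag correlated with the slow
coordinate. It does not reproduce rugged many-well landscapes,
force-field physics, solvent, discretization error from imperfect
featurization of a 3N-dimensional system, or experimental comparisons.
Passing tests therefore demonstrate correctness of the estimators and the
end-to-end machinery — not that any particular protein has the inferred
landscape.

## Known limitations

* PCCA+ uses the inner-simplex construction without the subsequent
  feasibility optimization; for two metastable states (the supported
  production case) the two are equivalent up to membership clipping.
* The Chapman–Kolmogorov test re-estimates at k·τ from the same data, so
  its error bars are bootstrap-based and correlated across k.
* The PDB reader normalizes insertion codes to lower case ("221a");
  mixed-case codes in the same residue number would collide.
* Multi-chain topologies are supported in the data model but the
  featurization helpers resolve residue labels chain-agnostically.
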