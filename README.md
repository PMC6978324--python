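# thrombin-msm

Markov-state-model (MSM) analysis of the sodium-regulated equilibrium
between the active (E) and inactive (E\*) conformations of thrombin-like
serine proteases — built as a reusable, fully tested pipeline, with a
synthetic-dynamics module that provides exactly solvable ground truth for
every stage.

## Who this is for

Computational structural biologists who want to quantify an allosteric
population shift from conformational ensembles: featurize structures in
chymotrypsin numbering (insertion codes such as R221a included), reduce
with time-lagged independent component analysis (TICA), discretize with
k-means, estimate a reversible MSM, lump it into metastable states with
PCCA+, and report stationary probabilities, mean first passage times
(MFPTs), MSM-weighted feature distributions and circular dihedral
entropies.

## The model

A trajectory ensemble discretized into microstates is summarized by a
row-stochastic transition matrix `T(τ)` at lag time `τ`, estimated by
maximum likelihood under detailed balance `π_i T_ij = π_j T_ji`. Its
spectrum gives implied timescales `t_i = −τ / ln λ_i(τ)`; PCCA+ lumps
microstates into two metastable states via the dominant eigenvectors;
MFPTs solve `m_i = τ + Σ_j T_ij m_j` with `m = 0` on the target set.
Equilibrium feature distributions weight each frame by `π_i / N_i` for its
microstate `i` (microstates with metastable membership ≤ 0.90 excluded).

Geometric descriptors follow the activation-state conventions of the
field: `WCT` (W215 heavy-atom centre to catalytic-triad Cα centre), `RCT`
(R221a guanidinium C to triad centre), `GG` (G193–G216 Cα distance, S1
pocket), `PhiD` (φ of D221, the slow loop torsion), the binary sodium
coordinate (Na⁺ within 3.8 Å of both the R221a and K224 backbone oxygens)
and residue-wise centres of mass of the sodium-loop V213–T229.

The synthetic module generates overdamped Langevin dynamics on a 2-D
double well whose E-well depth grows with a sodium-like coupling,
deterministically embedded into toy loop structures so every geometric
feature is computable; grid quadrature and the discretized Smoluchowski
generator provide independent reference populations, relaxation times and
MFPTs.

## Worked example

```python
from thrombin_msm.pipeline import run_synthetic_condition
from thrombin_msm.synthetic_dynamics import PotentialSpec, reference_solution

spec = PotentialSpec()            # E well 2.6 kT, E* well 3.0 kT, coupling 1.2 kT
res_off = run_synthetic_condition(spec, sodium_state=0, seed=101, n_boot=30)
res_on = run_synthetic_condition(spec, sodium_state=1, seed=202, n_boot=30)
print("without Na+: E =", round(res_off.populations["E"], 3))
print("with Na+:    E =", round(res_on.populations["E"], 3))
print("reference:   E =", round(reference_solution(spec, 0).populations[0], 3),
      "/", round(reference_solution(spec, 1).populations[0], 3))
```

prints (seeds as above, 8 trajectories × 30 000 steps per condition):

```
without Na+: E = 0.486
with Na+:    E = 0.585
reference:   E = 0.453 / 0.607
```

i.e. the pipeline recovers the quadrature ground truth within its
bootstrap confidence intervals, and switching the sodium coupling on
shifts the equilibrium toward the active E state — the qualitative
population-shift mechanism the pipeline is designed to detect. The same
stages are scriptable from the shell via the `thrombin-msm` CLI
(`simulate`, `embed`, `featurize`, `tica`, `cluster`, `msm`, `its`, `ck`,
`report`, …).

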