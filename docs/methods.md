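# Methods

## Model summary

Each cell is a diffuse two-dimensional domain described by a phase
field φ (1 inside, 0 outside) whose ½-level set is the membrane. The
interface obeys an overdamped force balance: an active term
(αρχ − β)|∇φ| that protrudes where active Rac ρ is high **and** the
substrate is adhesive (stripe field χ), and the variational force of a
Hamiltonian with

* line tension γ(P) — constant γ₀ below a critical perimeter P_cr and
  stiffening as γ₀(1 + γ_per(P − P_cr)) above it, which caps the
  unlimited perimeter growth that strong cell–cell adhesion would
  otherwise drive;
* bending rigidity κ acting on the deviation of the interface profile
  from its equilibrium tanh shape;
* pairwise terms: volume exclusion (g/2)·φ⁽ⁱ⁾φ⁽ʲ⁾ and an
  interface–interface adhesion −σ ε³ C_adh |∇φ⁽ⁱ⁾|²|∇φ⁽ʲ⁾|².

Cell polarity is a mass-conserved wave-pinning circuit: membrane Rac
attaches from a well-mixed cytosolic pool at rate k_b(ρ²/(K_a²+ρ²) +
k_a) ρ_cyt and detaches at k_c(1 + I/I₀)ρ. The conserved per-cell
total N_tot closes the system through ρ_cyt = (N_tot − ∫φρ)/∫φ. The
inhibitor I decays at k₋I, receives δ-correlated Langevin noise of
amplitude η, and is produced at contacts by contact repolarization
(k_CR, any overlap) and front repolarization (k_FR, only where the
neighbour's φρ exceeds the critical overlap O_crit), each through the
saturating switch S(x) = max(0, tanh(x/x₀)). I may be negative — it
measures the deviation of the detachment rate from base; runs are
flagged invalid if the effective detachment rate would turn negative.

Chemistry inside the moving cell uses the φ-weighted conservative form
∂t(φu) = ∇·(φD∇u) + φf, whose sharp-interface limit is the bulk
reaction–diffusion equation with no-flux membrane boundary conditions.

## Numerics

* Lattice: cell-centred, dx = 1 µm, interface width ε = 3 µm (the
  dx ≤ ε/2 rule), periodic in x (stripe axis), mirror/no-flux in y.
  Collision domain 160 × 40 µm, single-cell domain 96 × 40 µm.
* Time stepping: first-order explicit Euler, dt = 0.04 s; halving dt
  changes the single-cell steady speed by < 0.1%. The validator bounds
  dt by dx²/(8 max D) because the harmonic face weighting (below) can
  double the worst-case diffusive rate.
* Transport stencil: face fluxes with **harmonic-mean** φ weights. An
  arithmetic mean makes the effective CFL number of the concentration
  update diverge in the interface tail (flux ∝ φ_face but mass ∝ φ_i);
  the harmonic mean bounds it. φ is clipped at 0 inside the stencil —
  the interface law tolerates small undershoots and a negative face
  weight would act as negative diffusivity.
* Discrete energies are written so the analytic forces are their exact
  lattice gradients (face-based Dirichlet term ↔ 5-point Laplacian);
  the suite verifies this against brute-force differentiation.
* γ(P) enters quasi-statically as a scalar prefactor re-evaluated each
  step; the nonlocal γ′(P) term is omitted (γ(P) exists only to cap
  perimeter growth, which the prefactor form achieves).
* Hot loops are numba kernels mirroring the numpy discretisation
  one-to-one; the energy-gradient oracles and closed-form tests cover
  them.

## Calibration (shipped defaults)

Printed constants are kept verbatim: γ_per = 0.5 µm⁻¹, P_cr = 58 µm,
I₀ = 1 µm⁻², x₀ = 0.1, β = 0.2 pN/µm, γ₀ = 1.8 pN, k_b = 10 s⁻¹,
α = 0.4 α₀, T = 2500 s. The remaining constants were fixed by the
three-stage protocol in `scripts/calibrate.py`:

1. **0-D wave-pinning analysis.** K_a = 1 µm⁻² scales the pinned
   plateau pair to (0.011, 1.49) µm⁻²; k_a = 0.005 sets their ratio
   (≈ 135, matching front ≈ 1.4 vs rear ≈ 0.01); k_c = 7 s⁻¹ places
   the pinning cytosol density at ρ_cyt ≈ 1.5 µm⁻². The large
   cytosolic reservoir matters: the Maxwell point of this reaction
   form sits only ~7% above the lower fold of the bistable window
   (a structural property, independent of K_a, k_a, k_c), so the high
   plateau survives perturbations only if that 7% margin is large in
   absolute Rac numbers.
2. **Single cell.** N_tot = 595 puts the mechanical area/perimeter
   balance at P ≈ 56.6 µm with band-front ρ ≈ 1.40 µm⁻², band-rear
   ρ ≈ 0.011 µm⁻² and speed ≈ 0.04 µm/s. τ = 3.5 pN s/µm³ sets the
   speed scale; D_ρ = 2 µm²/s keeps the Rac wall sharp enough to hold
   a thin rear cap, D_I = 3 µm²/s spreads the inhibitor across the
   cell within its lifetime 1/k₋I = 10 s.
3. **Pair.** C_adh = 0.462 places the noise-free reversal/sticking
   boundary at σ ∈ (3.80, 3.90) for k_CR = 0.1 s⁻¹, α = 0.4. κ = 0.5
   pN µm² is required here: the quartic adhesion term is an effective
   negative interface diffusivity, and near the pull-off boundary it
   compresses the profile; the bending term penalises exactly that
   distortion. (κ = 1 violates the explicit dt bound.) For the same
   reason C_adh cannot take O(1) values at ε = 3 µm — the dimensional
   ε³ keeps the published energy form, and the single free constant is
   absorbed by this calibration.

Cells are initialised directly on the pinned two-plateau ρ profile
(front-loaded tanh wall through the centre). A weak linear bias was
tried first and rejected: during the unpolarised transient the
contraction + tension shrink the cell, the cytosolic density rises
past the upper ρ branch, and the cell falls into a stable round
uniform-high-Rac state before a front can pin.

Collision protocol: two noise-free relaxed cells, mirrored, centres
1.5 cell diameters apart; replicate variability enters only through
the seeded inhibitor noise (η = 0.25 by default) during the collision
run. Replicates are seed-indexed (base_seed + k) so results are
independent of execution order.

## What the model reproduces, and what it does not

Reproduced (tested):

* single-cell steady state: P ≈ 56.5 µm, ρ_front ≈ 1.4 µm⁻²,
  ρ_rear ≈ 0.01 µm⁻², persistent noise-free migration;
* reversal under strong contact repolarization, with the speed dip
  during repolarization and post-separation boost;
* sticking at high adhesion, with the sharp reversal→sticking
  transition at σ ≈ 3.85 for α = 0.4 (the published crossing);
* perimeter capping by γ(P) (no unlimited growth above the sticking
  transition);
* four-cell trains at reversal parameters stay well distributed.

Not reproduced (documented limitations, left red in the acceptance
suite):

* **The reversal/sticking/walk-past mixture at the reference set**
  (σ = 3.85, k_CR = 0.01, k_FR = 0.04, O_crit = 0.15). With weak CIL
  the head-on stall compresses the cells; the released membrane Rac
  raises ρ_cyt past the wave-pinning fold, the rear cap is consumed,
  and the depolarised pair bonds — sticking dominates instead of a
  reversal majority. The thin fold margin noted above is the root
  cause; strong CR (k_CR = 0.1) writes a large low-Rac region at the
  contact and repolarises cleanly, which is why the transition-regime
  results hold.
* **Walk-past.** Pairs reach the diagonal mid-pass configuration but
  never complete the pass at d = 26 µm (they arrest or depolarise);
  narrow-stripe suppression (0% at d = 22 µm) does hold. At dx = 1 µm
  the Rac wall (width √(D_ρ/k_c) ≈ 0.5 µm) is lattice-pinned, which
  stabilises the rear cap but also resists the gentle FR-driven front
  rotation that powers the pass.
* **The propulsion sweep range.** Single cells migrate only for
  α ≈ 0.37–0.47 with the fixed chemistry: the area balance
  α∮ρ ds ≈ βP + 2πγ leaves a feasible high-Rac arc fraction only near
  the calibration point. The transition-line fit is therefore taken
  over α ∈ {0.40, 0.45} and comes out steeper (slope ≈ 16) than the
  published 11.65.

## Scaled protocol of the test suite

The published outcome statistics use 100 replicates of 2500 s runs;
the acceptance tests run 1–3 replicates of 1200–1500 s so the whole
suite stays desk-scale, and compare through Wilson 95% intervals
(which is also the published comparison). `T_sim`, replicate counts
and all classifier thresholds are configuration, not constants.

## What the synthetic classifier fixtures do and do not show

`cilpf.fixtures` builds analytic centre-of-mass tracks with matching
overlap/polarity series for each outcome archetype (including the
double walk-past). They validate the decision rules exactly, but they
contain none of the shape dynamics — classifier performance on real
simulated trajectories is exercised separately by the archetype runs
in the acceptance tests.
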