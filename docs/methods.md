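# Methods

## The problem

Fitting an atomic model into a cryo-EM density map is an inverse problem:
many configurations produce similar maps, and a biasing potential built
naively from the map is rugged at high resolution. `mlfit` implements a
maximum-likelihood formulation: the model structure x is scored by the
likelihood that it generated the observed map ρ, which — under simple
per-voxel scattering statistics — reduces to a similarity score S(ρ, ρˢ)
between the observed map and a model density ρˢ generated from x. The
fitting potential is

    U_tot(x, ρ) = U_ff(x) + U_fit(x, ρ),   U_fit = −k · S(ρ, ρˢ(x)),

with U_ff the structural prior (a molecular force field; here, harmonic
bonds and angles of the toy systems) and k a force constant balancing
the two.

## Forward model: Gaussian spreading

Each atom i with amplitude A_i (1 for heavy atoms, 0 for hydrogens)
contributes a normalized isotropic Gaussian of width σ evaluated at the
voxel centers:

    ρˢ_v = Σ_i A_i (2πσ²)^(−d/2) exp(−|r_i − c_v|² / 2σ²),

where d is the number of non-degenerate grid dimensions (1D/2D model
systems reuse the same code on degenerate grids). The sum is truncated
at a hard real-space radius of 4σ, which keeps >99.8% of the analytic
mass in 3D (chi distribution with 3 degrees of freedom evaluated at 4)
and makes the cost O(atoms · (σ/δ)³). Voxel values are point
evaluations, not per-voxel integrals.

σ is selected so the Gaussian's full width at half maximum equals the
target resolution, σ = res / (2√(2 ln 2)); where no resolution estimate
applies, the finest resolution representable on the grid — twice the
voxel size δ — is used, giving σ ≈ 0.85 δ (1.0447 Å for 1.23 Å voxels).
A separate EMAN2-convention width, σ = res/(π√2) (0.45 Å at 2 Å), is
provided only for building comparison densities for FSC monitoring; the
two conventions are deliberately distinct.

If σ < δ/2 the Gaussian is undersampled and a warning is logged.

## Similarity scores

All four scores are larger-is-better; probability-based kinds require
the target prepared by clipping negatives and rescaling to unit sum
(cryo-EM map values carry an arbitrary scale) and the model density
normalized the same way:

* inner product: S = Σ ρ_v ρˢ_v (equivalent to a potential proportional
  to the inverted density);
* cross-correlation: cosine similarity, no mean subtraction (self-score
  exactly 1);
* relative entropy: S = Σ_{ρ_v>0} ρ_v log(ρˢ_v / ρ_v) = −KL(ρ‖ρˢ) ≤ 0,
  zero iff the densities agree on the support — the maximum-likelihood
  score under per-voxel Poisson counting statistics;
* swapped relative entropy: S = Σ ρˢ_v log ρ_v — the Dirichlet-model
  score, an inner product with the target replaced by its logarithm.

A positivity floor ε = 10⁻¹² (relative to unit-sum densities) clamps
log arguments where the truncated spreading yields exact zeros; where
the floor binds the derivative is zero. Without it, any atom not
overlapping the target support would produce an infinite score. The
score sign convention follows the stated domain [−∞, 0]: some published
forms of these scores carry a leading minus that would contradict
larger-is-better; we fix the convention once, U_fit = −k·S, so fitting
forces are F = k∇S everywhere.

## Forces

The per-atom force is the exact chain rule

    F_i = k Σ_v (∂S/∂ρˢ_v) ∇_{r_i} ρˢ_v,

with the analytic Gaussian gradient and, for the probability-based
kinds, the Jacobian of the sum-to-one normalization propagated
(dS/du_v = (g_v − g·p)/Σu for raw spread u, normalized model p). This
makes F = −∇U_fit to machine-level accuracy, which the test suite
asserts by central finite differences for all four kinds (<10⁻⁵
relative error; measured <5·10⁻⁸).

Multiple time-stepping applies density forces only every N_fit steps,
scaled by N_fit, delivering the same impulse as per-step application.
`estimate_max_timestep` probes the local stiffness of the fitting
potential numerically and reports the oscillation period divided by π;
it is advisory only, since the stiffness depends on map, score kind and
force constant.

## Adaptive force scaling and work

The force constant starts low and is updated once per fitting
application by comparing an exponential moving average (EMA) of S with
its previous value: divide k by (1+α) on an increase (ties included),
multiply by (1+2α) on a decrease. The asymmetry enforces net similarity
increase and, under score fluctuations, ratchets k upward (expected
log-k drift +α/2 per update at 50/50 fluctuations) until the density
term dominates; the run terminates when the largest per-atom force
exceeds f_max, a proxy for integrator stability. α couples to the
simulation time scale via α = N_fit·Δt/τ.

Defaults and rationale:

* EMA weight 0.1 per fitting application — smooths single-step noise
  over ~10 applications; exposed in `ScalingConfig`.
* tie rule ΔS = 0 → decrease k — biases toward gentleness, consistent
  with minimizing exerted work.
* k_init — study-specific; the protocol's premise is to start low and
  let the ratchet find the working range.
* f_max — system-specific; `suggest_fmax` returns 10× the largest prior
  force seen in a short unbiased equilibration. For Brownian dynamics a
  useful bound is f_max·dt/γ ≲ a fraction of σ (displacement per step).

With S as reaction coordinate the exerted work is
W = ∫ k dS ≈ Σ k_frame ΔS_frame; the k logged with each frame is the
one in effect when that frame's S was recorded, so the trajectory's
work column is exactly reproducible from its (k, S) columns. The
protocol's work guarantee — less work than holding k fixed at the
final value — applies to its intended operating regime: start low,
ratchet up under noise, stop at the force threshold, so that k_final is
near the maximum over the trace. It does not apply to a hypothetical
strictly monotone trace (there k only decreases and the inequality
reverses); the test suite therefore checks the guarantee on actual
stochastic refinement runs driven into the force-threshold regime.

## Toy dynamics and model studies

Propagation is overdamped Brownian: x ← x + (Δt/γ)F + √(2kT Δt/γ)·ξ.
The claims under test (landscape shape, work accounting, first-passage
ordering) are propagator-agnostic, so no thermostatted Verlet
integration is included. Identical seeds give bit-identical
trajectories.

Study conditions (reduced units: energy in kT-scale units, length in Å,
γ = 1):

* 1D landscapes — a particle (or two) spread at σ = 1 Å against
  Gaussian targets on a 0.2–0.25 Å grid. The relative-entropy landscape
  for a single particle is harmonic with curvature 1/σ² (quadratic fit
  residual < 1% over ±3σ; measured at rounding level). For two
  particles against two unequal peaks (amplitudes 1:2), inner product
  has its global minimum with both particles coincident on the higher
  peak, while relative entropy has exactly the two assignment minima
  separated by a single swap barrier. Landscape scans of the
  probability-based kinds use a wider model truncation (8σ) so the
  scanned window stays inside the model support; the production default
  remains 4σ.
* 1D refinement — a particle 5σ from the target converges to <0.1σ
  within 15 000 steps (kT = 0.01, Δt = 10⁻³, α = 0.01, k_init = 0.1,
  f_max = 20) under relative entropy, while inner product at a small
  fixed k leaves it >4σ away: the long-range/short-range contrast of
  the two potentials.
* Brownian work benchmark — a Gaussian barrier (height 3, width 1)
  between start x=0 and absorbing target x=10, kT = 0.05, Δt = 10⁻²,
  similarity S(x) = x. The adaptive arm (α = 5·10⁻³, EMA 0.1,
  k_init = 0.02) is compared against a constant force calibrated by
  log-space bisection to the same mean first-passage time within 5%.
  kT well below the barrier is essential: the protocol must see drift,
  not noise, to release force after the barrier — at kT ≈ 0.2 the
  noise-driven ratchet keeps k high and the ordering reverses. At the
  chosen conditions the adaptive arm exerts ~35% less work
  (one-sided Welch test p ≈ 10⁻³⁹ at 100 replicas). Replicas are
  propagated in lockstep (vectorized), and per-replica (k, S) traces
  reproduce the work exactly.
* Bead-helix refinement — a 20-bead helix (rise 1.5 Å, radius 2.3 Å,
  twist 100°/bead; bonds k = 100, angles k = 50 at the built geometry —
  connectivity and stiffness without dihedrals, so the chain can kink)
  refined into the synthetic density of the same helix kinked by 30°
  about its midpoint, spread at σ = 2 Å on a 1 Å grid. Conditions:
  kT = 0.5, Δt = 10⁻³, N_fit = 2, α = 0.01, EMA 0.1, k_init = 5,
  f_max = 300 (≈0.3 Å max step displacement). Five seeded replicas all
  reach ≈3.5% of the initial superposition-free RMSD; the acceptance
  threshold is <25% in ≥4/5. At kT = 1 the noise floor lets only some
  replicas converge within the same budget — the study is run at the
  colder condition.

Distorted starting models are emulated by seeded random coordinate
perturbation (`perturbed`), not by high-temperature unfolding.

## Scoring

FSC uses shells one reciprocal voxel wide up to Nyquist, DC excluded
(otherwise the unweighted average is dominated by a trivially-1 shell);
FSC(s) = Re Σ F₁F₂* / √(Σ|F₁|² Σ|F₂|²) per shell. The unweighted FSC
average is the plain mean over shells — a convergence monitor
independent of the fitting potential. Threshold resolution uses linear
interpolation between shells; a curve that never crosses returns the
Nyquist-limit resolution with a no-crossing flag. Note that the FSC
between a map and a deterministically filtered copy of itself is
identically 1 (the per-shell normalization cancels any radial transfer
function); validating threshold crossings therefore requires a pair
whose true shell correlation is known, which the tests construct as
F₂ = G·F₁ + √(1−G²)·W with independent noise W.

RMSD is computed in the map's absolute frame without superposition
(the density fixes the frame), heavy atoms only; it upper-bounds the
aligned RMSD, which the tests verify against a Kabsch oracle.

## What the synthetic data does and does not emulate

The generators produce noise-free targets from the same forward model
used in fitting (inverse crime by design): they probe the potentials'
geometry, the force algebra, and the scaling protocol, not robustness
to experimental noise, solvent density, masking artifacts, or
map-model mismatch. The relative-entropy score is known to be the most
sensitive of the four to unmodeled density; nothing here measures that.
Passing these studies shows the machinery is correct and the protocol
behaves as designed under ideal data — not that it will outperform
alternatives on deposited maps.

## Numerical choices and degenerate inputs

* Positivity floor ε = 10⁻¹²; derivative zero where it binds.
* All-zero spread with `normalize=True` stays all-zero (an atom set
  entirely outside the grid produces zero force and a finite, very
  negative score).
* Anisotropic grids are readable but rejected by the spreading module.
* MRC origin: ORIGIN header fields when nonzero, else NXSTART·δ; axis
  permutations normalized to X,Y,Z on read, always written X,Y,Z.
* The tie rule, EMA initialization (first score seeds the average, the
  first comparison counts as an increase) and the strict f_max
  inequality are fixed conventions, asserted in tests.
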