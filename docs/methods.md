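# Methods

This note documents the models, conventions, and numerical choices behind
the package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and conventions

Length in Å, energy in kcal/mol, charge in elementary charges,
temperature in K, angles in radians. Coulomb constant
k_e = 332.0716 kcal·Å/(mol·e²); k_B = 0.0019872041 kcal/(mol·K). Bond and
angle energies use the force-field convention **U = K(x − x0)² without the
½ prefactor**; the single exception is the Drude spring, whose self-energy
is ½·k_D·d² so that the charge-on-spring relations below hold exactly.
Atom ids are 1-based in all text formats and 0-based in memory; the
reader/writer layer owns the boundary.

## The toy model family

A `SystemModel` is a topology (atoms with solute/solvent tags, bonds,
angles, 1-2/1-3 exclusions) plus a type-keyed parameter set, tagged with a
Hamiltonian level: `MM` (the sampling force field), `MM'` (tailored), or
`TARGET` (the surrogate high-level Hamiltonian). Builders are pure
functions of (spec, seed).

**Solutes** are acyclic (tree) molecules embedded deterministically from
their equilibrium internal coordinates with a 10⁻³ Å seeded jitter; every
atom gets its own named type, which makes per-bond parameter edits
expressible in a type-keyed table. Rings are out of scope — chemical
realism of the solutes is explicitly not a goal.

**Solvent boxes** place bent triatomic molecules (b0 = 0.9572 Å,
θ0 = 104.52°, stiff springs k_b = 450, k_θ = 55 — rigidity by stiffness,
no constraint algorithm) on a jittered cubic lattice with random
orientations, rejecting any placement with an intermolecular pair closer
than 0.8 × (rmin_half_i + rmin_half_j). The `polarizable4site` variant
adds one Drude oscillator on each central atom. Full-scale production conditions
(1687 waters, ~36.9 Å cells, 5 ns production) are recorded as metadata
constants only; the builders operate at desk scale (8–27 molecules).

**Surrogate targets** stand in for a quantum-level Hamiltonian: they share
the base topology but may shift equilibrium bond lengths and angles,
rescale charges (which also rescales Drude charges, hence α by the square
of the factor), and replace harmonic bonds with Morse wells
U = D(1 − e^(−a(b−b0)))², a = √(k_b/D), matching the harmonic curvature at
the minimum. Perturbation magnitudes are free synthetic choices recorded
in model metadata; they deliberately do not claim correspondence to any
particular quantum method.

## Drude polarization

A polarizable atom with (mechanical) polarizability α and spring k_D
carries a Drude particle of charge q_D = −√(α·k_D); the core charge is
q − q_D so the site's total charge is unchanged. With the ½·k_D·d² spring,
the relaxed displacement in a uniform field E is d = q_D E / k_D and the
induced dipole is q_D d = α E, i.e. α = q_D²/k_D. Note the unit of α here
is e²·Å²·(kcal/mol)⁻¹ — the "mechanical" polarizability; the familiar
volume polarizability is α_Å³ = k_e · α_mech, so the solvent default
α_mech = 10⁻³ (q_D = −1 e at k_D = 1000 kcal/mol/Å²) corresponds to
≈ 0.33 ų.

Self-consistent relaxation (`drude_relax`) iterates the damped fixed
point d ← d + γ(q_D E_local/k_D − d), γ = 0.5, with all atoms held in
place, until the largest displacement-gradient component falls below
10⁻⁸ kcal/mol/Å (default) or 500 iterations; an energy increase across an
iteration raises a polarization-catastrophe error advising a stiffer
spring. An optional radius restricts relaxation to Drude particles within
a given distance of the solute; whether such a radius should scale with
box size is left as a configuration knob. Samplers offer two regimes:
`scf_each_step` relaxes before every energy use (the cold-Drude limit) and
`lagged` carries the previous displacements unchanged, emulating
extended-Lagrangian propagation; the full dual-thermostat machinery is
intentionally not reproduced.

## Energy evaluation

Nonbonded terms use Lorentz-Berthelot combining
(rmin_ij = rmin_half_i + rmin_half_j, ε_ij = √(ε_i ε_j)). Two evaluation
conventions coexist, mirroring the split between simulation and
post-processing:

* **sampling**: 12-6 LJ multiplied by the cubic switching function
  S(r) = (r_off²−r²)²(r_off²+2r²−3r_on²)/(r_off²−r_on²)³ on
  r_on < r < r_off, with defaults r_on = 0.35·edge, r_off = 0.45·edge
  (the 10–12 Å convention rescaled to the toy box); minimum-image Coulomb,
  never switched.
* **bookend** (post-processing): no cutoff, no switching, full
  minimum-image sums.

Periodic electrostatics are minimum-image only — no Ewald/PME; this is a
stated desk-scale limitation, acceptable because toy boxes are small and
the bookend ΔU uses solute-centered terms.

**Alchemical scaling.** Charges first: all solute charges (including
solute Drude charges) are multiplied by (1 − λ_elec), so intra-solute
electrostatics scale as (1 − λ_elec)² and solute-solvent electrostatics
linearly. Then van der Waals: every non-excluded pair involving a solute
atom switches to the separation-shifted soft-core form

    u = σ²/(r² + δ λ σ²),  U = (1 − λ_vdw) · 4ε(u⁶ − u³),

switched like plain LJ, finite at r = 0 for λ > 0, with δ = 0.5 by
default (the reference implementation's defaults are not published; δ is
recorded in every result file). Scaling covers intra-solute nonbonded
pairs as well as solute-solvent ones — this is annihilation, not
decoupling — and is applied identically in gas and aqueous phases so the
hydration cycle is consistent. The protocol constraint λ_vdw > 0 ⇒
λ_elec = 1 (charges off before vdW) is enforced by the
`AlchemicalState` type.

**Decomposition.** `decompose_energy` classifies pair energies by group
membership (solute-solute, solute-solvent elec, solute-solvent vdW,
solvent-solvent); the solvent's own stiff-spring bonded energy is folded
into the solvent-solvent component (the breakdown has no separate slot
for it, and the components must sum to the total). The bookend
ΔU = U_B − U_A between Hamiltonian levels keeps only solute-solute
nonbonded, solute bonded, and electrostatic solute-solvent terms — the
solvent-solvent and solute-solvent vdW contributions are identical at
both levels and cancel. `recenter` translates the solute centroid to the
box center and wraps solvent molecules whole; minimum-image energies are
unchanged and the operation is idempotent.

Analytic gradients cover every term (bonds incl. Morse, angles, switched
LJ, soft-core, minimum-image Coulomb over charge sites, Drude springs);
finite-difference agreement to 10⁻⁶ relative is asserted in the test
suite. They serve the Drude SCF, geometry minimization, and the Langevin
integrator.

## Sampling

The **primary sampler is single-particle Metropolis MC** — exact
stationary distribution, which every statistical test leans on. A step
displaces one uniformly chosen atom by up to ±move_width/2 per axis.
A BAOAB **Langevin** integrator (gas phase, 1 fs / 1 ps⁻¹ defaults) is
provided for completeness but carries finite-timestep bias and backs no
quantitative check.

**λ schedules** are the production grids: charge stage
(0, 0.20, 0.55, 1) for the fixed-charge family and
(0, 0.10, 0.25, 0.50, 0.75, 1) for the Drude family; vdW stage
(0, 0.15, 0.30, 0.45, 0.60, 0.75, 0.87, 0.96, 1) and the 11-point uniform
grid respectively. (The source text describes the first grid as "three
steps" while printing four λ values — four states, three intervals; the
four printed states are what the schedule returns.)

**Replica exchange** attempts neighbor swaps of alternating parity after
every sweep, with acceptance min{1, e^(−β[U_i(x_j)+U_j(x_i)−U_i(x_i)−U_j(x_j)])};
configurations and replica ids travel together, the replica→state map is
checked to remain a bijection, and every energy entering a decision is
logged. The desk default is 50 MC steps between attempts (the full-scale
20 000-step interval is metadata). Seeds: window streams use
base + 1000·repeat + window; swap decisions use base + 1000·repeat + 997.

An annihilation leg runs replica exchange per stage, accumulates
forward/reverse ΔU for each adjacent window pair once per sweep,
estimates each window by BAR, and reports mean ± sample SD (n−1) over
independently seeded repeats (default four).

## Estimators

All exponential averages run through log-sum-exp with max-subtraction
(|βΔU| up to ~700 without overflow — poor overlap is the regime of
interest). BAR solves the self-consistent equation given in the README by
bracketed root finding (`brentq` on a monotone function, bracket at the
two one-sided EXP estimates ± 50 kcal/mol, expanded if needed; tolerance
10⁻⁸ kcal/mol). NBB multiplies each sample's Fermi term by a normalized
weight ∝ e^(+βb); with all biases zero the weights are exactly 1.0 and the
solve is bit-identical to BAR. Degenerate weights (bias ESS < 2 on either
side) are an error with diagnostics, as is a bracket failure.

Within-run BAR uncertainty is deliberately **not** reported on results —
protocol uncertainties come from repeats, and per-window diagnostics carry
effective sample sizes instead. Bennett's large-sample variance
(`bar_asymptotic_variance`) is available as a diagnostic; the validation
benchmarks use it where a stable single-run error scale is needed (see
below).

## Tailored MM′ generation

Geometry minimization is quasi-Newton (L-BFGS-B on the analytic gradient)
polished, when a very tight tolerance is requested, by damped Newton steps
on a finite-difference Hessian; default gradient tolerance
10⁻⁶ kcal/mol/Å, deterministic, and hitting the iteration cap returns an
unconverged report rather than raising. Tailoring refuses anything but a
converged `MinimizationReport` — a bare coordinate set carries no evidence
of convergence.

The MM′ model assigns every atom a fresh unique type, sets each bond's b0
and angle's θ0 to the value measured in the target-minimized geometry, and
copies charges, LJ parameters, polarizabilities and force constants from
the base unchanged. Copying force constants is the procedure's main
limitation: a target whose *anharmonicity* (not just equilibrium
geometry) differs from the base is not fully absorbed — which is exactly
what keeps the MM′→TARGET reweighting non-trivial in the validation
benchmark. Dihedral and Urey-Bradley terms do not exist in the toy model
family, so tailoring covers bonds and angles exactly.

## Validation benchmarks and their study conditions

`bookend.validation` drives both the acceptance tests and
`scripts/acceptance.py`. Sizes were fixed once as the desk protocol:
10⁴ samples/window for the replica-exchange BAR recovery (4 repeats),
10⁵ samples for estimator-vs-quadrature equivalence (8 repeats), 10⁴
sweeps for the exchange acceptance rate, 2 × 10⁴ samples/side for cycle
closure (4 repeats), and 10 repeats × 2000 frames for the tailoring
contrast.

Two statistical conventions deserve a note. First, for the
quadrature-equivalence check the quoted standard error is that of a
*single* n = 10⁵ estimate (estimated as the SD across repeats): at that
sample size the standard error of the *mean* over many repeats shrinks to
the scale of BAR's own O(1/n) finite-sample bias, and a 3·SE-of-the-mean
window would test the bias, not the implementation. Second, cycle closure
uses the quadrature-combined per-leg Bennett asymptotic errors rather
than a 4-repeat SD of the loop sum, which has only three degrees of
freedom and randomly under- or overshoots.

The tailoring benchmark deserves its own paragraph. The target keeps the
canonical +0.36 Å equilibrium bond-length shift (the magnitude of a known
force-field-vs-semi-empirical discrepancy), but the benchmark triatomic
uses deliberately **soft bonds** (k_b = 4 kcal/mol/Å², b0 = 1.5 Å,
k_θ = 10): with production-stiff bonds a 0.36 Å shift costs ~100 kT and
the direct one-sided route can never converge at any feasible sample
size, making a route-agreement check meaningless. The soft bonds put the
direct route in the poor-but-estimable regime the tailoring procedure
targets (effective sample size of order 10² at n = 2000). The target's
bonds are additionally Morse wells (D = 20 kcal/mol) — anharmonicity that
tailoring, which copies harmonic force constants, cannot absorb; without
it MM′ would coincide with TARGET exactly and the comparison would be
degenerate. Both choices follow from this overlap analysis, not from the
test thresholds.

## What the toys do and do not show

The synthetic systems exercise the estimators, the replica-exchange
bookkeeping, the alchemical scaling, the Drude SCF and the tailoring
transformation against exact references. They do not emulate real water
structure, long-range (Ewald) electrostatics, Thole screening, charge
transfer, constraint dynamics, NPT ensembles, or production-scale trajectory
lengths; passing tests therefore certify the machinery, not the absolute
hydration numbers of any real force field. The printed-table fixtures are
inputs re-entered verbatim (including ± SDs, with the typographic minus
normalized on read); recomputing their RMSD/MSD/R² rows validates the
metrics implementation, and the recomputed values are the arbiter where
the source's running text and its tables disagree (e.g. a Drude RMSD
quoted as 0.55 in prose vs 0.53 printed — the column recomputes to 0.53).

## Known limitations

* Minimum-image electrostatics only; no PME.
* Tailoring adjusts equilibrium bonded values only — no charge or LJ
  refitting against the target (raised as future work by the source).
* The Langevin sampler is approximate (finite timestep) and untested
  statistically; MC is the reference sampler.
* MBAR across more than two states, autocorrelation-time estimation and
  thermodynamic integration are out of scope.
* `scale_fit` implements the simplest least-squares multiplicative
  correction s = Σ(ref·pred)/Σ(pred²); its output says so.
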