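# Methods

This note documents the models, numerical choices and limitations behind
`hybridsolv`. It is the design record of the package; every number quoted
here is either a model parameter or a quantity the test suite and
`scripts/acceptance.py` recompute at run time.

## The hybrid AA/CG model

The package implements a two-resolution description of a solvated small
molecule. The solute is all-atom: Lennard-Jones sites with fixed point
charges (parameters are *consumed* from a parameter file; atom typing and
parameter generation are out of scope). The solvent is coarse-grained in the
Elba style:

* **Water** is a Stockmayer particle — one Lennard-Jones bead with an
  embedded point dipole. The bead carries a rotational degree of freedom (a
  linear rotor: orientation unit vector plus an angular velocity kept
  perpendicular to it).
* **Cyclohexane** is three bonded, uncharged Lennard-Jones beads placed (when
  coarse-graining an all-atom ring) on ring carbons 1, 3 and 5, and joined
  into a triangle by three harmonic bonds. A ring of three bonds was chosen
  over a two-bond chain because the three mapped carbons are geometrically
  equivalent and the source model describes the sites simply as "connected";
  with equal bond parameters the triangle preserves that symmetry. No angle
  term is used — with three equal bonds on three sites the bond network alone
  fixes the shape.

### Interactions

All truncated non-bonded terms use the shifted-force construction
`U_sf(r) = U(r) − U(r_c) − (r − r_c) U′(r_c)`, applied to each radial kernel
of the multipole expansion (1/r for charge–charge, 1/r² for charge–dipole,
1/r³ for dipole–dipole, and the LJ 6/12 terms). Energy and force therefore go
*continuously to zero* at the cutoff — the property the test suite asserts
exactly. The published description of the CG pair potentials does not state
whether the LJ part is shifted-force or plain-cutoff; we apply the
shifted-force form uniformly because it is required for the good energy
conservation the multiple-timestep integrator assumes.

Atom–atom electrostatics are shifted-force Coulomb with the same cutoff. A
reciprocal-space mesh sum is deliberately not implemented: the package
targets neutral solutes in desk-scale boxes, where the shifted-force form is
the standard well-behaved truncation. This is a documented deviation from
setups that use mesh Ewald for the atomistic subsystem.

Cross LJ parameters follow Lorentz–Berthelot combination (arithmetic sigma,
geometric epsilon), the convention of the atomistic force fields whose
parameters the package consumes.

Intramolecular non-bonded pairs are excluded entirely; bonded terms use the
convention `E = k (r − r0)²` (no ½), matching the simulator convention the CG
solvent parameters were published in (cyclohexane: r0 = 4.05 Å,
k = 12.69 kJ/mol/Å²; beads: sigma = 4.1 Å, epsilon = 3.19 kJ/mol, i.e. the
lipid-tail bead scaled by 0.9).

### Water bead parameters

The Elba water parameters are ordinary configuration entries
(`data/params_water.yaml`), defaulted from the published Elba water model:
sigma = 3.05 Å, epsilon = 0.55 kcal/mol = 2.3012 kJ/mol, dipole = 2.6 D.
The rotational inertia of the bead is a model parameter with no direct
physical counterpart; the default (4.0 g/mol Å²) was chosen so that
orientational motion is integrated smoothly at the 6 fs outer timestep.
Equilibrium averages are independent of this choice; only orientational
kinetics depend on it.

### Units

Å, fs, g/mol, kJ/mol, K, atm, elementary charge; Coulomb prefactor
1389.35458 kJ Å/(mol e²). One conversion layer (`units.py`) holds every
constant; kernels never convert.

## Dynamics

The integrator is an impulse (r-RESPA-style) multiple-timestep scheme:
CG–CG non-bonded forces are the *outer* (slow) class, applied as impulses
every `dt_inner × mts_ratio` (defaults 2 fs × 3 = 6 fs); all other forces —
solute–solvent, solute internal, bonded — advance on the inner 2 fs step.
The inner step is a BAOAB-splitting Langevin step; with friction zero the
scheme reduces exactly to impulse-MTS velocity Verlet (and with
`mts_ratio = 1` to plain velocity Verlet — both asserted bit-level in the
tests). The thermostat acts on the inner step; whether the original
implementation thermostats inner or outer steps is not documented, and the
inner placement is the standard stable choice for BAOAB-RESPA.

* **Thermostats.** Solute and solvent couple to two independent Langevin
  thermostats (separate counter-based noise streams) with friction
  γ = 1/τ, τ = 6 ps. Rotational degrees of freedom are thermostatted with
  the same γ; the orientational noise is drawn in 3D and projected onto the
  plane perpendicular to the dipole (2 degrees of freedom per bead).
* **Rotations.** Orientations are propagated by exact Rodrigues rotation
  about the angular velocity, so unit norm is preserved by construction and
  free rotation conserves rotational kinetic energy exactly (a rigid-rotor
  period test asserts this). For a *linear* rotor a constant torque produces
  uniformly accelerated in-plane rotation, not precession, so the free-rotor
  period is the closed-form oracle used.
* **Constraints.** SHAKE iterates corrections along the pre-step bond
  vectors to |d² − d0²| < 1e−8 Å²; a RATTLE-style velocity projection keeps
  velocities on the constraint manifold after stochastic kicks.
* **Barostat.** Weak coupling with μ = [1 − (dt/τ_p) κ (P₀ − P)]^{1/3},
  τ_p = 6 ps, κ = 4.5e−5 atm⁻¹ (water-like, configurable). Molecule
  *centres* are scaled, never intramolecular geometry. The instantaneous
  pressure comes from the pairwise virial; the (small) constraint
  contribution to the virial is neglected, which is irrelevant for the toy
  solutes carrying at most one constraint.
* **Randomness.** One counter-based generator (Philox) per run, with
  substreams spawned per purpose (initial velocities, solvent thermostat,
  solute thermostat, rotational thermostat), so independent repeats differ
  only by seed and checkpoint restart is bit-exact.

Energy bookkeeping: kinetic temperature uses 3N − n_constraints
translational and 2 per dipolar bead rotational degrees of freedom.

## Solvation free energies

Thermodynamic integration with the quartic coupling f(λ) = (1 − λ)⁴ applied
to the *total* solute–solvent non-bonded energy (LJ and electrostatics
together, no split legs, no soft core — the quartic power is the
endpoint-smoothing device; the fully decoupled endpoint is never simulated).
Solute intramolecular terms are never scaled: the decoupled solute must
behave as a gas-phase molecule, so its internal energy stays on.

The default schedule is 25 equally spaced λ from 0 to 0.96 (spacing 0.04),
visited step-wise in one continuous trajectory; the head of each window is
discarded as equilibration and ∂U/∂λ = f′(λ)·U_sv is sampled on the rest.
The integrand at λ = 1 is linearly extrapolated from the last two grid
points (0.92, 0.96) and the composite trapezium rule is applied over [0, 1].
Repeats differ only by seed and combine as mean ± sd/√n.

Two protocol presets exist. The production-scale preset (4.8 ns windows,
1.2 ns discard, 0.6 ps sampling; 10 repeats in water, 5 in cyclohexane) is
cluster work. The desk-scale preset
(`LambdaSchedule.desk_scale()`: 10 ps windows, 2.5 ps discard, 0.12 ps
sampling, 125-bead boxes with a 7.5 Å cutoff) keeps every algorithmic
ingredient — window sequence, discards, extrapolation, repeats — at sizes a
single CPU handles in about a minute; this is the preset the tests and the
acceptance script run. Note that desk-scale boxes are too small for the
production 12 Å cutoff (minimum image requires box ≥ 2 r_cut), so the toy
presets shorten the cutoff rather than enlarging the box.

The free-energy-perturbation (exponential averaging) estimator exists only
as a validation oracle in the test layer, computed from the same per-window
energy samples with forward/backward averaging; it is never the production
estimator.

## Analysis layer

log D ≈ log P = [ΔG_solv(water) − ΔG_solv(cyclohexane)] / (2.3 R T) with
T = 298 K and the literal factor 2.3 (not ln 10); per-phase standard errors
propagate in quadrature. The packaged 53-compound table
(`data/table1.csv`) stores ΔG pairs, predicted and experimental log D; on
load every record's log D is verified against its ΔG pair within 0.02,
which absorbs the one-decimal rounding of the ΔG columns, the 2.3 vs ln 10
difference and the 298 vs 298.15 K ambiguity.

Quality metrics: MAD, MSD = mean(pred − exp), RMSD, Pearson's R (an explicit
`None` error state on zero variance, never silently 1), and sign accuracy
(an exact zero on one side counts as a mismatch unless both are zero). The
significance-filtered sign accuracy keeps only records whose prediction and
experiment are both significantly non-zero; because determining a *sign* is
a one-sided question the default critical value is the one-sided 95 %
quantile (z = 1.645) applied to value/uncertainty on both sides, with a
two-sided variant switchable.

Group diagnostics rank compounds worst-deviation-first and compute the
Truchon–Bailey BEDROC per chemical group, its uncertainty from 500 bootstrap
resamples of the full record set, the uniform baseline (exact analytic
expectation — under a random permutation E[RIE] = 1 — with a seeded
Monte-Carlo estimator alongside for validation), and a two-sided pooled-
variance t-test of the group's absolute deviations against the entire
population (Welch variant available). The BEDROC alpha defaults to 20, the
conventional early-recognition setting, and is always an explicit, logged
parameter; with alpha near 1 the analytic uniform baseline reproduces the
0.43–0.56 range that group-size-dependent published baselines show, so
reported BEDROC values are only comparable at a stated alpha. Bootstrap
resamples that lose all members (or all non-members) are skipped as
undefined. Group *membership* is input data: the packaged
`groups_stub.csv` carries empty memberships because the per-compound group
assignments were produced by an external perception tool and are not part
of the published record; group tests therefore run on synthetic
memberships.

## What the synthetic fixtures do and do not show

The builders generate everything the tests consume: solvent boxes by random
non-overlapping insertion (minimum pair distance 0.8 sigma, momenta zeroed),
and three toy solutes — a neutral LJ site, a charged LJ site (exercising the
charge–dipole path), and a constrained diatomic with ± partial charges
(exercising SHAKE and both charge–dipole directions). These fixtures probe
every code path at full numerical fidelity, but they are not chemistry: a
passing TI cross-check on an LJ site in 125 CG waters validates the
estimator machinery, not the accuracy of any compound's predicted log D.
The packaged prediction table conversely validates the entire analysis
pipeline against published statistics without any simulation.

## Numerical choices and degenerate inputs

* Tolerances: SHAKE 1e−8 Å² (max 500 iterations, non-convergence names the
  worst constraint); minimiser stops at max |F| < 1 kJ/mol/Å or the step
  limit; forces are validated against central finite differences to 1e−6.
* The steepest-descent minimiser uses an adaptive step (×1.2 on accepted
  steps, ×0.5 on rejected ones) and also rotates dipoles along their
  torques; energy is non-increasing by construction.
* Cell-list evaluation activates when the box admits ≥ 3 cells of size
  ≥ r_cut per dimension and is asserted equal to the all-pairs sweep;
  otherwise the all-pairs path is used (systems this package targets are
  small enough that all-pairs is usually faster anyway).
* Overlapping sites raise an error naming the pair; force blow-ups raise a
  diagnostic naming the simulation time and suggesting a smaller step.
* Ties in BEDROC scores and deviation rankings are broken by first
  occurrence in input order (stable sort), documented and tested.
* Empty systems, zero-length runs and single-repeat estimates (SE = 0) are
  all defined.

## Known limitations

* Orthorhombic periodic boxes only; no triclinic cells, no long-range
  dispersion corrections, no reciprocal-space electrostatics.
* The CG cyclohexane bonded topology (ring vs chain, presence of an angle
  term) is not documented in the source description; the symmetric
  three-bond ring adopted here is one defensible reading.
* Kinetic temperatures carry the usual O(dt²) discretisation bias of
  splitting integrators; at the default timesteps this is a fraction of a
  per cent. Because the mean kinetic temperature of a small toy box is also
  statistically noisy (the SE of a 500 ps / 125-bead average is itself
  ~1 %), thermostat-fidelity checks use a 343-bead box, 1 ns of production
  and the kinetic temperature over *all* thermostatted degrees of freedom,
  giving the estimator a standard error of ~0.25 %.
* The desk-scale presets shorten cutoffs and windows; absolute free
  energies from them are model quantities for validating machinery, not
  converged predictions.
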