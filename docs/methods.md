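# Methods

## The force field

Four flexible, nonpolarizable water parameterizations are built in. The two
parents target bulk water (FBA/ε, three sites; TIP4P/ε_flex, four sites);
the two low-electrostatic descendants (FBA_mem, T4F_mem) keep their
parent's charges, bond/angle force constants and LJ well depth, and differ
only in the equilibrium bend angle θ₀ — opened until the liquid's static
dielectric constant falls to ≈20 at 309.65 K — and in the LJ diameter σ_OO,
retuned to bulk density. Opening the angle works because the molecular
dipole of a rigid-charge water is μ = 2 q_H r₀ cos(θ₀/2): a wider angle
means a smaller dipole, weaker dipolar fluctuations, and a lower ε.

Functional form (GROMACS harmonic conventions, ½k(x−x₀)²):

- bonds: ½k_b(r−r₀)² on each O–H;
- bend: ½k_a(θ−θ₀)² per molecule;
- LJ between oxygens only (no LJ on H or M);
- Coulomb between all charged sites of distinct molecules.

Parameters are stored bit-exactly as published; the registry is immutable
and serializable to a plain INI file so new models need no code changes.

### The M-site

The four-site models place the negative charge on a massless M-site on the
HOH bisector, a distance d_OM from the oxygen. d_OM is not part of the
published parameter table; we inherit 0.0105 nm from the TIP4P/ε family the
flexible parent derives from, and expose it as an ordinary spec field so it
can be overridden. The site is constructed as the GROMACS-style *linear*
three-atom virtual site r_M = r_O + a(r_H1−r_O) + a(r_H2−r_O), with a
chosen so |OM| = d_OM at the equilibrium geometry. For a flexible molecule
|OM| then breathes slightly with the vibrations; in exchange the force
redistribution F_O += (1−2a)F_M, F_H += aF_M is exact — net force, net
torque and virial of every molecule are preserved identically, which the
test suite checks numerically.

## Dynamics

- **Integrator**: half-step-offset leapfrog, dt = 1 fs. No bond
  constraints: these are deliberately flexible models (the bond/angle
  distributions are validation observables), and at 1 fs the stiffest O–H
  mode is integrated with ~11 steps per period. Reported kinetic energies
  and temperatures use the average of the two adjacent half-step kinetic
  energies, which removes the leading O(dt²) half-step bias (~2 K here).
- **Thermostat**: stochastic velocity rescaling (canonical sampling),
  τ_T = 0.1 ps. One scale factor per step, so velocity directions are
  untouched; deterministic under the protocol seed.
- **Barostat**: Berendsen weak coupling, τ_P = 2 ps, isotropic,
  compressibility 4.5×10⁻⁵ bar⁻¹. The box and the molecular centers of
  mass are scaled; internal geometry never is, keeping the stiff bonds out
  of the pressure coupling. The per-step scale factor is clamped to
  [0.98, 1.02] (with a warning) so minimization leftovers cannot explode
  the box. Weak coupling does not generate a rigorous NPT distribution;
  for the mean-value observables computed here that bias is far below the
  statistical noise of desk-scale runs.
- **Degrees of freedom**: 3 × (massive sites) − 3; the total momentum is
  removed every step.
- **Pressure**: virial route, P = (2K + Σ r·F)/(3V), pairwise terms for
  the nonbonded and bond contributions, atom-based (translation-invariant)
  terms for the bend, plus the analytic LJ tail correction.

## Electrostatics: reaction field, not PME

Production-scale studies of these models use particle-mesh Ewald. A
desk-scale engine simulating 125–350 molecules cannot meaningfully use a
mesh Ewald, so Coulomb interactions are damped with a reaction field at
conducting boundary (ε_RF = ∞): V = f q_i q_j (1/r + r²/2r_c³ − 3/2r_c),
whose potential *and* force both vanish at the cutoff. This matches the
conducting-boundary convention assumed by the dipole-fluctuation dielectric
estimator. A naive full Ewald summation (energy route) is included for
boxes of ≤64 molecules purely as a validation cross-check of the Coulomb
arithmetic.

The published protocol uses a 1.2 nm cutoff; the minimum-image convention
requires cutoff ≤ box/2, which a 125-molecule box (edge ≈ 1.56 nm) cannot
honor. Desk-scale presets therefore use 0.65 nm (125 molecules) or 0.8 nm
(216 molecules); the long-range liquid-structure check uses 343 molecules
at 1.05 nm, the largest cutoff that box affords. Consequences we observe
and report rather than hide: densities shift by ~1–2% relative to PME
results, outer g(r) structure beyond ~0.7 nm is progressively distorted at
the shorter cutoffs, and four-site hydrogen-bond counts run a few percent
low (see Limitations).

## Neighbor searching

A Verlet list over *molecule* pairs anchored on oxygen positions
(skin 0.1 nm, rebuild when any oxygen has moved skin/2), with an anchor
radius of cutoff + skin + 0.3 nm covering the maximal site offset from the
oxygen. The force kernel walks molecule pairs, applies an O–O prefilter,
and computes each site pair's own minimum image — necessary near half-box
separations, where the oxygen's image is not always the site pair's
nearest. A generic site-level cell list (with an O(N²) oracle twin) backs
the public `neighbor_pairs` API and the test suite; boxes smaller than
three cells per dimension fall back to the quadratic scan automatically.

## Observables

- **Dielectric constant**: ε = 1 + (⟨|M|²⟩−|⟨M⟩|²)/(3ε₀⟨V⟩k_BT) with M in
  e·nm; the cumulative-estimate series is returned for convergence plots.
  Block averaging (10 blocks) supplies the standard error.
- **g_OO(r)**: shell-normalized histogram of minimum-image O–O distances,
  default 0.002 nm bins; coordination n(r) = 4πρ_O ∫ g s² ds. Extrema are
  located on a 5-bin moving-average copy (the raw curve is always
  reported); maxima below g = 0.2 are ignored as excluded-volume noise.
- **Self-diffusion**: Einstein relation on unwrapped molecular
  centers of mass (the engine propagates unwrapped coordinates, so no
  unwrap pass is needed; wrapped input is detected and refused). D =
  slope/6 by least squares over lags in 10–50% of the maximum lag,
  excluding the ballistic regime.
- **Hydrogen bonds**: geometric criterion — donor–acceptor O–O distance
  ≤ 0.35 nm and hydrogen–donor–acceptor angle ≤ 30°, each (D,H,A) triple
  counted once, intramolecular triples excluded. Occupancy per directed
  molecule pair is the percentage of frames bonded; per-group occupancies
  sum over the group's pairs and may exceed 100%.
- **Free-energy landscapes**: ΔG(bin) = −k_BT ln(P/P_max) on a 2-D
  histogram; the modal bin is exactly 0 and empty bins are NaN
  (unreachable), never 0.
- **Burn-in and errors**: property means discard the equilibration segment
  (50% of short runs by default) and report 10-block standard errors.

## Calibration

The two-stage fit is a stochastic bisection because every objective
evaluation is a noisy NPT simulation: stage 1 varies θ₀ against an ε
target, stage 2 varies σ_OO against a density target (ε_OO held fixed, as
in the published retuning, which changed σ only). The bracket is maintained
on the sign of (estimate − target) and an evaluation is accepted when
|estimate − target| ≤ tolerance + pooled standard error — the stderr
inflation prevents oscillating non-convergence on noisy objectives.
Desk-scale defaults (125 molecules, 100 ps, 3 replicates) demonstrate the
machinery; a converged dielectric fit genuinely needs 500-molecule boxes
and tens of nanoseconds (the `full_fidelity` preset), since the ε estimator
converges on the 10-ns scale.

## Synthetic fixtures

Every analysis path is regression-tested against generators with known
parameters: Gaussian dipole streams (closed-form ε), 3-D Brownian walks
(known D), two-state reaction-coordinate series (known ΔG gap), hand-built
hydrogen-bond clusters (known bond count, built with >99° angular
separations so no spurious bond can form), dimer scans (LJ zero and minimum
at σ and 2^{1/6}σ), and jittered-lattice boxes. These fixtures emulate the
*statistics* the estimators consume, not water physics: passing them shows
the estimators are correct, not that the force field is.

## Problem sizes and seeds

Desk-scale validation runs use 125-molecule boxes (216–343 where outer
liquid structure is the point), 20 ps NPT equilibration and 50–180 ps
production at the state points of interest (298.15–309.65 K, 1 bar). All
stochastic elements (lattice jitter, orientations, initial velocities,
thermostat noise) flow from a single seed through spawned generator
streams; rerunning with the same seed reproduces trajectories bit-exactly.

## Known limitations

- Reaction-field + short cutoffs shift absolute densities by ~1–2%,
  distort g(r) near and beyond the cutoff (at 0.8 nm the third-shell peak
  appears ~0.4–0.6 Å outward of its large-box position), and weaken
  four-site hydrogen bonding by ~5% relative to published mesh-Ewald
  counts. Three-site H-bond counts and all intramolecular geometry agree
  with the published values to ≤1%.
- Desk-scale dielectric estimates are single-decade indicators: they
  separate ε ≈ 20 from ε ≈ 78 cleanly but carry tens-of-percent
  uncertainty at 200 ps.
- No finite-size corrections are applied to D or ε.
- Berendsen pressure coupling and velocity-rescaling temperature coupling
  are weak-coupling choices favoring robustness at small N over exact
  ensemble character.
- Water only: no ions, peptides or lipids, no semi-isotropic coupling, no
  constraint solver.
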