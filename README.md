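# lewmd — low-electrostatic flexible water models with a desk-scale MD engine

Within roughly two nanometers of a lipid membrane, water no longer screens
charges like bulk water: the effective static dielectric constant drops from
~78 to ~20. `lewmd` implements two flexible, nonpolarizable water models
parameterized for that regime — **FBA_mem** (three-site) and **T4F_mem**
(four-site, massless charged M-site on the HOH bisector) — together with
their bulk-water parents (**FBA/ε** and **TIP4P/ε_flex**), as a fully
executable force field:

- a molecular-dynamics engine (energy minimization, NVE/NVT/NPT; leapfrog
  integrator, stochastic velocity-rescaling thermostat, weak-coupling
  barostat, reaction-field electrostatics, virtual-site force
  redistribution);
- the pure-water validation observables: static dielectric constant from
  total-dipole fluctuations, density, oxygen–oxygen radial distribution
  function g_OO(r) with coordination number, Einstein-relation
  self-diffusion, geometric hydrogen-bond analysis and occupancies, and
  free-energy landscapes ΔG = −k_BT ln(P/P_max);
- the two-stage target-property calibration that produces the models
  (bend angle → dielectric constant target, then LJ diameter → density
  target);
- GROMACS-format interchange (ITP/TOP topologies, GRO coordinates,
  XVG-style tables).

## The models

All four models share the OPLS-style functional form

```
V = Σ ½k_b (r_OH − r₀)² + Σ ½k_a (θ_HOH − θ₀)²
  + Σ 4ε_OO[(σ_OO/r)¹² − (σ_OO/r)⁶]        (O–O pairs)
  + Σ f q_i q_j (1/r + k_rf r² − c_rf)      (reaction field, r < r_c)
```

The low-electrostatic descendants keep their parent's charges and bonded
constants and differ only in θ₀ (opened until ε ≈ 20 at 309.65 K, which
lowers the molecular dipole μ = 2 q_H r₀ cos(θ₀/2)) and σ_OO (retuned to
bulk density). The dielectric constant is estimated from equilibrium
fluctuations of the box dipole **M** under the conducting-boundary
convention:

```
ε = 1 + (⟨|M|²⟩ − |⟨M⟩|²) / (3 ε₀ ⟨V⟩ k_B T)
```

## Worked example

```python
from lewmd import get_model, build_box, SimulationProtocol, minimize, run
from lewmd.observables import dielectric_constant, hbond_count, geometry_distributions

spec = get_model("FBA_mem")                     # θ0 = 132.5°, σ_OO = 0.31616 nm
box = build_box(spec, 125, target_density=0.99, seed=11)
proto = SimulationProtocol(ensemble="NPT", T_ref=309.65, cutoff=0.65,
                           seed=11, n_steps=70_000, save_every=100)
box = minimize(box, proto, max_steps=300, f_tol=500.0)
traj = run(box, proto)                          # ~1 min on one CPU

bond, angle, _, _ = geometry_distributions(traj, burn_in=0.3)
_, per_mol = hbond_count(traj, burn_in=0.3)
eps = dielectric_constant(traj.dipole_array(), traj.volume_array(),
                          309.65, burn_in=0.3)
print(f"O-H {bond.mean:.5f} nm  angle {angle.mean:.2f} deg  "
      f"HB/molecule {per_mol.mean:.3f}  eps {eps.mean:.1f}")
```

Output from this exact run:

```
O-H 0.10554 nm  angle 128.66 deg  HB/molecule 1.794  eps 21.2
```

Read: in the liquid the O–H bond stretches past its 0.1027 nm equilibrium
and the bend closes from 132.5° to ~128.7°; each molecule participates in
~1.79 donor-counted hydrogen bonds (~897 per 500 molecules); and the
70 ps dielectric estimate already sits at the low-dielectric design point
(ε ≈ 20) rather than bulk water's ~78.

The same pipeline is scriptable from the shell:

```bash
lewmd simulate --preset fba_mem_pure_309K --outdir out/
lewmd export-topology T4F_mem --outdir topologies/
lewmd calibrate --model FBA/eps --stage angle_vs_epsilon --target 20
```

## Scope

Pure-water systems only: no ions, no peptides, no lipid membranes, no PME,
no constraint solver — see `docs/methods.md` for the model's assumptions,
the numerical choices, and known limitations of the desk-scale protocol.
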