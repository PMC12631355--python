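"""Dynamics: leapfrog integration, V-rescale thermostat, Berendsen barostat,
steepest-descent minimization and the run orchestrator.

The integrator is the half-step-offset leapfrog: velocities live at
t - dt/2, get kicked by the force at t, and carry the positions to t + dt.
Massless M-sites are re-placed geometrically after every position update.
Temperature control is stochastic velocity rescaling (canonical sampling),
pressure control weak isotropic coupling acting on the box and on molecular
centers of mass (internal geometry is never scaled, which keeps the stiff
bonds out of the barostat).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .forces import BlowUpError, EnergyReport, compute_forces, kinetic_energy, n_dof
from .neighbors import WaterPairList
from .system import (Configuration, SimulationProtocol,
                     maxwell_boltzmann_velocities, place_msites)

__all__ = ["Trajectory", "minimize", "step_leapfrog", "thermostat_vrescale",
           "barostat_berendsen", "run"]


@dataclass
class Trajectory:
    """Time-ordered frames with per-frame box, total dipole and energies."""

    spec: object
    times: list = field(default_factory=list)  # ps
    positions: list = field(default_factory=list)  # (n_sites, 3) nm per frame
    boxes: list = field(default_factory=list)  # (3,) nm per frame
    dipoles: list = field(default_factory=list)  # (3,) e nm per frame
    energies: list = field(default_factory=list)  # EnergyReport per frame
    com: list = field(default_factory=list)  # (n_mol, 3) nm, unwrapped
    final_config: Configuration | None = None

    def append(self, t: float, config: Configuration, report: EnergyReport) -> None:
        if self.times and t <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        self.times.append(t)
        self.positions.append(config.positions.copy())
        self.boxes.append(config.box.copy())
        self.dipoles.append(config.total_dipole())
        self.energies.append(report)
        self.com.append(config.molecule_com())

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def dipole_array(self) -> np.ndarray:
        return np.array(self.dipoles)

    def volume_array(self) -> np.ndarray:
        return np.prod(np.array(self.boxes), axis=1)

    def com_array(self) -> np.ndarray:
        """(n_frames, n_mol, 3) unwrapped molecular centers of mass."""
        return np.array(self.com)

    def energy_frame(self, name: str) -> np.ndarray:
        return np.array([getattr(e, name) for e in self.energies])


def minimize(config: Configuration, protocol: SimulationProtocol,
             max_steps: int = 1000, f_tol: float = 100.0) -> Configuration:
    """Steepest descent with adaptive step; stops at max|F| <= f_tol (kJ/mol/nm).

    Accepted moves never increase the potential energy; step size grows by
    1.2 on acceptance and shrinks by 0.2 on rejection (the classic scheme).
    """
    config = config.copy()
    place_msites(config)
    pairs = WaterPairList(config, protocol.cutoff, protocol.skin)
    forces, report = compute_forces(config, protocol, pairs)
    energy = report.potential
    h = 0.01  # nm
    massive = config.masses > 0
    for _ in range(max_steps):
        fmax = float(np.abs(forces[massive]).max())
        if fmax <= f_tol:
            break
        trial = config.copy()
        trial.positions[massive] += h * forces[massive] / fmax
        place_msites(trial)
        pairs.maybe_rebuild(trial)
        try:
            f_trial, rep_trial = compute_forces(trial, protocol, pairs)
            e_trial = rep_trial.potential
        except FloatingPointError:
            e_trial = np.inf
        if not np.isfinite(e_trial):
            raise BlowUpError("minimization diverged (non-finite energy)",
                              last_config=config)
        if e_trial <= energy:
            config, forces, energy = trial, f_trial, e_trial
            h = min(h * 1.2, 0.05)
        else:
            h *= 0.2
            if h < 1e-8:
                break
            pairs.maybe_rebuild(config)
    return config


def step_leapfrog(config: Configuration, forces: np.ndarray,
                  dt: float, in_place: bool = False,
                  step: int | None = None) -> Configuration:
    """One leapfrog update: v(t+dt/2) = v(t-dt/2) + dt F(t)/m, x(t+dt) = x(t) + dt v.

    Massless sites are re-placed geometrically afterwards.  A displacement
    beyond half the box in one step raises :class:`BlowUpError`.
    """
    out = config if in_place else config.copy()
    m = out.masses
    massive = m > 0
    out.velocities[massive] += dt * forces[massive] / m[massive, None]
    dx = dt * out.velocities[massive]
    if np.abs(dx).max(initial=0.0) > 0.5 * float(out.box.min()):
        raise BlowUpError("single-step displacement exceeds half the box",
                          step=step, last_config=config)
    out.positions[massive] += dx
    place_msites(out)
    return out


def thermostat_vrescale(velocities: np.ndarray, masses: np.ndarray,
                        T_ref: float, tau_T: float, dt: float,
                        rng: np.random.Generator,
                        ndof: int | None = None) -> np.ndarray:
    """Stochastic velocity rescaling (canonical sampling through rescaling).

    All velocities are multiplied by a single scale factor per call, so
    directions are preserved.  In the tau_T -> infinity limit the scale
    tends to 1; deterministic under a fixed generator state.
    """
    if tau_T <= 0:
        raise ValueError("tau_T must be positive")
    massive = masses > 0
    if ndof is None:
        ndof = 3 * int(massive.sum()) - 3
    ke = 0.5 * float((masses[massive] * (velocities[massive] ** 2).sum(axis=1)).sum())
    if ke <= 0.0:
        # degenerate start: reseed from Maxwell-Boltzmann
        out = velocities.copy()
        sigma = np.sqrt(KB * T_ref / masses[massive])
        out[massive] = rng.normal(size=(int(massive.sum()), 3)) * sigma[:, None]
        return out
    ke_target = 0.5 * ndof * KB * T_ref
    c = math.exp(-dt / tau_T)
    r1 = rng.normal()
    s = rng.chisquare(ndof - 1) if ndof > 1 else 0.0
    alpha2 = (c
              + (1.0 - c) * (r1 * r1 + s) * ke_target / (ndof * ke)
              + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ke_target / (ndof * ke)))
    out = velocities.copy()
    out[massive] *= math.sqrt(max(alpha2, 0.0))
    return out


def barostat_berendsen(config: Configuration, pressure: float, P_ref: float,
                       tau_P: float, compressibility: float, dt: float,
                       in_place: bool = False) -> Configuration:
    """Weak-coupling isotropic box scaling toward P_ref.

    mu = [1 - (dt/tau_P) kappa (P_ref - P)]^(1/3); molecular centers of mass
    scale with the box while internal geometry is untouched.  The scale is
    clamped to [0.98, 1.02] per step (with a warning) to survive transients.
    """
    if tau_P <= 0:
        raise ValueError("tau_P must be positive")
    mu3 = 1.0 - (dt / tau_P) * compressibility * (P_ref - pressure)
    mu = mu3 ** (1.0 / 3.0)
    if not 0.98 <= mu <= 1.02:
        warnings.warn(f"barostat scale {mu:.4f} clamped to [0.98, 1.02]",
                      RuntimeWarning, stacklevel=2)
        mu = min(max(mu, 0.98), 1.02)
    out = config if in_place else config.copy()
    if mu != 1.0:
        com = out.molecule_com()
        shift = (mu - 1.0) * com
        out.positions += np.repeat(shift, out.spec.n_sites, axis=0)
        out.box *= mu
    return out


def _remove_com_motion(config: Configuration) -> None:
    m = config.masses
    massive = m > 0
    p = (m[massive, None] * config.velocities[massive]).sum(axis=0)
    config.velocities[massive] -= p / m[massive].sum()


def run(config: Configuration, protocol: SimulationProtocol,
        observers: tuple = ()) -> Trajectory:
    """Run MD per the protocol and return a :class:`Trajectory`.

    Frames (positions, box, total dipole, energy report) are recorded at
    step 0, every ``save_every`` steps, and at the final step.  Fully
    reproducible for a fixed protocol seed.  ``observers`` are callables
    ``(step, config, report)`` invoked at every recorded frame.
    """
    config = config.copy()
    place_msites(config)
    ss = np.random.SeedSequence([int(protocol.seed) % (2 ** 31), 0x7E57])
    rng_thermo, rng_vel = [np.random.Generator(np.random.PCG64(s))
                           for s in ss.spawn(2)]
    if protocol.ensemble in ("NVT", "NPT") and not config.velocities.any():
        maxwell_boltzmann_velocities(config, protocol.T_ref, rng_vel)
        place_msites(config)
    pairs = WaterPairList(config, protocol.cutoff, protocol.skin)
    traj = Trajectory(spec=config.spec)
    dof = n_dof(config)
    dt = protocol.dt

    def record(step: int) -> None:
        _, report = compute_forces(config, protocol, pairs)
        traj.append(step * dt, config, report)
        for obs in observers:
            obs(step, config, report)

    for step in range(protocol.n_steps):
        pairs.maybe_rebuild(config)
        forces, report = compute_forces(config, protocol, pairs)
        recorded = step % protocol.save_every == 0
        snapshot = config.copy() if recorded else None
        ke_before = report.kinetic
        try:
            step_leapfrog(config, forces, dt, in_place=True, step=step)
        except BlowUpError as err:
            err.step = step
            raise
        if recorded:
            # leapfrog kinetic energy at time t: average of the two
            # adjacent half-step values (removes the half-step bias)
            ke_t = 0.5 * (ke_before + kinetic_energy(config))
            report.kinetic = ke_t
            report.temperature = 2.0 * ke_t / (dof * KB)
            traj.append(step * dt, snapshot, report)
            for obs in observers:
                obs(step, snapshot, report)
        if protocol.ensemble in ("NVT", "NPT"):
            config.velocities = thermostat_vrescale(
                config.velocities, config.masses, protocol.T_ref,
                protocol.tau_T, dt, rng_thermo, ndof=dof)
        if protocol.ensemble == "NPT":
            barostat_berendsen(config, report.pressure, protocol.P_ref,
                               protocol.tau_P, protocol.compressibility, dt,
                               in_place=True)
        _remove_com_motion(config)
    pairs.maybe_rebuild(config)
    record(protocol.n_steps)
    traj.final_config = config
    return traj
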