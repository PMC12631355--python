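"""Integrator, thermostat, barostat and run-loop contracts."""

import math

import numpy as np
import pytest

from lewmd import SimulationProtocol, build_box, get_model, minimize, run
from lewmd.constants import KB
from lewmd.engine import (barostat_berendsen, step_leapfrog,
                          thermostat_vrescale)
from lewmd.forces import compute_forces
from lewmd.models import ideal_geometry
from lewmd.system import Configuration, place_msites


def _isolated_molecule(model="FBA_mem", box=4.0):
    spec = get_model(model)
    geo = ideal_geometry(spec).site_positions + box / 2
    cfg = Configuration(geo, np.zeros_like(geo), np.full(3, box), spec)
    place_msites(cfg)
    return cfg


class TestLeapfrog:
    def test_zero_forces_zero_velocities_static(self):
        cfg = _isolated_molecule()
        out = step_leapfrog(cfg, np.zeros_like(cfg.positions), 1e-3)
        assert np.allclose(out.positions, cfg.positions)

    def test_constant_force_matches_discrete_recursion(self):
        """Single free particle under constant force follows the exact
        discrete leapfrog trajectory."""
        spec = get_model("FBA_mem")
        # use one molecule but push only via a constant external force on O
        cfg = _isolated_molecule()
        f0 = 50.0  # kJ/mol/nm on O along x
        dt = 1e-3
        m = spec.site_masses[0]
        forces = np.zeros_like(cfg.positions)
        forces[0, 0] = f0
        x = cfg.positions[0, 0]
        v = 0.0
        sim = cfg.copy()
        for _ in range(100):
            sim = step_leapfrog(sim, forces, dt)
            v += dt * f0 / m
            x += dt * v
        assert sim.positions[0, 0] == pytest.approx(x, rel=1e-12)

    def test_blowup_detected(self):
        cfg = _isolated_molecule()
        cfg.velocities[:] = 1e5
        from lewmd.forces import BlowUpError
        with pytest.raises(BlowUpError):
            step_leapfrog(cfg, np.zeros_like(cfg.positions), 1e-1)


def test_nve_energy_drift_bounded():
    """Water dimer, 1 fs leapfrog, 10 ps NVE: drift <= 0.01 kJ/mol per molecule
    per ps (linear fit removes the bounded leapfrog oscillation)."""
    spec = get_model("FBA_mem")
    geo = ideal_geometry(spec).site_positions
    pos = np.concatenate([geo + 2.0, geo @ np.diag([1, 1, -1.0]) + [2.3, 2.0, 2.0]])
    cfg = Configuration(pos, np.zeros_like(pos), np.full(3, 5.0), spec)
    proto = SimulationProtocol(ensemble="NVE", cutoff=1.2, n_steps=10000,
                               save_every=50, tail_correction=False)
    cfg = minimize(cfg, proto, max_steps=200, f_tol=50.0)
    rng = np.random.default_rng(5)
    cfg.velocities = rng.normal(scale=0.3, size=cfg.velocities.shape)
    traj = run(cfg, proto)
    e = np.array([rep.total for rep in traj.energies])
    t = np.array(traj.times)
    slope = np.polyfit(t, e, 1)[0]  # kJ/mol per ps
    assert abs(slope) / 2 <= 0.01  # per molecule


def test_nvt_mean_temperature_matches_setpoint():
    """125 FBA_mem molecules at 309.65 K: mean instantaneous T within 3 SE."""
    cfg = build_box(get_model("FBA_mem"), 125, 0.99, seed=21)
    proto = SimulationProtocol(ensemble="NVT", T_ref=309.65, cutoff=0.65,
                               seed=21, n_steps=12000, save_every=20)
    cfg = minimize(cfg, proto, max_steps=200, f_tol=1000.0)
    traj = run(cfg, proto)
    temps = traj.energy_frame("temperature")[len(traj.times) // 2:]
    n_blocks = 10
    blocks = np.array_split(temps, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = means.std(ddof=1) / math.sqrt(n_blocks)
    assert abs(temps.mean() - 309.65) <= 3 * max(se, 1.0)


class TestThermostat:
    def test_infinite_tau_leaves_velocities(self, rng):
        v = rng.normal(size=(30, 3))
        m = np.ones(30)
        out = thermostat_vrescale(v, m, 300.0, 1e12, 1e-3, rng)
        assert np.allclose(out, v, rtol=1e-4)

    def test_directions_preserved(self, rng):
        v = rng.normal(size=(30, 3))
        m = np.ones(30)
        out = thermostat_vrescale(v, m, 300.0, 0.1, 1e-3, rng)
        ratio = out / v
        assert np.allclose(ratio, ratio.flat[0])

    def test_deterministic_under_seed(self):
        v = np.random.default_rng(0).normal(size=(30, 3))
        m = np.ones(30)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            outs.append(thermostat_vrescale(v, m, 300.0, 0.1, 1e-3, rng))
        assert np.array_equal(outs[0], outs[1])

    def test_zero_kinetic_reseeds(self):
        v = np.zeros((30, 3))
        m = np.ones(30)
        out = thermostat_vrescale(v, m, 300.0, 0.1, 1e-3,
                                  np.random.default_rng(0))
        ke = 0.5 * (m * (out ** 2).sum(axis=1)).sum()
        assert ke > 0


class TestBarostat:
    def test_at_reference_pressure_unchanged(self):
        cfg = build_box(get_model("FBA_mem"), 27, 0.994, seed=1)
        out = barostat_berendsen(cfg, pressure=1.0, P_ref=1.0, tau_P=2.0,
                                 compressibility=4.5e-5, dt=1e-3)
        assert np.array_equal(out.box, cfg.box)
        assert np.array_equal(out.positions, cfg.positions)

    def test_overpressure_grows_box(self):
        cfg = build_box(get_model("FBA_mem"), 27, 0.994, seed=1)
        out = barostat_berendsen(cfg, pressure=5000.0, P_ref=1.0, tau_P=2.0,
                                 compressibility=4.5e-5, dt=1e-3)
        assert np.all(out.box > cfg.box)

    def test_internal_geometry_not_scaled(self):
        cfg = build_box(get_model("FBA_mem"), 27, 0.994, seed=1)
        out = barostat_berendsen(cfg, pressure=-8000.0, P_ref=1.0, tau_P=2.0,
                                 compressibility=4.5e-5, dt=1e-3)
        r0 = np.linalg.norm(cfg.positions[1] - cfg.positions[0])
        r1 = np.linalg.norm(out.positions[1] - out.positions[0])
        assert r1 == pytest.approx(r0, rel=1e-12)

    def test_extreme_pressure_clamped_with_warning(self):
        cfg = build_box(get_model("FBA_mem"), 27, 0.994, seed=1)
        with pytest.warns(RuntimeWarning, match="clamped"):
            barostat_berendsen(cfg, pressure=1e9, P_ref=1.0, tau_P=1e-3,
                               compressibility=4.5e-5, dt=1e-3)


class TestMinimize:
    def test_already_minimal_unchanged(self):
        cfg = _isolated_molecule()
        proto = SimulationProtocol(cutoff=1.0, n_steps=0)
        out = minimize(cfg, proto, max_steps=50, f_tol=1.0)
        assert np.allclose(out.positions, cfg.positions, atol=1e-6)

    def test_stretched_bond_relaxes_to_r0(self):
        spec = get_model("FBA_mem")
        cfg = _isolated_molecule()
        u = cfg.positions[1] - cfg.positions[0]
        cfg.positions[1] += 0.02 * u / np.linalg.norm(u)
        proto = SimulationProtocol(cutoff=1.0, n_steps=0)
        out = minimize(cfg, proto, max_steps=2000, f_tol=0.01)
        r = np.linalg.norm(out.positions[1] - out.positions[0])
        assert r == pytest.approx(spec.r_OH0, abs=1e-5)

    def test_overlapping_dimer_energy_decreases(self):
        spec = get_model("FBA_mem")
        geo = ideal_geometry(spec).site_positions
        pos = np.concatenate([geo + 2.0, geo + [2.25, 2.0, 2.0]])
        cfg = Configuration(pos, np.zeros_like(pos), np.full(3, 5.0), spec)
        proto = SimulationProtocol(cutoff=1.2, n_steps=0, tail_correction=False)
        _, rep0 = compute_forces(cfg, proto)
        out = minimize(cfg, proto, max_steps=300, f_tol=10.0)
        _, rep1 = compute_forces(out, proto)
        assert rep1.potential < rep0.potential


class TestRun:
    def test_zero_steps_yields_initial_frame(self):
        cfg = build_box(get_model("FBA_mem"), 27, 0.994, seed=1)
        proto = SimulationProtocol(cutoff=0.36, skin=0.08, n_steps=0)
        traj = run(cfg, proto)
        assert traj.n_frames == 1
        assert traj.times == [0.0]

    def test_reproducible_under_seed(self):
        cfg = build_box(get_model("FBA_mem"), 27, 0.994, seed=9,
                        T_velocities=300.0)
        proto = SimulationProtocol(ensemble="NVT", T_ref=300.0, cutoff=0.36,
                                   skin=0.08, seed=5, n_steps=300, save_every=100)
        t1 = run(cfg, proto)
        t2 = run(cfg, proto)
        assert np.array_equal(t1.positions[-1], t2.positions[-1])
        assert np.array_equal(t1.dipole_array(), t2.dipole_array())

    def test_momentum_stays_zero(self):
        cfg = build_box(get_model("FBA_mem"), 27, 0.994, seed=9)
        proto = SimulationProtocol(ensemble="NVT", T_ref=300.0, cutoff=0.36,
                                   skin=0.08, seed=5, n_steps=500, save_every=500)
        traj = run(cfg, proto)
        final = traj.final_config
        m = final.masses
        p = (m[:, None] * final.velocities).sum(axis=0)
        assert np.abs(p).max() < 1e-9

    def test_msite_velocities_zero_and_placed(self):
        cfg = build_box(get_model("T4F_mem"), 27, 0.994, seed=9)
        proto = SimulationProtocol(ensemble="NVT", T_ref=300.0, cutoff=0.36,
                                   skin=0.08, seed=5, n_steps=200, save_every=200)
        traj = run(cfg, proto)
        final = traj.final_config
        assert np.all(final.velocities[3::4] == 0.0)
        spec = final.spec
        a = spec.vsite_coeff
        pos = final.positions.reshape(-1, 4, 3)
        expected = pos[:, 0] + a * (pos[:, 1] - pos[:, 0]) + a * (pos[:, 2] - pos[:, 0])
        assert np.allclose(pos[:, 3], expected, atol=1e-12)
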