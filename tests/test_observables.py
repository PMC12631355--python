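"""Analysis-operation oracles: closed-form dielectric, RDF normalization,
Brownian diffusion recovery, hydrogen-bond geometry and FEL arithmetic."""

import math

import numpy as np
import pytest

from lewmd import get_model
from lewmd.constants import KB
from lewmd.fixtures import (brownian_walk_trajectory, gaussian_dipoles,
                            hbond_cluster, synthetic_trajectory,
                            two_state_series)
from lewmd.models import ideal_geometry
from lewmd.observables import (HBondCriterion, block_average,
                               coordination_number, detect_hbonds,
                               dielectric_constant, fel_surface,
                               geometry_distributions, hbond_count,
                               hbond_occupancy, rdf_OO, self_diffusion)
from lewmd.system import Configuration
from lewmd.engine import Trajectory
from lewmd.forces import EnergyReport


def _static_traj(config, n_frames=12, dt=1.0):
    traj = Trajectory(spec=config.spec)
    for k in range(n_frames):
        traj.append(k * dt, config, EnergyReport())
    return traj


class TestDielectric:
    def test_constant_dipole_gives_unity(self):
        m = np.tile([0.5, -0.2, 0.1], (200, 1))
        est = dielectric_constant(m, np.full(200, 10.0), 300.0)
        assert est.mean == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("variance", [0.01, 0.1, 1.0, 10.0])
    def test_gaussian_closed_form_across_decades(self, variance):
        m, v, manifest = gaussian_dipoles(n_samples=40000, variance=variance,
                                          seed=3)
        est = dielectric_constant(m, v, manifest["T"])
        expected = manifest["eps_expected"]
        assert est.mean == pytest.approx(expected, rel=0.05)
        # and within ~3 block standard errors of the plug-in value
        assert abs(est.mean - expected) <= 4 * est.stderr + 1e-9

    def test_convergence_series_ends_at_estimate(self):
        m, v, manifest = gaussian_dipoles(n_samples=5000, seed=1)
        est = dielectric_constant(m, v, manifest["T"])
        assert est.series[-1] == pytest.approx(est.mean, rel=1e-9)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            dielectric_constant(np.zeros((5, 3)), np.ones(5), 300.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            dielectric_constant(np.zeros((100, 3)), np.zeros(100), 300.0)


class TestRDF:
    def test_ideal_gas_is_flat(self):
        """Uniform random oxygens: g(r) = 1 within counting noise beyond 0.2 nm."""
        rng = np.random.default_rng(8)
        spec = get_model("FBA_mem")
        box = np.full(3, 3.0)
        traj = Trajectory(spec=spec)
        n_ox = 200
        for k in range(40):
            ox = rng.uniform(0, 3.0, (n_ox, 3))
            pos = np.repeat(ox, 3, axis=0)  # H's coincident with O: irrelevant
            pos = ox[:, None, :] + np.zeros((n_ox, 3, 3))
            traj.append(float(k), Configuration(pos.reshape(-1, 3),
                                                np.zeros((n_ox * 3, 3)), box,
                                                spec), EnergyReport())
        rdf = rdf_OO(traj, dr=0.02)
        sel = rdf.bin_centers > 0.2
        # 3-sigma counting band per bin
        n_pairs = n_ox * (n_ox - 1) / 2 * 40
        shell_frac = 4 * np.pi * rdf.bin_centers[sel] ** 2 * 0.02 / 27.0
        sigma = 1.0 / np.sqrt(n_pairs * shell_frac)
        assert np.all(np.abs(rdf.g[sel] - 1.0) < 4 * sigma)
        assert np.all(np.diff(rdf.coordination) >= -1e-12)

    def test_two_particle_normalization(self):
        """Two oxygens at fixed separation: single occupied bin with the
        analytic height 2V/(N(N-1) * shell volume) ... with N=2: V/shell."""
        spec = get_model("FBA_mem")
        box = np.full(3, 4.0)
        d = 0.7
        dr = 0.01
        pos = np.zeros((6, 3))
        pos[0:3] += 1.0
        pos[3:6] += 1.0
        pos[3:6, 0] += d
        cfg = Configuration(pos, np.zeros((6, 3)), box, spec)
        traj = _static_traj(cfg, n_frames=5)
        rdf = rdf_OO(traj, dr=dr)
        k = np.searchsorted(rdf.bin_centers, d) - 0  # bin containing d
        # locate the occupied bin
        occ = np.nonzero(rdf.g > 0)[0]
        assert len(occ) == 1 and abs(rdf.bin_centers[occ[0]] - d) <= dr
        edges_lo = occ[0] * dr
        shell = 4.0 / 3.0 * np.pi * ((edges_lo + dr) ** 3 - edges_lo ** 3)
        expected = 64.0 / shell  # V / shell volume, N(N-1)/2 = 1 pair
        assert rdf.g[occ[0]] == pytest.approx(expected, rel=1e-9)

    def test_r_max_beyond_half_box_rejected(self):
        cfg_traj = _static_traj(
            Configuration(np.zeros((3, 3)) + 1.0, np.zeros((3, 3)),
                          np.full(3, 3.0), get_model("FBA_mem")))
        with pytest.raises(ValueError, match="half"):
            rdf_OO(cfg_traj, r_max=2.0)

    def test_uniform_coordination_closed_form(self):
        """For g = 1, n(r) = 4 pi rho r^3 / 3."""
        rng = np.random.default_rng(9)
        spec = get_model("FBA_mem")
        box = np.full(3, 3.0)
        traj = Trajectory(spec=spec)
        n_ox = 300
        for k in range(30):
            ox = rng.uniform(0, 3.0, (n_ox, 3))
            pos = ox[:, None, :] + np.zeros((n_ox, 3, 3))
            traj.append(float(k), Configuration(pos.reshape(-1, 3),
                                                np.zeros((n_ox * 3, 3)), box,
                                                spec), EnergyReport())
        rdf = rdf_OO(traj, dr=0.02)
        rho = n_ox / 27.0
        idx = np.searchsorted(rdf.bin_centers, 1.0)
        r_edge = rdf.bin_centers[idx] + 0.01  # cumulative through this bin
        expected = 4.0 / 3.0 * np.pi * rho * r_edge ** 3
        assert rdf.coordination[idx] == pytest.approx(expected, rel=0.05)


class TestSelfDiffusion:
    def test_immobile_particles_give_zero(self):
        pos = np.zeros((50, 20, 3))
        traj = synthetic_trajectory(pos, get_model("FBA_mem"), np.full(3, 100.0))
        est = self_diffusion(traj)
        assert est.mean == pytest.approx(0.0, abs=1e-12)

    def test_brownian_recovery_within_5_percent(self):
        walk, manifest = brownian_walk_trajectory(n_particles=400,
                                                  n_steps=6000, seed=12)
        traj = synthetic_trajectory(walk, get_model("FBA_mem"),
                                    np.full(3, 1e6), dt_frame=manifest["dt"])
        est = self_diffusion(traj)
        assert est.mean == pytest.approx(manifest["D_true"], rel=0.05)

    def test_msd_fit_is_linear_on_brownian_data(self):
        walk, manifest = brownian_walk_trajectory(n_particles=300,
                                                  n_steps=4000, seed=5)
        com = walk
        lags = np.arange(1, 400, 10)
        msd = np.array([((com[l:] - com[:-l]) ** 2).sum(axis=2).mean()
                        for l in lags])
        r = np.corrcoef(lags, msd)[0, 1]
        assert r ** 2 > 0.99

    def test_wrapped_input_detected(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(size=(60, 10, 3)), axis=0)
        box = np.full(3, 2.0)
        pos_wrapped = pos - np.floor(pos / box) * box
        traj = synthetic_trajectory(pos_wrapped, get_model("FBA_mem"), box)
        with pytest.raises(ValueError, match="wrap"):
            self_diffusion(traj)

    def test_ballistic_regime_excluded(self):
        """Straight-line motion: MSD ~ t^2; the central fit window still
        yields slope/6 of the local tangent, but the regime check is that the
        short-lag points are not in the fit."""
        t = np.arange(200, dtype=float)
        pos = np.zeros((200, 5, 3))
        pos[:, :, 0] = t[:, None] * 0.01
        traj = synthetic_trajectory(pos, get_model("FBA_mem"), np.full(3, 1e6))
        est = self_diffusion(traj, fit_window=(0.1, 0.5))
        # ballistic MSD grows superlinearly; D is finite and positive but the
        # estimate must come from lags >= 10% of max lag only
        assert est.mean > 0


class TestHBonds:
    def _two_waters(self, d, angle_deg):
        """Donor at origin with one O-H rotated angle_deg off the O-O axis."""
        spec = get_model("FBA_mem")
        box = np.full(3, 5.0)
        r_oh = spec.r_OH0
        th = math.radians(angle_deg)
        pos = np.zeros((6, 3))
        pos[:] = 2.0
        # donor O at 2,2,2; H1 at angle off +x axis; H2 far below
        pos[1] = pos[0] + r_oh * np.array([math.cos(th), math.sin(th), 0.0])
        pos[2] = pos[0] + r_oh * np.array([0.0, 0.0, -1.0])
        # acceptor O along +x at distance d; its H's pointing +x
        pos[3] = pos[0] + np.array([d, 0.0, 0.0])
        pos[4] = pos[3] + r_oh * np.array([0.8, 0.6, 0.0])
        pos[5] = pos[3] + r_oh * np.array([0.8, -0.6, 0.0])
        return Configuration(pos, np.zeros((6, 3)), box, spec)

    @pytest.mark.parametrize("d,angle,expected", [
        (0.30, 0.0, 1),   # criterion interior
        (0.36, 0.0, 0),   # distance violation
        (0.30, 35.0, 0),  # angle violation
        (0.349, 29.0, 1),  # just inside both limits
    ])
    def test_geometric_criterion(self, d, angle, expected):
        cfg = self._two_waters(d, angle)
        bonds = detect_hbonds(cfg.positions, cfg.box, 3)
        assert len(bonds) == expected

    def test_isolated_molecule_has_no_bonds(self):
        spec = get_model("FBA_mem")
        geo = ideal_geometry(spec).site_positions + 2.0
        cfg = Configuration(geo, np.zeros_like(geo), np.full(3, 5.0), spec)
        assert len(detect_hbonds(cfg.positions, cfg.box, 3)) == 0

    @pytest.mark.parametrize("n_bonds", [1, 2, 3, 4])
    def test_constructed_cluster_counts(self, n_bonds):
        cfg, manifest = hbond_cluster("FBA_mem", n_bonds=n_bonds)
        bonds = detect_hbonds(cfg.positions, cfg.box, cfg.spec.n_sites)
        assert len(bonds) == manifest["n_bonds"]

    def test_four_site_cluster(self):
        cfg, manifest = hbond_cluster("T4F_mem", n_bonds=4)
        bonds = detect_hbonds(cfg.positions, cfg.box, 4)
        assert len(bonds) == 4

    def test_hbond_count_trajectory(self):
        cfg, _ = hbond_cluster("FBA_mem", n_bonds=4)
        traj = _static_traj(cfg, n_frames=8)
        total, per_mol = hbond_count(traj, burn_in=0.0, n_blocks=4)
        assert total.mean == 4.0
        assert per_mol.mean == pytest.approx(4.0 / 5.0)

    def test_untagged_sites_rejected(self):
        with pytest.raises(ValueError, match="n_sites"):
            detect_hbonds(np.zeros((6, 3)), np.full(3, 5.0), 5)


class TestOccupancy:
    def test_always_bonded_pair_is_100(self):
        cfg, _ = hbond_cluster("FBA_mem", n_bonds=1)
        traj = _static_traj(cfg, n_frames=6)
        table = hbond_occupancy(traj)
        assert set(table.pair_occupancy.values()) == {100.0}

    def test_group_occupancy_sums_over_pairs(self):
        """Two pairs at 60% and 80% in one group -> 140%."""
        cfg_on, _ = hbond_cluster("FBA_mem", n_bonds=2)
        cfg_one = cfg_on.copy()
        # push the second neighbor out of range in some frames
        cfg_one.positions[6:9] += 1.5
        cfg_off = cfg_on.copy()
        cfg_off.positions[3:9] += 1.5
        traj = Trajectory(spec=cfg_on.spec)
        frames = [cfg_on] * 3 + [cfg_one] * 1 + [cfg_off] * 1  # 5 frames
        for k, c in enumerate(frames):
            traj.append(float(k), c, EnergyReport())
        table = hbond_occupancy(traj, grouping={0: "center", 1: None, 2: None})
        # pair (0,1): frames 0-3 bonded = 4/5 = 80%; pair (0,2): 3/5 = 60%
        occ = sorted(table.pair_occupancy.values())
        assert occ == [60.0, 80.0]
        assert table.group_occupancy["center"] == pytest.approx(140.0)

    def test_single_frame_rejected(self):
        cfg, _ = hbond_cluster("FBA_mem", n_bonds=1)
        traj = _static_traj(cfg, n_frames=1)
        with pytest.raises(ValueError, match="2 frames"):
            hbond_occupancy(traj)

    def test_empty_grouping_rejected(self):
        cfg, _ = hbond_cluster("FBA_mem", n_bonds=1)
        traj = _static_traj(cfg, n_frames=3)
        with pytest.raises(ValueError, match="grouping"):
            hbond_occupancy(traj, grouping={})


class TestFEL:
    def test_two_state_gap_closed_form(self):
        x, y, manifest = two_state_series(seed=4)
        surf = fel_surface(x, y, manifest["T"], n_bins=8)
        finite = surf.deltaG[np.isfinite(surf.deltaG)]
        gap = finite.max() - finite.min()
        # kB * 309.65 * ln 10 = 5.93 kJ/mol
        assert manifest["gap_expected"] == pytest.approx(5.93, abs=0.01)
        assert gap == pytest.approx(manifest["gap_expected"], rel=0.02)

    def test_modal_bin_is_exactly_zero(self):
        x, y, _ = two_state_series(seed=4)
        surf = fel_surface(x, y, 309.65, n_bins=8)
        assert np.nanmin(surf.deltaG) == 0.0

    def test_uniform_histogram_flat_surface(self):
        rng = np.random.default_rng(0)
        # exactly equal counts per bin: regular grid of samples
        g = np.linspace(0.05, 0.95, 10)
        x, y = np.meshgrid(g, g)
        surf = fel_surface(x.ravel(), y.ravel(), 300.0, n_bins=10)
        assert np.allclose(surf.deltaG, 0.0)

    def test_uniform_count_shift_preserves_differences(self):
        """Adding a constant count per bin rescales P but preserves dG
        differences exactly in the log."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        counts, xe, ye = np.histogram2d(x, y, bins=6)
        T = 300.0
        with np.errstate(divide="ignore"):
            dg1 = -KB * T * np.log(counts / counts.max())
            shifted = counts * 3.0  # uniform multiplicative shift
            dg2 = -KB * T * np.log(shifted / shifted.max())
        assert np.allclose(dg1[np.isfinite(dg1)], dg2[np.isfinite(dg2)])

    def test_population_ratio_reproduced_exactly(self):
        # two bins with known counts: dG difference = kBT ln(n1/n2)
        x = np.array([0.0] * 30 + [1.0] * 10)
        y = x.copy()
        surf = fel_surface(x, y, 250.0, n_bins=2)
        finite = np.sort(surf.deltaG[np.isfinite(surf.deltaG)])
        assert finite[-1] == pytest.approx(KB * 250.0 * math.log(3.0), rel=1e-12)

    def test_constant_series_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fel_surface(np.ones(50), np.ones(50), 300.0)


class TestGeometryDistributions:
    def test_static_ideal_geometry_is_delta(self):
        spec = get_model("FBA_mem")
        from lewmd import build_box
        cfg = build_box(spec, 8, 0.5, seed=2)
        traj = _static_traj(cfg, n_frames=6)
        bond, angle, (rc, rh), (tc, th) = geometry_distributions(traj,
                                                                 burn_in=0.0)
        assert bond.mean == pytest.approx(spec.r_OH0, abs=1e-12)
        assert angle.mean == pytest.approx(spec.theta0, abs=1e-9)
        assert bond.stderr == pytest.approx(0.0, abs=1e-12)


def test_block_average_reduces_to_sem_for_iid():
    rng = np.random.default_rng(0)
    x = rng.normal(size=10000)
    mean, err = block_average(x, n_blocks=10)
    assert mean == pytest.approx(x.mean())
    assert err == pytest.approx(x.std() / 100.0, rel=0.8)
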