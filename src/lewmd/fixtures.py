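"""Deterministic synthetic fixtures with manifest oracles.

Every generator returns (and optionally writes) data whose defining
parameters are recorded in a manifest; the regression suite checks that the
corresponding observable recovers each manifest value.  Nothing here needs a
download or a binary file.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .constants import DIFFUSION_TO_1E5_CM2_S, KB
from .engine import Trajectory
from .forces import EnergyReport
from .models import WaterModelSpec, get_model, ideal_geometry
from .system import Configuration, build_box

__all__ = ["gen_fixture", "FIXTURE_KINDS", "brownian_walk_trajectory",
           "gaussian_dipoles", "two_state_series", "hbond_cluster",
           "dimer_scan_configs", "synthetic_trajectory"]


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, tag])))


def brownian_walk_trajectory(n_particles: int = 1000, n_steps: int = 10000,
                             d_true: float = 2.5, dt: float = 0.001,
                             seed: int = 0) -> tuple[np.ndarray, dict]:
    """3-D Brownian walk with known diffusion coefficient.

    ``d_true`` is in 1e-5 cm^2/s; per-step displacement variance is
    2 D dt per dimension.  Returns (positions (n_steps, n_particles, 3) nm,
    manifest).
    """
    d_nm2_ps = d_true / DIFFUSION_TO_1E5_CM2_S
    sigma = math.sqrt(2.0 * d_nm2_ps * dt)
    rng = _rng(seed, 1)
    steps = rng.normal(scale=sigma, size=(n_steps, n_particles, 3))
    walk = np.cumsum(steps, axis=0)
    manifest = {"kind": "brownian_walk", "D_true": d_true, "dt": dt,
                "n_particles": n_particles, "n_steps": n_steps, "seed": seed}
    return walk, manifest


def gaussian_dipoles(n_samples: int = 20000, variance: float = 1.0,
                     volume: float = 15.0, T: float = 309.65,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray, dict]:
    """Isotropic Gaussian total-dipole stream with a closed-form dielectric.

    Per-component variance ``variance`` (e^2 nm^2) at fixed volume gives
    eps = 1 + 3 v / (3 eps0 V kB T) = 1 + 4 pi f v / (V kB T).
    """
    from .constants import F_COULOMB
    rng = _rng(seed, 2)
    m = rng.normal(scale=math.sqrt(variance), size=(n_samples, 3))
    vols = np.full(n_samples, volume)
    eps_expected = 1.0 + 4.0 * math.pi * F_COULOMB * 3.0 * variance / (
        3.0 * volume * KB * T)
    manifest = {"kind": "gaussian_dipoles", "variance": variance,
                "volume": volume, "T": T, "n_samples": n_samples,
                "eps_expected": eps_expected, "seed": seed}
    return m, vols, manifest


def two_state_series(n_samples: int = 11000, ratio: float = 10.0,
                     T: float = 309.65, seed: int = 0):
    """Two well-separated 2-D states populated ratio:1.

    The free-energy gap between the two occupied basins is kB T ln(ratio).
    """
    rng = _rng(seed, 3)
    n_a = int(n_samples * ratio / (ratio + 1.0))
    x = np.concatenate([np.zeros(n_a), np.ones(n_samples - n_a)])
    y = x.copy()
    # tiny jitter keeps the histogram well-conditioned without mixing states
    x += rng.uniform(-0.01, 0.01, n_samples)
    y += rng.uniform(-0.01, 0.01, n_samples)
    manifest = {"kind": "two_state_series", "ratio": ratio, "T": T,
                "gap_expected": KB * T * math.log(ratio), "seed": seed}
    return x, y, manifest


def hbond_cluster(model: str = "FBA_mem", n_bonds: int = 4,
                  ) -> tuple[Configuration, dict]:
    """A central water donating/accepting exactly ``n_bonds`` constructed bonds.

    Neighbor oxygens are placed at 0.28 nm with a hydrogen of the donor
    aligned toward the acceptor (angle 0), comfortably inside the geometric
    criterion; the box is large enough that no other pair qualifies.
    """
    if not 1 <= n_bonds <= 4:
        raise ValueError("n_bonds must be 1..4")
    spec = get_model(model)
    geo = ideal_geometry(spec).site_positions
    box = np.full(3, 5.0)
    center = np.full(3, 2.5)
    mols = [geo + center]
    d = 0.28
    half = math.radians(spec.theta0) / 2.0
    s, c = math.sin(half), math.cos(half)
    # acceptors sit on the central molecule's O-H directions; donors sit on
    # the mirrored directions in the y-z plane.  All pairwise angular
    # separations exceed 99 degrees, so at 0.28 nm every non-central O-O
    # distance is > 0.42 nm and no spurious bond can form.
    placements = [
        ("donate", np.array([s, 0.0, c])),
        ("donate", np.array([-s, 0.0, c])),
        ("accept", np.array([0.0, s, -c])),
        ("accept", np.array([0.0, -s, -c])),
    ][:n_bonds]
    for mode, u in placements:
        o_pos = center + d * u
        if mode == "donate":
            # acceptor: orient its hydrogens away from the axis
            rot = _rotation_from_z(-u)
            mols.append(geo @ rot.T + o_pos)
        else:
            # neighbor donates: one O-H must point from its O toward center
            rot = _rotation_oh_towards(spec, -u)
            mols.append(geo @ rot.T + o_pos)
    pos = np.concatenate(mols)
    config = Configuration(pos, np.zeros_like(pos), box, spec)
    from .system import place_msites
    place_msites(config)
    manifest = {"kind": "hbond_cluster", "model": spec.name, "n_bonds": n_bonds}
    return config, manifest


def _rotation_from_z(target: np.ndarray) -> np.ndarray:
    """Rotation mapping +z to ``target`` (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, target)
    c = float(z @ target)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _rotation_oh_towards(spec: WaterModelSpec, direction: np.ndarray) -> np.ndarray:
    """Rotation placing the first O-H bond of the ideal geometry along ``direction``."""
    half = math.radians(spec.theta0) / 2.0
    oh1 = np.array([math.sin(half), 0.0, math.cos(half)])
    return _rotation_from_z(direction) @ _rotation_from_z(oh1).T


def dimer_scan_configs(model: str = "FBA_mem", distances=None):
    """Two molecules at prescribed O-O separations in a large box.

    With charges switched off in analysis, the LJ energy is 0 at r = sigma
    and -eps_OO at r = 2^(1/6) sigma.
    """
    spec = get_model(model)
    if distances is None:
        distances = [spec.sigma_OO, 2 ** (1 / 6) * spec.sigma_OO, 0.4, 0.6]
    geo = ideal_geometry(spec).site_positions
    configs = []
    box = np.full(3, 6.0)
    for r in distances:
        a = geo + np.array([2.0, 3.0, 3.0])
        b = geo @ np.diag([1.0, 1.0, -1.0]) + np.array([2.0 + r, 3.0, 3.0])
        pos = np.concatenate([a, b])
        cfg = Configuration(pos, np.zeros_like(pos), box, spec)
        from .system import place_msites
        place_msites(cfg)
        configs.append(cfg)
    manifest = {"kind": "dimer_scan", "model": spec.name,
                "distances": [float(r) for r in distances],
                "sigma_OO": spec.sigma_OO, "eps_OO": spec.eps_OO}
    return configs, manifest


def synthetic_trajectory(positions: np.ndarray, spec: WaterModelSpec | None,
                         box: np.ndarray, dt_frame: float = 1.0) -> Trajectory:
    """Wrap an (n_frames, n_points, 3) center-of-mass array as a Trajectory.

    Used to feed synthetic random walks to the MSD estimator; site-level
    fields mirror the COM data so frame bookkeeping stays consistent.
    """
    traj = Trajectory(spec=spec)
    for k, frame in enumerate(positions):
        traj.times.append(k * dt_frame)
        traj.positions.append(frame)
        traj.boxes.append(np.asarray(box, float))
        traj.dipoles.append(np.zeros(3))
        traj.energies.append(EnergyReport())
        traj.com.append(frame)
    return traj


FIXTURE_KINDS = ("lattice_box", "hbond_cluster", "brownian_walk",
                 "two_state_series", "gaussian_dipoles", "dimer_scan")


def gen_fixture(kind: str, seed: int = 0, outdir=None, model: str = "FBA_mem"):
    """Generate a named fixture; optionally write files plus a JSON manifest."""
    if kind == "lattice_box":
        config = build_box(get_model(model), 27, target_density=0.994, seed=seed)
        manifest = {"kind": kind, "model": model, "n_molecules": 27,
                    "target_density": 0.994, "seed": seed}
        payload = config
    elif kind == "hbond_cluster":
        payload, manifest = hbond_cluster(model)
    elif kind == "brownian_walk":
        payload, manifest = brownian_walk_trajectory(n_particles=200,
                                                     n_steps=4000, seed=seed)
    elif kind == "two_state_series":
        x, y, manifest = two_state_series(seed=seed)
        payload = (x, y)
    elif kind == "gaussian_dipoles":
        m, v, manifest = gaussian_dipoles(seed=seed)
        payload = (m, v)
    elif kind == "dimer_scan":
        payload, manifest = dimer_scan_configs(model)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS}")
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{kind}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        _write_payload(kind, payload, outdir, manifest)
    return payload, manifest


def _write_payload(kind, payload, outdir: Path, manifest) -> None:
    from .gmxio import write_gro
    if kind == "lattice_box":
        write_gro(payload, outdir / "lattice_box.gro")
    elif kind == "hbond_cluster":
        write_gro(payload, outdir / "hbond_cluster.gro")
    elif kind == "dimer_scan":
        for cfg, r in zip(payload, manifest["distances"]):
            write_gro(cfg, outdir / f"dimer_{r:.4f}nm.gro")
    elif kind == "brownian_walk":
        np.savetxt(outdir / "brownian_walk_first_particle.txt", payload[:, 0, :],
                   header="x y z (nm), one row per frame")
    elif kind == "two_state_series":
        np.savetxt(outdir / "two_state_series.txt", np.column_stack(payload),
                   header="x y")
    elif kind == "gaussian_dipoles":
        np.savetxt(outdir / "gaussian_dipoles.txt",
                   np.column_stack([payload[0], payload[1]]),
                   header="Mx My Mz (e nm), V (nm^3)")
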