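"""Periodic water boxes: configuration container and lattice construction."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .constants import KB, U_PER_NM3_TO_G_CM3
from .models import WaterModelSpec, ideal_geometry

__all__ = ["Configuration", "SimulationProtocol", "build_box", "place_msites"]


@dataclass
class SimulationProtocol:
    """Run-control parameters for minimization and MD.

    Defaults encode the production protocol (1 fs leapfrog, 1.2 nm cutoff,
    compressibility 4.5e-5 1/bar, V-rescale thermostat); desk-scale presets
    shrink the cutoff to fit small boxes.
    """

    ensemble: str = "NPT"  # NVE | NVT | NPT
    T_ref: float = 309.65  # K
    P_ref: float = 1.0  # bar
    dt: float = 1.0e-3  # ps (1 fs)
    n_steps: int = 0
    cutoff: float = 1.2  # nm
    eps_rf: float = np.inf  # reaction-field dielectric; inf = conducting boundary
    tau_T: float = 0.1  # ps
    tau_P: float = 2.0  # ps
    compressibility: float = 4.5e-5  # 1/bar
    seed: int = 2024
    save_every: int = 100  # steps
    skin: float = 0.1  # nm, neighbor-list margin
    tail_correction: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.ensemble not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.cutoff <= 0 or self.skin < 0:
            raise ValueError("cutoff must be positive and skin non-negative")


@dataclass
class Configuration:
    """Positions/velocities/box of an N-molecule water system under PBC.

    Sites are stored molecule-major: molecule ``m`` occupies rows
    ``m*n_sites … (m+1)*n_sites-1`` in the order OW, HW1, HW2[, MW].
    Molecules are kept whole (no per-site wrapping); interactions use the
    minimum image so coordinates may be carried unwrapped during dynamics.
    """

    positions: np.ndarray  # (n_sites_total, 3) nm
    velocities: np.ndarray  # (n_sites_total, 3) nm/ps
    box: np.ndarray  # (3,) nm, orthorhombic edges
    spec: WaterModelSpec
    molecule_index: np.ndarray = field(default=None)  # site -> molecule

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite values")
        ns = self.spec.n_sites
        if self.positions.shape[0] % ns:
            raise ValueError("site count is not a multiple of n_sites")
        if self.molecule_index is None:
            self.molecule_index = np.repeat(np.arange(self.n_molecules), ns)

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0] // self.spec.n_sites

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def masses(self) -> np.ndarray:
        if getattr(self, "_masses", None) is None or len(self._masses) != self.n_sites:
            self._masses = np.tile(self.spec.site_masses, self.n_molecules)
        return self._masses

    @property
    def charges(self) -> np.ndarray:
        if getattr(self, "_charges", None) is None or len(self._charges) != self.n_sites:
            self._charges = np.tile(self.spec.site_charges, self.n_molecules)
        return self._charges

    def oxygen_positions(self) -> np.ndarray:
        return self.positions[:: self.spec.n_sites]

    def molecule_com(self) -> np.ndarray:
        """Centers of mass per molecule, (n_molecules, 3)."""
        ns = self.spec.n_sites
        m = self.spec.site_masses
        pos = self.positions.reshape(self.n_molecules, ns, 3)
        return (pos * m[None, :, None]).sum(axis=1) / m.sum()

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.velocities.copy(),
                             self.box.copy(), self.spec)

    def wrapped(self) -> "Configuration":
        """Copy with each molecule shifted so its COM lies in [0, box)."""
        out = self.copy()
        com = out.molecule_com()
        shift = np.floor(com / out.box) * out.box
        ns = self.spec.n_sites
        out.positions -= np.repeat(shift, ns, axis=0)
        return out

    def total_dipole(self) -> np.ndarray:
        """Total box dipole M = sum q_i r_i, e*nm (molecules whole, so well defined)."""
        return self.charges @ self.positions


def place_msites(config: Configuration) -> None:
    """Re-place virtual M-sites from the current O/H positions (in place).

    Linear three-atom construction r_M = r_O + a (r_H1 - r_O) + a (r_H2 - r_O);
    a no-op for three-site models.
    """
    spec = config.spec
    if spec.n_sites == 3:
        return
    a = spec.vsite_coeff
    pos = config.positions.reshape(config.n_molecules, 4, 3)
    pos[:, 3] = pos[:, 0] + a * (pos[:, 1] - pos[:, 0]) + a * (pos[:, 2] - pos[:, 0])
    config.velocities.reshape(config.n_molecules, 4, 3)[:, 3] = 0.0


def maxwell_boltzmann_velocities(config: Configuration, T: float,
                                 rng: np.random.Generator) -> None:
    """Draw site velocities at temperature T (in place); massless sites get zero.

    Net momentum is removed and the result rescaled to hit T exactly on the
    COM-free degrees of freedom.
    """
    m = config.masses
    v = np.zeros_like(config.positions)
    massive = m > 0
    sigma = np.sqrt(KB * T / m[massive])
    v[massive] = rng.normal(size=(massive.sum(), 3)) * sigma[:, None]
    # remove COM momentum
    p = (m[massive, None] * v[massive]).sum(axis=0)
    v[massive] -= p / m[massive].sum()
    ndof = 3 * int(massive.sum()) - 3
    ke = 0.5 * float((m[massive] * (v[massive] ** 2).sum(axis=1)).sum())
    v[massive] *= np.sqrt(0.5 * ndof * KB * T / ke)
    config.velocities[:] = v


def build_box(
    spec: WaterModelSpec,
    n_molecules: int,
    target_density: float = 0.994,
    seed: int = 0,
    T_velocities: Optional[float] = None,
    jitter: float = 0.02,
) -> Configuration:
    """Pack ``n_molecules`` water molecules on a jittered cubic lattice.

    The cubic box edge is fixed by mass/volume = ``target_density`` (g/cm^3).
    Molecules are placed at ideal internal geometry with random orientations;
    the lattice guarantees no initial overlap for jitter amplitudes well
    below half the lattice spacing.

    Deterministic for a fixed seed.
    """
    if target_density <= 0:
        raise ValueError("target_density must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0xB0C5])))
    mass = n_molecules * spec.site_masses.sum()  # u
    volume = mass * U_PER_NM3_TO_G_CM3 / target_density  # nm^3
    edge = volume ** (1.0 / 3.0)
    n_side = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = edge / n_side
    if jitter > 0.3 * spacing:
        raise ValueError(
            f"density {target_density} g/cm^3 gives lattice spacing {spacing:.3f} nm; "
            "jitter would create unresolvable overlaps"
        )
    geo = ideal_geometry(spec).site_positions
    cells = np.stack(np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"), axis=-1)
    cells = cells.reshape(-1, 3)[:n_molecules]
    centers = (cells + 0.5) * spacing + rng.uniform(-jitter, jitter, (n_molecules, 3))
    positions = np.empty((n_molecules * spec.n_sites, 3))
    for i in range(n_molecules):
        rot = _random_rotation(rng)
        positions[i * spec.n_sites:(i + 1) * spec.n_sites] = geo @ rot.T + centers[i]
    config = Configuration(positions, np.zeros_like(positions),
                           np.full(3, edge), spec)
    if T_velocities is not None:
        maxwell_boltzmann_velocities(config, T_velocities, rng)
    place_msites(config)
    return config


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
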