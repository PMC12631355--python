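"""Force and energy evaluation for the flexible water force field.

Intramolecular terms are harmonic bonds V = 1/2 k_b (r - r0)^2 on each O-H
and a harmonic bend V = 1/2 k_a (theta - theta0)^2 per molecule.
Intermolecular terms are LJ between oxygens only and Coulomb between all
charged sites of distinct molecules under the minimum image, with
reaction-field damping inside the cutoff:

    V_c(r) = f q_i q_j (1/r + k_rf r^2 - c_rf),   r < r_c

With a conducting boundary (eps_RF = infinity) k_rf = 1/(2 r_c^3) and
c_rf = 3/(2 r_c), which makes both the potential and the force vanish at
the cutoff.  Forces landing on the massless M-site are redistributed onto
O, H1, H2 by the linear virtual-site weights, which preserves the net force,
torque and virial of each molecule exactly.

A naive Ewald energy path (``ewald_energy``) is provided for small
validation boxes only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .constants import F_COULOMB, KB, PRESSURE_TO_BAR
from .neighbors import SITE_OFFSET_MARGIN, WaterPairList
from .system import Configuration, SimulationProtocol

__all__ = ["EnergyReport", "compute_forces", "kinetic_energy", "ewald_energy"]

#: hard floor on pair distances, nm; below this the configuration is unphysical
R_SINGULAR = 1e-4


@dataclass
class EnergyReport:
    """Per-configuration energy decomposition plus instantaneous T and P."""

    bond: float = 0.0
    angle: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    kinetic: float = 0.0
    pressure: float = 0.0  # bar, virial route
    temperature: float = 0.0  # K, equipartition on 3 N_massive - 3 dof

    @property
    def potential(self) -> float:
        return self.bond + self.angle + self.lj + self.coulomb

    @property
    def total(self) -> float:
        return self.potential + self.kinetic


class SingularityError(RuntimeError):
    """Two interacting sites closer than the hard floor."""


class BlowUpError(RuntimeError):
    """Integration produced an unphysical displacement or non-finite state."""

    def __init__(self, message, step=None, last_config=None):
        super().__init__(message)
        self.step = step
        self.last_config = last_config


@njit(cache=True, fastmath=True)
def _water_kernel(pos, box, mol_i, mol_j, ns, qprod, sigma, eps, rc, prefilter,
                  krf, crf, fcoul, forces):
    """Nonbonded LJ + reaction-field Coulomb over molecule pairs.

    Each site pair gets its own minimum image (required near half-box
    separations); a cheap O-O prefilter skips molecule pairs entirely out
    of range.  qprod is the ns x ns matrix of site-charge products.
    """
    e_lj = 0.0
    e_coul = 0.0
    virial = 0.0
    r2min = 1.0e30
    rc2 = rc * rc
    pre2 = prefilter * prefilter
    sig2 = sigma * sigma
    ibx = 1.0 / box[0]
    iby = 1.0 / box[1]
    ibz = 1.0 / box[2]
    for k in range(mol_i.shape[0]):
        oi = mol_i[k] * ns
        oj = mol_j[k] * ns
        dx = pos[oi, 0] - pos[oj, 0]
        dy = pos[oi, 1] - pos[oj, 1]
        dz = pos[oi, 2] - pos[oj, 2]
        dx -= box[0] * math.floor(dx * ibx + 0.5)
        dy -= box[1] * math.floor(dy * iby + 0.5)
        dz -= box[2] * math.floor(dz * ibz + 0.5)
        if dx * dx + dy * dy + dz * dz > pre2:
            continue
        for a in range(ns):
            ia = oi + a
            for b in range(ns):
                jb = oj + b
                qp = qprod[a, b]
                is_oo = a == 0 and b == 0
                if qp == 0.0 and not is_oo:
                    continue
                ddx = pos[ia, 0] - pos[jb, 0]
                ddy = pos[ia, 1] - pos[jb, 1]
                ddz = pos[ia, 2] - pos[jb, 2]
                ddx -= box[0] * math.floor(ddx * ibx + 0.5)
                ddy -= box[1] * math.floor(ddy * iby + 0.5)
                ddz -= box[2] * math.floor(ddz * ibz + 0.5)
                r2 = ddx * ddx + ddy * ddy + ddz * ddz
                if r2 >= rc2:
                    continue
                if r2 < r2min:
                    r2min = r2
                inv_r2 = 1.0 / r2
                fscal = 0.0
                if is_oo:
                    sr2 = sig2 * inv_r2
                    sr6 = sr2 * sr2 * sr2
                    sr12 = sr6 * sr6
                    e_lj += 4.0 * eps * (sr12 - sr6)
                    fscal += 24.0 * eps * (2.0 * sr12 - sr6) * inv_r2
                if qp != 0.0:
                    r = math.sqrt(r2)
                    e_coul += fcoul * qp * (1.0 / r + krf * r2 - crf)
                    fscal += fcoul * qp * (1.0 / (r2 * r) - 2.0 * krf)
                fx = fscal * ddx
                fy = fscal * ddy
                fz = fscal * ddz
                forces[ia, 0] += fx
                forces[ia, 1] += fy
                forces[ia, 2] += fz
                forces[jb, 0] -= fx
                forces[jb, 1] -= fy
                forces[jb, 2] -= fz
                virial += fx * ddx + fy * ddy + fz * ddz
    return e_lj, e_coul, virial, r2min


@njit(cache=True, fastmath=True)
def _bonded_kernel(pos, n_mol, ns, k_b, r0, k_a, theta0, forces):
    """Harmonic O-H bonds and H-O-H bend for every molecule (direct distances:
    molecules are kept whole, never split across the boundary)."""
    e_bond = 0.0
    e_angle = 0.0
    virial = 0.0
    for m in range(n_mol):
        o = m * ns
        # two O-H bonds
        for h in (o + 1, o + 2):
            dx = pos[h, 0] - pos[o, 0]
            dy = pos[h, 1] - pos[o, 1]
            dz = pos[h, 2] - pos[o, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - r0
            e_bond += 0.5 * k_b * dr * dr
            fscal = -k_b * dr / r  # force on h along (h-o)
            fx = fscal * dx
            fy = fscal * dy
            fz = fscal * dz
            forces[h, 0] += fx
            forces[h, 1] += fy
            forces[h, 2] += fz
            forces[o, 0] -= fx
            forces[o, 1] -= fy
            forces[o, 2] -= fz
            virial += fx * dx + fy * dy + fz * dz
        # bend
        h1 = o + 1
        h2 = o + 2
        ax = pos[h1, 0] - pos[o, 0]
        ay = pos[h1, 1] - pos[o, 1]
        az = pos[h1, 2] - pos[o, 2]
        bx = pos[h2, 0] - pos[o, 0]
        by = pos[h2, 1] - pos[o, 1]
        bz = pos[h2, 2] - pos[o, 2]
        ra = math.sqrt(ax * ax + ay * ay + az * az)
        rb = math.sqrt(bx * bx + by * by + bz * bz)
        cosq = (ax * bx + ay * by + az * bz) / (ra * rb)
        if cosq > 1.0:
            cosq = 1.0
        elif cosq < -1.0:
            cosq = -1.0
        theta = math.acos(cosq)
        dth = theta - theta0
        e_angle += 0.5 * k_a * dth * dth
        sinq = math.sqrt(1.0 - cosq * cosq)
        if sinq < 1e-8:
            sinq = 1e-8
        coef = -k_a * dth / sinq  # dV/dcos(theta)
        # d cos/d r_h1 etc.
        f1x = coef * (bx / (ra * rb) - cosq * ax / (ra * ra))
        f1y = coef * (by / (ra * rb) - cosq * ay / (ra * ra))
        f1z = coef * (bz / (ra * rb) - cosq * az / (ra * ra))
        f2x = coef * (ax / (ra * rb) - cosq * bx / (rb * rb))
        f2y = coef * (ay / (ra * rb) - cosq * by / (rb * rb))
        f2z = coef * (az / (ra * rb) - cosq * bz / (rb * rb))
        forces[h1, 0] -= f1x
        forces[h1, 1] -= f1y
        forces[h1, 2] -= f1z
        forces[h2, 0] -= f2x
        forces[h2, 1] -= f2y
        forces[h2, 2] -= f2z
        forces[o, 0] += f1x + f2x
        forces[o, 1] += f1y + f2y
        forces[o, 2] += f1z + f2z
        # translation-invariant atom-based virial for the three-body term
        virial += -(f1x * ax + f1y * ay + f1z * az)
        virial += -(f2x * bx + f2y * by + f2z * bz)
    return e_bond, e_angle, virial


def _rf_coefficients(cutoff: float, eps_rf: float | None) -> tuple[float, float]:
    """Reaction-field k_rf/c_rf; eps_rf=None gives plain shifted truncation."""
    if eps_rf is None:
        return 0.0, 1.0 / cutoff
    if math.isinf(eps_rf):
        krf = 1.0 / (2.0 * cutoff ** 3)
    else:
        krf = (eps_rf - 1.0) / ((2.0 * eps_rf + 1.0) * cutoff ** 3)
    return krf, 1.0 / cutoff + krf * cutoff ** 2


def _lj_tail(spec, n_mol: int, volume: float, cutoff: float) -> tuple[float, float]:
    """Analytic LJ tail corrections: (energy kJ/mol, pressure contribution kJ/mol/nm^3)."""
    rho = n_mol / volume  # oxygen density
    s3 = (spec.sigma_OO / cutoff) ** 3
    s9 = s3 ** 3
    pref = (8.0 / 3.0) * math.pi * rho * spec.eps_OO * spec.sigma_OO ** 3
    e_tail = pref * n_mol * (s9 / 3.0 - s3)
    p_tail = (16.0 / 3.0) * math.pi * rho * rho * spec.eps_OO * spec.sigma_OO ** 3 \
        * (2.0 / 3.0 * s9 - s3)
    return e_tail, p_tail


def kinetic_energy(config: Configuration) -> float:
    """Kinetic energy of the massive sites, kJ/mol."""
    m = config.masses
    return 0.5 * float((m * (config.velocities ** 2).sum(axis=1)).sum())


def n_dof(config: Configuration) -> int:
    """3 x massive sites - 3 (COM motion removed)."""
    return 3 * int((config.spec.site_masses > 0).sum()) * config.n_molecules - 3


def compute_forces(
    config: Configuration,
    protocol: SimulationProtocol,
    pairlist: WaterPairList | None = None,
) -> tuple[np.ndarray, EnergyReport]:
    """Evaluate forces (kJ mol^-1 nm^-1 per site) and an :class:`EnergyReport`.

    M-site forces are already redistributed in the returned array (M rows are
    zero).  The virial-route pressure includes the LJ tail correction when the
    protocol enables it.
    """
    spec = config.spec
    if pairlist is None:
        pairlist = WaterPairList(config, protocol.cutoff, protocol.skin)
    krf, crf = _rf_coefficients(protocol.cutoff, protocol.eps_rf)
    forces = np.zeros_like(config.positions)
    q = spec.site_charges
    qprod = np.ascontiguousarray(np.outer(q, q))
    prefilter = protocol.cutoff + 2.0 * SITE_OFFSET_MARGIN
    e_lj, e_coul, w_nb, r2min = _water_kernel(
        config.positions, config.box, pairlist.mol_i, pairlist.mol_j,
        spec.n_sites, qprod, spec.sigma_OO, spec.eps_OO,
        protocol.cutoff, prefilter, krf, crf, F_COULOMB, forces)
    if r2min < R_SINGULAR ** 2:
        raise SingularityError(
            f"pair distance {math.sqrt(r2min):.2e} nm below hard floor {R_SINGULAR} nm")
    e_bond, e_angle, w_bonded = _bonded_kernel(
        config.positions, config.n_molecules, spec.n_sites,
        spec.k_b, spec.r_OH0, spec.k_a, math.radians(spec.theta0), forces)
    if spec.n_sites == 4:
        a = spec.vsite_coeff
        f = forces.reshape(config.n_molecules, 4, 3)
        fm = f[:, 3].copy()
        f[:, 0] += (1.0 - 2.0 * a) * fm
        f[:, 1] += a * fm
        f[:, 2] += a * fm
        f[:, 3] = 0.0
    e_tail = p_tail = 0.0
    if protocol.tail_correction:
        e_tail, p_tail = _lj_tail(spec, config.n_molecules, config.volume,
                                  protocol.cutoff)
    ke = kinetic_energy(config)
    dof = n_dof(config)
    temperature = 2.0 * ke / (dof * KB) if dof > 0 else 0.0
    volume = config.volume
    pressure = PRESSURE_TO_BAR * (
        (2.0 * ke + w_nb + w_bonded) / (3.0 * volume) + p_tail)
    report = EnergyReport(
        bond=e_bond, angle=e_angle, lj=e_lj + e_tail, coulomb=e_coul,
        kinetic=ke, pressure=pressure, temperature=temperature)
    return forces, report


# ---------------------------------------------------------------------------
# naive Ewald (validation only, energy route for <= 64-molecule boxes)

def ewald_energy(config: Configuration, alpha: float | None = None,
                 kmax: int = 8) -> float:
    """Coulomb energy by direct Ewald summation, kJ/mol.

    O(N^2 + N k^3): intended as an electrostatics cross-check on tiny boxes,
    not for production.  Tinfoil (conducting) boundary; intramolecular pairs
    excluded in real space and corrected in reciprocal space.
    """
    if config.n_molecules > 64:
        raise ValueError("naive Ewald is restricted to <= 64-molecule validation boxes")
    if alpha is None:
        # real-space sum converged within the minimum image, reciprocal sum
        # converged within kmax shells
        alpha = 6.0 / float(np.min(config.box))
    q = config.charges
    pos = config.positions
    box = config.box
    n = len(q)
    # real space over all distinct-molecule pairs (minimum image)
    d = pos[:, None, :] - pos[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt((d ** 2).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    inter = config.molecule_index[iu] != config.molecule_index[ju]
    rr = r[iu, ju]
    qq = q[iu] * q[ju]
    from scipy.special import erfc, erf
    e_real = float((qq[inter] * erfc(alpha * rr[inter]) / rr[inter]).sum())
    # reciprocal space
    vol = config.volume
    e_rec = 0.0
    mlist = range(-kmax, kmax + 1)
    for mx in mlist:
        for my in mlist:
            for mz in mlist:
                if mx == 0 and my == 0 and mz == 0:
                    continue
                k = 2.0 * np.pi * np.array([mx / box[0], my / box[1], mz / box[2]])
                k2 = float(k @ k)
                rho = np.sum(q * np.exp(1j * (pos @ k)))
                e_rec += (4.0 * np.pi / (2.0 * vol)) * np.exp(-k2 / (4 * alpha ** 2)) \
                    / k2 * float(np.abs(rho) ** 2)
    # self term
    e_self = -alpha / math.sqrt(math.pi) * float((q ** 2).sum())
    # intramolecular exclusion correction (remove reciprocal-space interaction
    # of excluded pairs)
    intra = ~inter
    e_excl = -float((qq[intra] * erf(alpha * rr[intra]) / rr[intra]).sum())
    return F_COULOMB * (e_real + e_rec + e_self + e_excl)
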