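"""Flexible water force-field parameterizations.

Four nonpolarizable flexible models are built in: two literature parents
(FBA/eps, a three-site model, and TIP4P/eps_flex, a four-site model with a
massless charged M-site on the HOH bisector) and their two low-electrostatic
descendants (FBA_mem and T4F_mem) obtained by opening the equilibrium bend
angle until the liquid's static dielectric constant drops to ~20 at
physiological temperature, then retuning the LJ diameter to recover ambient
bulk density.  Charges are frozen in that procedure, so each descendant
differs from its parent only in ``theta0`` and ``sigma_OO``.

The functional form is OPLS-like with GROMACS harmonic conventions:
V_bond = 1/2 k_b (r - r_OH0)^2, V_angle = 1/2 k_a (theta - theta0)^2,
LJ acts between oxygens only, Coulomb between all charged sites of distinct
molecules.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .constants import ENM_TO_DEBYE, MASS_H, MASS_O

__all__ = [
    "WaterModelSpec",
    "MoleculeGeometry",
    "MODEL_NAMES",
    "get_model",
    "ideal_geometry",
    "molecular_dipole",
    "perturb_model",
    "registry_to_config",
    "registry_from_config",
]


@dataclass(frozen=True)
class WaterModelSpec:
    """One named flexible water parameterization.

    Parameters
    ----------
    name : str
        Registry label.
    n_sites : int
        3 (charges on O, H, H) or 4 (charges on H, H, M; LJ still on O).
    r_OH0 : float
        Equilibrium O-H bond length, nm.
    k_b : float
        Bond force constant, kJ mol^-1 nm^-2 (1/2 k convention).
    theta0 : float
        Equilibrium H-O-H angle, degrees.
    k_a : float
        Angle force constant, kJ mol^-1 rad^-2 (1/2 k convention).
    eps_OO, sigma_OO : float
        LJ well depth (kJ mol^-1) and diameter (nm) for the O-O pair.
    q_H : float
        Hydrogen partial charge, e.  The negative site carries -2 q_H.
    d_OM : float
        O-to-M distance along the HOH bisector at equilibrium geometry, nm.
        Zero for three-site models.
    """

    name: str
    n_sites: int
    r_OH0: float
    k_b: float
    theta0: float
    k_a: float
    eps_OO: float
    sigma_OO: float
    q_H: float
    d_OM: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites not in (3, 4):
            raise ValueError(f"n_sites must be 3 or 4, got {self.n_sites}")
        if (self.n_sites == 3) != (self.d_OM == 0.0):
            raise ValueError("three-site models require d_OM = 0, four-site d_OM > 0")
        if not 0.0 < self.theta0 < 180.0:
            raise ValueError("theta0 must lie in (0, 180) degrees")
        for field_name in ("r_OH0", "k_b", "k_a", "eps_OO", "sigma_OO"):
            if getattr(self, field_name) <= 0.0:
                raise ValueError(f"{field_name} must be positive")

    @property
    def q_neg(self) -> float:
        """Charge of the negative site (O for 3-site, M for 4-site), e."""
        return -2.0 * self.q_H

    @property
    def site_names(self) -> tuple[str, ...]:
        return ("OW", "HW1", "HW2") if self.n_sites == 3 else ("OW", "HW1", "HW2", "MW")

    @property
    def site_masses(self) -> np.ndarray:
        m = [MASS_O, MASS_H, MASS_H]
        if self.n_sites == 4:
            m.append(0.0)  # M-site is massless
        return np.array(m)

    @property
    def site_charges(self) -> np.ndarray:
        if self.n_sites == 3:
            return np.array([self.q_neg, self.q_H, self.q_H])
        return np.array([0.0, self.q_H, self.q_H, self.q_neg])

    @property
    def vsite_coeff(self) -> float:
        """Linear virtual-site coefficient a in r_M = r_O + a (r_H1 - r_O) + a (r_H2 - r_O).

        Chosen so the M-site sits at d_OM from O on the bisector when the
        molecule is at its equilibrium internal geometry.
        """
        if self.n_sites == 3:
            return 0.0
        half = math.radians(self.theta0) / 2.0
        return self.d_OM / (2.0 * self.r_OH0 * math.cos(half))


@dataclass(frozen=True)
class MoleculeGeometry:
    """Explicit site coordinates of a single molecule (nm) with charges and masses."""

    site_positions: np.ndarray
    site_charges: np.ndarray
    site_masses: np.ndarray


#: d_OM of the TIP4P/eps family the flexible four-site parent derives from, nm.
_D_OM_TIP4P_EPS = 0.0105

_BUILTINS = (
    WaterModelSpec("FBA/eps", 3, 0.10270, 300000.0, 114.70, 383.00, 0.792324, 0.31776, 0.4225),
    WaterModelSpec("FBA_mem", 3, 0.10270, 300000.0, 132.50, 383.00, 0.792324, 0.31616, 0.4225),
    WaterModelSpec("TIP4P/eps_flex", 4, 0.09300, 157000.0, 111.50, 212.00, 0.794032, 0.31734,
                   0.5100, _D_OM_TIP4P_EPS),
    WaterModelSpec("T4F_mem", 4, 0.09300, 157000.0, 129.0, 212.00, 0.794032, 0.31498,
                   0.5100, _D_OM_TIP4P_EPS),
)

MODEL_NAMES: tuple[str, ...] = tuple(s.name for s in _BUILTINS)


def _alias_key(name: str) -> str:
    key = name.strip().lower()
    for uni, ascii_ in (("ε", "eps"), ("ϵ", "eps"), ("ε", "eps")):
        key = key.replace(uni, ascii_)
    return key.replace("-", "_")


_REGISTRY: dict[str, WaterModelSpec] = {}
for _s in _BUILTINS:
    _REGISTRY[_alias_key(_s.name)] = _s
# historical / alternate spellings
_REGISTRY[_alias_key("TIP4P_mem")] = _REGISTRY[_alias_key("T4F_mem")]
_REGISTRY[_alias_key("FBA_eps")] = _REGISTRY[_alias_key("FBA/eps")]
_REGISTRY[_alias_key("TIP4P_eps_flex")] = _REGISTRY[_alias_key("TIP4P/eps_flex")]


def get_model(name: str) -> WaterModelSpec:
    """Look up a built-in water model by name (case-insensitive, alias-tolerant)."""
    try:
        return _REGISTRY[_alias_key(name)]
    except KeyError:
        raise KeyError(
            f"unknown water model {name!r}; valid models: {', '.join(MODEL_NAMES)}"
        ) from None


def ideal_geometry(spec: WaterModelSpec) -> MoleculeGeometry:
    """Build one molecule at its equilibrium internal coordinates.

    Convention: O at the origin, the HOH bisector along +z (hydrogens at
    positive z), molecule in the x-z plane.
    """
    half = math.radians(spec.theta0) / 2.0
    r = spec.r_OH0
    o = np.zeros(3)
    h1 = np.array([r * math.sin(half), 0.0, r * math.cos(half)])
    h2 = np.array([-r * math.sin(half), 0.0, r * math.cos(half)])
    pos = [o, h1, h2]
    if spec.n_sites == 4:
        pos.append(np.array([0.0, 0.0, spec.d_OM]))
    return MoleculeGeometry(
        site_positions=np.array(pos),
        site_charges=spec.site_charges,
        site_masses=spec.site_masses,
    )


def molecular_dipole(geometry: MoleculeGeometry) -> tuple[float, np.ndarray]:
    """Dipole of a neutral site set: magnitude in Debye and vector in e*nm.

    Requires neutrality; for a charged set the dipole depends on the origin
    and is refused.
    """
    q = np.asarray(geometry.site_charges, dtype=float)
    if abs(q.sum()) > 1e-10:
        raise ValueError("site set is not neutral; dipole would be origin-dependent")
    mu_vec = q @ np.asarray(geometry.site_positions, dtype=float)
    return float(np.linalg.norm(mu_vec)) * ENM_TO_DEBYE, mu_vec


#: fields the calibration stages may vary, with validity bounds
_PERTURBABLE: dict[str, tuple[float, float]] = {
    "theta0": (60.0, 179.0),
    "sigma_OO": (0.2, 0.5),
    "eps_OO": (0.05, 5.0),
}


def perturb_model(spec: WaterModelSpec, field: str, value: float) -> WaterModelSpec:
    """Return a copy of ``spec`` with one tunable field changed.

    Only ``theta0``, ``sigma_OO`` and ``eps_OO`` may be varied: the
    reparameterization procedure freezes charges and bonded force constants
    by construction.
    """
    if field not in _PERTURBABLE:
        raise ValueError(
            f"field {field!r} is frozen by construction; "
            f"tunable fields: {sorted(_PERTURBABLE)}"
        )
    lo, hi = _PERTURBABLE[field]
    if not lo <= value <= hi:
        raise ValueError(f"{field}={value} outside validity bounds [{lo}, {hi}]")
    return replace(spec, **{field: value})


# ---------------------------------------------------------------------------
# plain key-value (INI) registry serialization

_CONFIG_FIELDS = ("n_sites", "r_OH0", "k_b", "theta0", "k_a", "eps_OO",
                  "sigma_OO", "q_H", "d_OM")


def registry_to_config(specs: Iterable[WaterModelSpec], path) -> None:
    """Write model specs to an INI file, one section per model."""
    cp = configparser.ConfigParser()
    for s in specs:
        cp[s.name] = {f: repr(getattr(s, f)) for f in _CONFIG_FIELDS}
    with open(path, "w") as fh:
        cp.write(fh)


def registry_from_config(path) -> dict[str, WaterModelSpec]:
    """Read model specs from an INI file written by :func:`registry_to_config`."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    out = {}
    for name in cp.sections():
        sec = cp[name]
        out[name] = WaterModelSpec(
            name=name,
            n_sites=sec.getint("n_sites"),
            r_OH0=sec.getfloat("r_OH0"),
            k_b=sec.getfloat("k_b"),
            theta0=sec.getfloat("theta0"),
            k_a=sec.getfloat("k_a"),
            eps_OO=sec.getfloat("eps_OO"),
            sigma_OO=sec.getfloat("sigma_OO"),
            q_H=sec.getfloat("q_H"),
            d_OM=sec.getfloat("d_OM", fallback=0.0),
        )
    return out
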