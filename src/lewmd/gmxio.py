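"""GROMACS-format interchange: ITP/TOP topologies and GRO coordinates.

Only the dialect this package emits is guaranteed parseable; anything else
(dihedrals, unknown function types) raises an explicit unsupported-feature
error rather than guessing.  Atom naming follows the interoperable water
convention: residue SOL, atoms OW/HW1/HW2/MW.
"""

from __future__ import annotations

import math
import re

import numpy as np

from .constants import MASS_H, MASS_O
from .models import WaterModelSpec
from .system import Configuration

__all__ = ["write_itp", "parse_itp", "write_gro", "read_gro", "write_top"]


def _type_suffix(spec: WaterModelSpec) -> str:
    return re.sub(r"[^A-Za-z0-9]", "", spec.name).upper()


def write_itp(spec: WaterModelSpec, path) -> None:
    """Write a flexible-water molecule topology (atomtypes + moleculetype).

    Bond/angle entries use GROMACS function type 1 (harmonic, 1/2 k
    convention); four-site models emit a ``virtual_sites3`` funct-1 line for
    the M-site plus full intramolecular exclusions.
    """
    sfx = _type_suffix(spec)
    lines = [
        f"; flexible water model {spec.name}",
        "",
        "[ atomtypes ]",
        ";name   at.num      mass    charge  ptype      sigma        epsilon",
    ]
    q_O = spec.site_charges[0]
    lines.append(f"OW_{sfx:<10s} 8  {MASS_O:10.4f} {q_O:9.4f}  A  "
                 f"{spec.sigma_OO:.8g}  {spec.eps_OO:.8g}")
    lines.append(f"HW_{sfx:<10s} 1  {MASS_H:10.4f} {spec.q_H:9.4f}  A  0  0")
    if spec.n_sites == 4:
        lines.append(f"MW_{sfx:<10s} 0  {0.0:10.4f} {spec.q_neg:9.4f}  D  0  0")
    lines += [
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        "SOL  2",
        "",
        "[ atoms ]",
        ";  nr  type       resnr  residue  atom  cgnr  charge      mass",
        f"    1  OW_{sfx}   1      SOL      OW    1  {q_O:9.5f}  {MASS_O:9.4f}",
        f"    2  HW_{sfx}   1      SOL      HW1   1  {spec.q_H:9.5f}  {MASS_H:9.4f}",
        f"    3  HW_{sfx}   1      SOL      HW2   1  {spec.q_H:9.5f}  {MASS_H:9.4f}",
    ]
    if spec.n_sites == 4:
        lines.append(f"    4  MW_{sfx}   1      SOL      MW    1  "
                     f"{spec.q_neg:9.5f}  {0.0:9.4f}")
    lines += [
        "",
        "[ bonds ]",
        "; i  j  funct       b0            kb",
        f"  1  2  1  {spec.r_OH0:.8g}  {spec.k_b:.8g}",
        f"  1  3  1  {spec.r_OH0:.8g}  {spec.k_b:.8g}",
        "",
        "[ angles ]",
        "; i  j  k  funct     theta0          ktheta",
        f"  2  1  3  1  {spec.theta0:.8g}  {spec.k_a:.8g}",
    ]
    if spec.n_sites == 4:
        a = spec.vsite_coeff
        lines += [
            "",
            f"; d_OM = {spec.d_OM:.8g} nm (linear construction)",
            "[ virtual_sites3 ]",
            "; site  from       funct      a          b",
            f"  4  1  2  3  1  {a!r}  {a!r}",
            "",
            "[ exclusions ]",
            "1 2 3 4",
            "2 1 3 4",
            "3 1 2 4",
            "4 1 2 3",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class UnsupportedTopologyError(ValueError):
    """Topology uses a feature outside the supported dialect subset."""


def parse_itp(path) -> WaterModelSpec:
    """Read a water model back from an ITP file written by :func:`write_itp`.

    Tolerant of comments and whitespace; anything structurally different
    (dihedrals, non-harmonic function types) errors with the line number.
    """
    sections: dict[str, list[tuple[int, str]]] = {}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split(";")[0].strip()
            if not line:
                continue
            m = re.match(r"\[\s*(\S+)\s*\]", line)
            if m:
                current = m.group(1).lower()
                if current in ("dihedrals", "pairs", "settles", "constraints"):
                    raise UnsupportedTopologyError(
                        f"line {lineno}: section [{current}] is not supported")
                sections.setdefault(current, [])
                continue
            if current is None:
                raise UnsupportedTopologyError(f"line {lineno}: data before a section")
            sections[current].append((lineno, line))

    def require(name: str):
        if name not in sections:
            raise UnsupportedTopologyError(f"missing required section [{name}]")
        return sections[name]

    sigma = eps = None
    for lineno, line in require("atomtypes"):
        f = line.split()
        if f[0].startswith("OW"):
            sigma, eps = float(f[5]), float(f[6])
    if sigma is None:
        raise UnsupportedTopologyError("no OW atomtype found")
    atoms = require("atoms")
    n_sites = len(atoms)
    if n_sites not in (3, 4):
        raise UnsupportedTopologyError(f"{n_sites} atoms; expected 3 or 4")
    q_H = float(atoms[1][1].split()[6])
    bonds = require("bonds")
    lineno, first_bond = bonds[0]
    bf = first_bond.split()
    if bf[2] != "1":
        raise UnsupportedTopologyError(f"line {lineno}: bond funct {bf[2]} unsupported")
    r_OH0, k_b = float(bf[3]), float(bf[4])
    lineno, first_angle = require("angles")[0]
    af = first_angle.split()
    if af[3] != "1":
        raise UnsupportedTopologyError(f"line {lineno}: angle funct {af[3]} unsupported")
    theta0, k_a = float(af[4]), float(af[5])
    d_OM = 0.0
    if n_sites == 4:
        lineno, vs = require("virtual_sites3")[0]
        vf = vs.split()
        if vf[4] != "1":
            raise UnsupportedTopologyError(
                f"line {lineno}: virtual-site funct {vf[4]} unsupported")
        a = float(vf[5])
        d_OM = a * 2.0 * r_OH0 * math.cos(math.radians(theta0) / 2.0)
    name = "parsed"
    with open(path) as fh:
        m = re.search(r"flexible water model (\S+)", fh.read())
        if m:
            name = m.group(1)
    return WaterModelSpec(name=name, n_sites=n_sites, r_OH0=r_OH0, k_b=k_b,
                          theta0=theta0, k_a=k_a, eps_OO=eps, sigma_OO=sigma,
                          q_H=q_H, d_OM=d_OM)


def write_top(spec: WaterModelSpec, n_molecules: int, itp_name: str, path) -> None:
    """Minimal system .top including the molecule ITP."""
    text = (
        "[ defaults ]\n; nbfunc  comb-rule  gen-pairs\n  1  3  no\n\n"
        f'#include "{itp_name}"\n\n'
        "[ system ]\n"
        f"{spec.name} water\n\n"
        "[ molecules ]\n"
        f"SOL {n_molecules}\n"
    )
    with open(path, "w") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# GRO coordinates

def write_gro(config: Configuration, path, title: str | None = None,
              velocities: bool = True) -> None:
    """Fixed-column GRO writer (positions %8.3f nm, velocities %8.4f nm/ps).

    Molecules are wrapped by center of mass into [0, box) before writing.
    """
    cfg = config.wrapped()
    spec = cfg.spec
    names = spec.site_names
    lines = [title or f"{spec.name} water, {cfg.n_molecules} molecules",
             f"{cfg.n_sites:5d}"]
    for i in range(cfg.n_sites):
        mol = i // spec.n_sites + 1
        name = names[i % spec.n_sites]
        x, y, z = cfg.positions[i]
        rec = (f"{mol % 100000:5d}{'SOL':<5s}{name:>5s}{(i + 1) % 100000:5d}"
               f"{x:8.3f}{y:8.3f}{z:8.3f}")
        if velocities:
            vx, vy, vz = cfg.velocities[i]
            rec += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
        lines.append(rec)
    bx, by, bz = cfg.box
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gro(path, spec: WaterModelSpec) -> tuple[Configuration, bool]:
    """Read a GRO file into a Configuration bound to ``spec``.

    Returns ``(configuration, had_velocities)``; missing velocities are
    zero-filled and flagged.  Malformed fixed columns raise with the line
    number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ValueError("GRO file too short")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as err:
        raise ValueError(f"line 2: bad atom count: {err}") from None
    if n_atoms % spec.n_sites:
        raise ValueError(f"{n_atoms} atoms is not a multiple of "
                         f"{spec.n_sites} sites per molecule")
    pos = np.empty((n_atoms, 3))
    vel = np.zeros((n_atoms, 3))
    had_velocities = False
    for k in range(n_atoms):
        line = lines[2 + k]
        lineno = 3 + k
        try:
            pos[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            if len(line.rstrip()) >= 68:
                vel[k] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
                had_velocities = True
        except (ValueError, IndexError) as err:
            raise ValueError(f"line {lineno}: malformed fixed columns: {err}") from None
    box_fields = lines[2 + n_atoms].split()
    if len(box_fields) < 3:
        raise ValueError(f"line {3 + n_atoms}: malformed box line")
    box = np.array([float(v) for v in box_fields[:3]])
    return Configuration(pos, vel, box, spec), had_velocities


# ---------------------------------------------------------------------------
# XVG-style observable tables

def write_xvg(path, columns: dict[str, np.ndarray], title: str = "",
              xaxis: str = "", yaxis: str = "") -> None:
    """Whitespace-column text table with XVG-style @ headers."""
    names = list(columns)
    arrays = [np.asarray(columns[n], float) for n in names]
    with open(path, "w") as fh:
        fh.write(f"@    title \"{title}\"\n")
        fh.write(f"@    xaxis  label \"{xaxis}\"\n")
        fh.write(f"@    yaxis  label \"{yaxis}\"\n")
        for idx, n in enumerate(names[1:]):
            fh.write(f"@ s{idx} legend \"{n}\"\n")
        for row in zip(*arrays):
            fh.write("  ".join(f"{v:14.6g}" for v in row) + "\n")
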