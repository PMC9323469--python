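"""CHARMM-format export: PSF (X-PLOR extended), RTF, and PRM writers.

Only export is supported; reading these dialects back is out of scope.  The
internal LJ convention (epsilon >= 0, sigma) is converted at this boundary to
CHARMM's (-epsilon, Rmin/2) with Rmin = 2^(1/6) * sigma.  Atom indices are
converted from the internal 0-based convention to CHARMM's 1-based one here
and nowhere else.
"""

from __future__ import annotations

import os
from typing import Union

from .molecular_model import MolecularSystem

__all__ = ["write_psf", "write_rtf", "write_prm"]

_VERSION_TAG = "ccsai v0.1.0"

_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "F": 18.998,
    "Cl": 35.45,
    "AR": 39.948,
    "Ar": 39.948,
    "X": 12.011,  # junction particle: carries its template atom's mass
}

_RMIN_OVER_SIGMA = 2.0 ** (1.0 / 6.0)


def _mass(element: str) -> float:
    try:
        return _MASSES[element]
    except KeyError:
        raise ValueError(f"no mass tabulated for element {element!r}") from None


def _type_name(system: MolecularSystem, i: int) -> str:
    # unique per-atom type names keep the PRM unambiguous for every state
    return f"{system.atoms[i].element.upper()}{i}"


def write_psf(system: MolecularSystem, path: Union[str, os.PathLike],
              segid: str = "SOLU") -> None:
    """Write an X-PLOR extended (EXT) PSF with explicit per-state charges."""
    n = system.n_atoms
    lines = ["PSF EXT XPLOR", ""]
    lines.append(f"{2:10d} !NTITLE")
    lines.append(f"* generated by {_VERSION_TAG}")
    lines.append(f"* system {system.label}")
    lines.append("")
    lines.append(f"{n:10d} !NATOM")
    for a in system.atoms:
        lines.append(
            f"{a.index + 1:10d} {segid:<8s} {1:<8d} {'MOL':<8s} "
            f"{a.name:<8s} {_type_name(system, a.index):<8s} "
            f"{a.charge:14.6f}{_mass(a.element):14.6f}{0:12d}"
        )
    bonds = sorted(system.bonds)
    lines.append("")
    lines.append(f"{len(bonds):10d} !NBOND: bonds")
    flat = [x + 1 for pair in bonds for x in pair]
    for k in range(0, len(flat), 8):
        lines.append("".join(f"{x:10d}" for x in flat[k:k + 8]))
    angles = [t for t in system.terms if t.kind == "angle"]
    lines.append("")
    lines.append(f"{len(angles):10d} !NTHETA: angles")
    flat = [x + 1 for t in angles for x in t.atoms]
    for k in range(0, len(flat), 9):
        lines.append("".join(f"{x:10d}" for x in flat[k:k + 9]))
    dihedrals = [t for t in system.terms if t.kind == "dihedral"]
    lines.append("")
    lines.append(f"{len(dihedrals):10d} !NPHI: dihedrals")
    flat = [x + 1 for t in dihedrals for x in t.atoms]
    for k in range(0, len(flat), 8):
        lines.append("".join(f"{x:10d}" for x in flat[k:k + 8]))
    lines.append("")
    lines.append(f"{0:10d} !NIMPHI: impropers")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_rtf(system: MolecularSystem, path: Union[str, os.PathLike]) -> None:
    lines = [f"* Topology generated by {_VERSION_TAG}", "*", "36  1", ""]
    for a in system.atoms:
        lines.append(
            f"MASS {a.index + 1:5d} {_type_name(system, a.index):<8s}"
            f"{_mass(a.element):10.5f} {a.element}"
        )
    total = sum(a.charge for a in system.atoms)
    lines.append("")
    lines.append(f"RESI MOL {total:10.5f}")
    lines.append("GROUP")
    for a in system.atoms:
        lines.append(
            f"ATOM {a.name:<8s} {_type_name(system, a.index):<8s}"
            f"{a.charge:10.5f}"
        )
    for i, j in sorted(system.bonds):
        lines.append(f"BOND {system.atoms[i].name:<8s} {system.atoms[j].name:<8s}")
    lines.append("")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_prm(system: MolecularSystem, path: Union[str, os.PathLike]) -> None:
    """Parameter file: bonded terms plus NONBONDED with (-eps, Rmin/2)."""
    tn = lambda i: _type_name(system, i)  # noqa: E731
    lines = [f"* Parameters generated by {_VERSION_TAG}", "*", ""]
    lines.append("BONDS")
    for t in system.terms:
        if t.kind == "bond":
            i, j = t.atoms
            lines.append(
                f"{tn(i):<8s} {tn(j):<8s} {t.force_constant:10.4f}"
                f"{t.equilibrium:10.4f}"
            )
    lines.append("")
    lines.append("ANGLES")
    for t in system.terms:
        if t.kind == "angle":
            i, j, k = t.atoms
            lines.append(
                f"{tn(i):<8s} {tn(j):<8s} {tn(k):<8s} "
                f"{t.force_constant:10.4f}{t.equilibrium:10.4f}"
            )
    lines.append("")
    lines.append("DIHEDRALS")
    for t in system.terms:
        if t.kind == "dihedral":
            i, j, k, l = t.atoms
            lines.append(
                f"{tn(i):<8s} {tn(j):<8s} {tn(k):<8s} {tn(l):<8s} "
                f"{t.force_constant:10.4f}{t.multiplicity:4d}"
                f"{t.equilibrium:10.2f}"
            )
    lines.append("")
    lines.append("NONBONDED nbxmod  5 atom cdiel fshift vatom vdistance vfswitch -")
    lines.append("cutnb 14.0 ctofnb 12.0 ctonnb 10.0 eps 1.0 e14fac 1.0 wmin 1.5")
    for a in system.atoms:
        rmin_half = 0.5 * _RMIN_OVER_SIGMA * a.lj_sigma
        lines.append(
            f"{tn(a.index):<8s}{0.0:10.4f}{-a.lj_epsilon:12.6f}"
            f"{rmin_half:12.6f}"
        )
    lines.append("")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
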