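"""Portable state file: the self-describing text format shared by all modules.

One record per atom (index, element, name, charge, epsilon, sigma, dummy
flag), then bonds, then bonded terms with explicit units, then an optional
coordinate block.  Floats are written with ``repr`` so a write/read round
trip reproduces every value bit-exactly.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np

from .molecular_model import (
    AtomRecord,
    BondedTerm,
    MolecularSystem,
    ValidationError,
    build_system,
)

__all__ = ["dumps_system", "loads_system", "write_portable", "read_portable"]

_MAGIC = "# ccsai portable state v1"


def dumps_system(system: MolecularSystem) -> str:
    lines = [_MAGIC]
    lines.append(f"label {system.label}")
    if system.trap_k is not None:
        lines.append(f"trap_k {system.trap_k!r}")
    lines.append(f"atoms {system.n_atoms}")
    lines.append("# index element name charge[e] epsilon[kcal/mol] sigma[A] dummy")
    for a in system.atoms:
        lines.append(
            f"{a.index} {a.element} {a.name} {a.charge!r} "
            f"{a.lj_epsilon!r} {a.lj_sigma!r} {int(a.is_dummy)}"
        )
    bonds = sorted(system.bonds)
    lines.append(f"bonds {len(bonds)}")
    for i, j in bonds:
        lines.append(f"{i} {j}")
    lines.append(f"terms {len(system.terms)}")
    lines.append(
        "# kind atoms... force_constant equilibrium[A|deg] [multiplicity]"
    )
    for t in system.terms:
        parts = [t.kind, *map(str, t.atoms), repr(t.force_constant), repr(t.equilibrium)]
        if t.kind == "dihedral":
            parts.append(str(t.multiplicity))
        lines.append(" ".join(parts))
    if system.coordinates is not None:
        lines.append(f"coordinates {system.n_atoms}")
        for xyz in system.coordinates:
            lines.append(f"{float(xyz[0])!r} {float(xyz[1])!r} {float(xyz[2])!r}")
    return "\n".join(lines) + "\n"


def loads_system(text: str) -> MolecularSystem:
    lines = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not (ln.strip().startswith("#") and ln.strip() != _MAGIC)
    ]
    if not lines or lines[0] != _MAGIC:
        raise ValidationError("not a ccsai portable state file")
    pos = 1

    def expect(keyword: str) -> list:
        nonlocal pos
        parts = lines[pos].split()
        if parts[0] != keyword:
            raise ValidationError(
                f"expected {keyword!r} block, found {lines[pos]!r}"
            )
        pos += 1
        return parts

    head = expect("label")
    label = " ".join(head[1:]) if len(head) > 1 else ""

    trap_k = None
    if lines[pos].split()[0] == "trap_k":
        trap_k = float(lines[pos].split()[1])
        pos += 1

    n_atoms = int(expect("atoms")[1])
    atoms = []
    for _ in range(n_atoms):
        idx, element, name, q, eps, sig, dummy = lines[pos].split()
        pos += 1
        atom = AtomRecord(
            index=int(idx),
            element=element,
            name=name,
            charge=float(q),
            lj_epsilon=float(eps),
            lj_sigma=float(sig),
        )
        if atom.is_dummy != bool(int(dummy)):
            raise ValidationError(
                f"atom {idx}: dummy flag inconsistent with charge/epsilon"
            )
        atoms.append(atom)

    n_bonds = int(expect("bonds")[1])
    bonds = []
    for _ in range(n_bonds):
        i, j = lines[pos].split()
        pos += 1
        bonds.append((int(i), int(j)))

    n_terms = int(expect("terms")[1])
    terms = []
    for _ in range(n_terms):
        parts = lines[pos].split()
        pos += 1
        kind = parts[0]
        if kind == "bond":
            terms.append(BondedTerm("bond", (int(parts[1]), int(parts[2])),
                                    float(parts[3]), float(parts[4])))
        elif kind == "angle":
            terms.append(BondedTerm("angle",
                                    (int(parts[1]), int(parts[2]), int(parts[3])),
                                    float(parts[4]), float(parts[5])))
        elif kind == "dihedral":
            terms.append(BondedTerm(
                "dihedral",
                (int(parts[1]), int(parts[2]), int(parts[3]), int(parts[4])),
                float(parts[5]), float(parts[6]), int(parts[7])))
        else:
            raise ValidationError(f"unknown term kind {kind!r}")

    coordinates = None
    if pos < len(lines) and lines[pos].split()[0] == "coordinates":
        n_coord = int(expect("coordinates")[1])
        rows = []
        for _ in range(n_coord):
            rows.append([float(x) for x in lines[pos].split()])
            pos += 1
        coordinates = np.array(rows, dtype=float)

    return build_system(atoms, bonds, terms, label=label,
                        coordinates=coordinates, trap_k=trap_k)


def write_portable(system: MolecularSystem, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_system(system))


def read_portable(path: Union[str, os.PathLike]) -> MolecularSystem:
    with open(path) as fh:
        return loads_system(fh.read())
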