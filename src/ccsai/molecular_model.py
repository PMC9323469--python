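"""Data model for parameterized molecules.

A :class:`MolecularSystem` holds everything the rest of the package needs to
know about one molecule (or one alchemical intermediate): atoms with partial
charges and Lennard-Jones parameters, the covalent bond graph, and the bonded
energy terms (harmonic bonds and angles, periodic dihedrals).

Conventions
-----------
* LJ parameters are stored as ``(epsilon >= 0, sigma)`` with epsilon in
  kcal/mol and sigma in Angstrom.  CHARMM files use ``(-epsilon, Rmin/2)``
  with ``Rmin = 2**(1/6) * sigma``; the conversion lives in the writers
  (:mod:`ccsai.charmm`), never here.
* Atom indices are 0-based everywhere inside the package.
* A *dummy atom* has exactly zero charge and zero LJ well depth; it does not
  interact through nonbonded forces at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AtomRecord",
    "BondedTerm",
    "MolecularSystem",
    "ValidationError",
    "build_system",
    "net_charge",
    "rings",
]


class ValidationError(ValueError):
    """A record violates the data-model invariants."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, partial charge, and LJ parameters.

    ``is_dummy`` is derived, never set independently: an atom is a dummy iff
    both its charge and its LJ well depth are exactly zero.
    """

    index: int
    element: str
    name: str
    charge: float
    lj_epsilon: float
    lj_sigma: float
    is_dummy: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValidationError(f"atom {self.name}: negative index {self.index}")
        if self.lj_epsilon < 0:
            raise ValidationError(
                f"atom {self.index} ({self.name}): lj_epsilon must be a "
                f"non-negative magnitude, got {self.lj_epsilon}"
            )
        if self.lj_sigma < 0:
            raise ValidationError(
                f"atom {self.index} ({self.name}): lj_sigma must be >= 0, "
                f"got {self.lj_sigma}"
            )
        dummy = self.charge == 0.0 and self.lj_epsilon == 0.0
        object.__setattr__(self, "is_dummy", dummy)


_TERM_ARITY = {"bond": 2, "angle": 3, "dihedral": 4}


@dataclass(frozen=True)
class BondedTerm:
    """A bonded energy term.

    kind          one of ``bond`` / ``angle`` / ``dihedral``
    atoms         tuple of 2/3/4 distinct atom indices
    force_constant  kcal/mol/A^2 (bond), kcal/mol/rad^2 (angle),
                    kcal/mol (dihedral amplitude)
    equilibrium   A (bond) or degrees (angle: theta0, dihedral: phase delta)
    multiplicity  dihedral periodicity n >= 1; None for bonds/angles
    """

    kind: str
    atoms: tuple
    force_constant: float
    equilibrium: float
    multiplicity: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in _TERM_ARITY:
            raise ValidationError(f"unknown bonded term kind {self.kind!r}")
        atoms = tuple(int(a) for a in self.atoms)
        object.__setattr__(self, "atoms", atoms)
        if len(atoms) != _TERM_ARITY[self.kind]:
            raise ValidationError(
                f"{self.kind} term needs {_TERM_ARITY[self.kind]} atoms, "
                f"got {atoms}"
            )
        if len(set(atoms)) != len(atoms):
            raise ValidationError(f"{self.kind} term has repeated atoms {atoms}")
        if self.kind == "dihedral":
            if self.multiplicity is None or self.multiplicity < 1:
                raise ValidationError(
                    f"dihedral {atoms}: multiplicity must be >= 1, "
                    f"got {self.multiplicity}"
                )
        elif self.multiplicity is not None:
            raise ValidationError(
                f"{self.kind} term {atoms} must not carry a multiplicity"
            )

    def canonical_atoms(self) -> tuple:
        """Direction-independent atom tuple (for term lookup)."""
        a = self.atoms
        return min(a, a[::-1])


@dataclass
class MolecularSystem:
    """A parameterized molecule or alchemical intermediate.

    ``bonds`` is stored as a frozenset of ``(i, j)`` pairs with ``i < j``.
    ``coordinates`` (optional, Angstrom, shape ``(n_atoms, 3)``) carry a
    reference geometry used to seed sampling.  ``trap_k`` (optional,
    kcal/mol/A^2) is the force constant of an isotropic harmonic confining
    trap centred at the origin acting on every atom; it models a finite
    cluster "solution" environment for the toy engine.
    """

    atoms: list
    bonds: frozenset
    terms: list
    label: str = ""
    coordinates: Optional[np.ndarray] = None
    trap_k: Optional[float] = None

    # -- queries ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def is_connected(self) -> bool:
        return self.n_atoms > 0 and nx.is_connected(self.graph())

    def neighbors(self, i: int) -> frozenset:
        return frozenset(
            b if a == i else a for a, b in self.bonds if i in (a, b)
        )

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def with_atoms(self, new_atoms: Sequence[AtomRecord]) -> "MolecularSystem":
        coords = None if self.coordinates is None else self.coordinates.copy()
        return MolecularSystem(
            atoms=list(new_atoms),
            bonds=self.bonds,
            terms=list(self.terms),
            label=self.label,
            coordinates=coords,
            trap_k=self.trap_k,
        )

    def with_terms(self, new_terms: Sequence[BondedTerm]) -> "MolecularSystem":
        coords = None if self.coordinates is None else self.coordinates.copy()
        return MolecularSystem(
            atoms=list(self.atoms),
            bonds=self.bonds,
            terms=list(new_terms),
            label=self.label,
            coordinates=coords,
            trap_k=self.trap_k,
        )


def build_system(
    atoms: Sequence[AtomRecord],
    bonds: Iterable,
    terms: Sequence[BondedTerm] = (),
    label: str = "",
    coordinates: Optional[np.ndarray] = None,
    trap_k: Optional[float] = None,
) -> MolecularSystem:
    """Validate records and assemble a :class:`MolecularSystem`.

    Raises :class:`ValidationError` naming the offending record on
    out-of-range indices, self-bonds, duplicate bonds, bond terms without a
    matching bond, or a non-integer total charge.
    """
    atoms = list(atoms)
    n = len(atoms)
    for pos, a in enumerate(atoms):
        if a.index != pos:
            raise ValidationError(
                f"atom at position {pos} carries index {a.index}; atoms must "
                "be listed in index order"
            )

    canon = set()
    for pair in bonds:
        i, j = (int(pair[0]), int(pair[1]))
        if i == j:
            raise ValidationError(f"self-bond ({i}, {j})")
        if not (0 <= i < n and 0 <= j < n):
            raise ValidationError(f"bond ({i}, {j}) references a missing atom")
        key = (min(i, j), max(i, j))
        if key in canon:
            raise ValidationError(f"duplicate bond {key}")
        canon.add(key)
    bond_set = frozenset(canon)

    for t in terms:
        for i in t.atoms:
            if not (0 <= i < n):
                raise ValidationError(
                    f"{t.kind} term {t.atoms} references a missing atom {i}"
                )
        if t.kind == "bond":
            key = (min(t.atoms), max(t.atoms))
            if key not in bond_set:
                raise ValidationError(
                    f"bond term {t.atoms} has no corresponding bond entry"
                )

    total = math.fsum(a.charge for a in atoms)
    if abs(total - round(total)) > 1e-9:
        raise ValidationError(
            f"system {label!r}: total charge {total} is not an integer"
        )

    if coordinates is not None:
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (n, 3):
            raise ValidationError(
                f"coordinates shape {coordinates.shape} != ({n}, 3)"
            )

    return MolecularSystem(
        atoms=atoms,
        bonds=bond_set,
        terms=list(terms),
        label=label,
        coordinates=coordinates,
        trap_k=trap_k,
    )


def net_charge(system: MolecularSystem, subset: Optional[Iterable] = None) -> float:
    """Exact sum of partial charges over ``subset`` (default: all atoms)."""
    if subset is None:
        idx = range(system.n_atoms)
    else:
        idx = sorted(set(int(i) for i in subset))
        for i in idx:
            if not (0 <= i < system.n_atoms):
                raise ValidationError(f"net_charge: unknown atom index {i}")
    return math.fsum(system.atoms[i].charge for i in idx)


def rings(system: MolecularSystem) -> tuple:
    """Smallest set of smallest rings of the bond graph.

    Returns a tuple of frozensets of atom indices, ordered by
    ``(ring size, smallest member index)`` for reproducibility.
    """
    basis = nx.minimum_cycle_basis(system.graph())
    out = [frozenset(cycle) for cycle in basis]
    out.sort(key=lambda r: (len(r), min(r)))
    return tuple(out)
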