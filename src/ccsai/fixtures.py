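"""Deterministic toy fixtures: small parameterized molecules and clusters.

The fixtures are *analogues* of common small solutes (methane-, ethane-,
methanol-, toluene-, cyclopentane-like graphs and two cyclopentyl-aryl
regioisomers) with invented but physically plausible force-field
parameters.  Charges are constructed so that every molecule is neutral and
so that molecules sharing a common core end up with identical core
parameters after mutation — the precondition for dummy-atom cancellation in
double free energy differences.

``lj_bath`` embeds a solute among neutral LJ particles held together by a
harmonic confining trap: a desk-scale stand-in for a solvent environment
(documented loudly as a scale substitution — it is not water).
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np

from .molecular_model import (
    AtomRecord,
    BondedTerm,
    MolecularSystem,
    ValidationError,
    build_system,
)
from .sampling import AnalyticSystem

__all__ = [
    "FIXTURE_NAMES",
    "make_fixture",
    "make_analytic",
    "bath_coordinates",
    "with_bath",
]

# LJ parameters (epsilon kcal/mol, sigma A) per atom class
_LJ = {
    "CT": (0.078, 3.634),   # aliphatic carbon
    "HA": (0.024, 2.352),   # aliphatic hydrogen
    "CA": (0.070, 3.550),   # aromatic carbon
    "HP": (0.030, 2.420),   # aromatic hydrogen
    "OH": (0.1521, 3.154),  # hydroxyl oxygen
    "HO": (0.046, 0.449),   # hydroxyl hydrogen
    "OA": (0.120, 2.940),   # aromatic ether oxygen
    "AR": (0.100, 3.000),   # neutral bath particle
}

_BONDS = {
    ("CT", "CT"): (222.5, 1.528),
    ("CT", "HA"): (322.0, 1.111),
    ("CT", "OH"): (360.0, 1.415),
    ("HO", "OH"): (545.0, 0.960),
    ("CA", "CA"): (305.0, 1.375),
    ("CA", "HP"): (340.0, 1.080),
    ("CA", "CT"): (230.0, 1.490),
    ("CA", "OA"): (350.0, 1.370),
}

_ANGLES = {
    ("HA", "CT", "HA"): (35.5, 109.47),
    ("CT", "CT", "HA"): (34.6, 110.10),
    ("CT", "CT", "CT"): (58.35, 113.50),
    ("HA", "CT", "OH"): (45.9, 108.90),
    ("CT", "OH", "HO"): (57.5, 106.00),
    ("CT", "CT", "OH"): (75.7, 110.10),
    ("CA", "CA", "CA"): (40.0, 120.00),
    ("CA", "CA", "HP"): (30.0, 120.00),
    ("CA", "CA", "CT"): (45.8, 120.00),
    ("CA", "CT", "HA"): (34.6, 110.10),
    ("CA", "CT", "CT"): (43.0, 112.00),
    ("CA", "OA", "CA"): (60.0, 106.00),
    ("CA", "CA", "OA"): (50.0, 110.00),
    ("HP", "CA", "OA"): (35.0, 113.00),
    ("CT", "CA", "OA"): (45.0, 117.00),
}

# dihedral parameters keyed by the central bond's classes
_DIHEDRALS = {
    ("CT", "CT"): (0.16, 3, 0.0),
    ("CT", "OH"): (0.14, 3, 0.0),
    ("CA", "CA"): (3.10, 2, 180.0),
    ("CA", "CT"): (0.10, 3, 0.0),
    ("CA", "OA"): (3.00, 2, 180.0),
}

_ELEMENT = {"CT": "C", "HA": "H", "CA": "C", "HP": "H", "OH": "O",
            "HO": "H", "OA": "O", "AR": "Ar"}

FIXTURE_NAMES = (
    "methane_like",
    "ethane_like",
    "methanol_like",
    "toluene_like",
    "cyclopentyl_like",
    "cpi2_like",
    "cpi7_like",
    "harmonic_pair",
    "lj_bath",
)


def _canon(key):
    return min(key, key[::-1])


def _assemble(label, species, bonds, coordinates=None, trap_k=None):
    """Build a system from (class, charge) records, auto-enumerating angle
    and dihedral terms from the bond graph via the class parameter tables."""
    atoms = []
    classes = []
    for idx, (cls, charge) in enumerate(species):
        eps, sig = _LJ[cls]
        element = _ELEMENT[cls]
        atoms.append(AtomRecord(
            index=idx, element=element, name=f"{element}{idx}",
            charge=charge, lj_epsilon=eps, lj_sigma=sig))
        classes.append(cls)

    nbrs = {i: set() for i in range(len(atoms))}
    for i, j in bonds:
        nbrs[i].add(j)
        nbrs[j].add(i)

    terms = []
    for i, j in sorted((min(b), max(b)) for b in bonds):
        k, r0 = _BONDS[_canon((classes[i], classes[j]))]
        terms.append(BondedTerm("bond", (i, j), k, r0))
    for j in range(len(atoms)):
        for i in sorted(nbrs[j]):
            for k in sorted(nbrs[j]):
                if i < k:
                    key = _canon((classes[i], classes[j], classes[k]))
                    kf, t0 = _ANGLES[key]
                    terms.append(BondedTerm("angle", (i, j, k), kf, t0))
    for j, k in sorted((min(b), max(b)) for b in bonds):
        key = _canon((classes[j], classes[k]))
        if key not in _DIHEDRALS:
            continue
        kf, mult, delta = _DIHEDRALS[key]
        for i in sorted(nbrs[j] - {k}):
            for l in sorted(nbrs[k] - {j}):
                if i != l:
                    terms.append(
                        BondedTerm("dihedral", (i, j, k, l), kf, delta, mult))

    return build_system(atoms, bonds, terms, label=label,
                        coordinates=coordinates, trap_k=trap_k)


def _tetrahedral_dirs():
    d = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return d / math.sqrt(3.0)


def _methyl_hydrogens(c_pos, axis, bond=1.111):
    """Three H positions around ``c_pos`` pointing away from ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    out = []
    for phi in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0):
        d = (-math.cos(math.radians(70.53)) * axis
             + math.sin(math.radians(70.53))
             * (math.cos(phi) * e1 + math.sin(phi) * e2))
        out.append(c_pos + bond * d)
    return out


def _methane():
    species = [("CT", -0.36)] + [("HA", 0.09)] * 4
    bonds = [(0, i) for i in range(1, 5)]
    coords = np.zeros((5, 3))
    coords[1:] = 1.111 * _tetrahedral_dirs()
    return _assemble("methane_like", species, bonds, coords)


def _ethane():
    species = [("CT", -0.27), ("CT", -0.27)] + [("HA", 0.09)] * 6
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 5), (1, 6), (1, 7)]
    c1 = np.zeros(3)
    c2 = np.array([1.528, 0.0, 0.0])
    coords = [c1, c2]
    coords += _methyl_hydrogens(c1, c2 - c1)
    coords += _methyl_hydrogens(c2, c1 - c2)
    return _assemble("ethane_like", species, bonds, np.array(coords))


def _methanol():
    # C(-0.09) H3(0.09 each) O(-0.60) H(0.42): neutral, and the dummy-region
    # charge deficit (-0.18) lands on the carbon, matching the mutated
    # methane-like core charge of -0.27
    species = [("CT", -0.09), ("OH", -0.60),
               ("HA", 0.09), ("HA", 0.09), ("HA", 0.09), ("HO", 0.42)]
    bonds = [(0, 1), (0, 2), (0, 3), (0, 4), (1, 5)]
    c = np.zeros(3)
    o = np.array([1.415, 0.0, 0.0])
    coords = [c, o]
    coords += _methyl_hydrogens(c, o - c)
    coords.append(o + 0.96 * np.array(
        [math.cos(math.radians(74.0)), math.sin(math.radians(74.0)), 0.0]))
    return _assemble("methanol_like", species, bonds, np.array(coords))


def _toluene():
    # 0 methyl C, 1 ipso C, 2-6 ring C, 7-9 methyl H, 10-14 ring H
    species = ([("CT", -0.27), ("CA", 0.0)] + [("CA", -0.115)] * 5
               + [("HA", 0.09)] * 3 + [("HP", 0.115)] * 5)
    ring = [1, 2, 3, 4, 5, 6]
    bonds = [(0, 1), (0, 7), (0, 8), (0, 9)]
    for a, b in zip(ring, ring[1:] + ring[:1]):
        bonds.append((a, b))
    for h, c in zip(range(10, 15), range(2, 7)):
        bonds.append((c, h))
    r_ring = 1.375
    angles = [math.radians(60.0 * k) for k in range(6)]
    ring_xy = [np.array([r_ring * math.cos(a), r_ring * math.sin(a), 0.0])
               for a in angles]
    cme = np.array([r_ring + 1.49, 0.0, 0.0])
    coords = [cme] + ring_xy
    coords += _methyl_hydrogens(cme, ring_xy[0] - cme)
    for a in angles[1:]:
        coords.append(np.array([(r_ring + 1.08) * math.cos(a),
                                (r_ring + 1.08) * math.sin(a), 0.0]))
    return _assemble("toluene_like", species, bonds, np.array(coords))


def _cyclopentane():
    species = [("CT", -0.18)] * 5 + [("HA", 0.09)] * 10
    ring = list(range(5))
    bonds = [(a, b) for a, b in zip(ring, ring[1:] + ring[:1])]
    h = 5
    for c in ring:
        bonds += [(c, h), (c, h + 1)]
        h += 2
    r_ring = 1.528 / (2.0 * math.sin(math.pi / 5.0))
    coords = []
    for k in range(5):
        a = 2.0 * math.pi * k / 5.0
        coords.append(np.array([r_ring * math.cos(a), r_ring * math.sin(a), 0.0]))
    for k in range(5):
        a = 2.0 * math.pi * k / 5.0
        outward = np.array([math.cos(a), math.sin(a), 0.0])
        for sz in (1.0, -1.0):
            d = 0.45 * outward + np.array([0.0, 0.0, sz * 0.89])
            d /= np.linalg.norm(d)
            coords.append(coords[k] + 1.111 * d)
    return _assemble("cyclopentyl_like", species, bonds, np.array(coords))


def _cpi(attach_position: int, label: str):
    """Cyclopentyl bound to a furan-like aromatic 5-ring.

    ``attach_position`` selects the ring carbon carrying the cyclopentyl
    group (1 = adjacent to the ring oxygen, 2 = one bond further), giving
    two regioisomers whose common core is the whole cyclopentyl fragment
    plus the junction.

    Ring indices: 0 = O, 1..4 = aromatic C.  Cyclopentyl indices: 5..9 = CT
    (5 is the attachment carbon), then hydrogens.
    """
    ring_cls = ["OA", "CA", "CA", "CA", "CA"]
    ring_q = [-0.18, -0.115, -0.115, -0.115, -0.115]
    ring_q[attach_position] = 0.0
    species = list(zip(ring_cls, ring_q))
    species += [("CT", 0.09)] + [("CT", -0.18)] * 4          # 5..9
    species.append(("HA", 0.09))                              # 10: H on C5
    species += [("HA", 0.09)] * 8                             # 11..18: CH2 H
    aro_h = [i for i in range(1, 5) if i != attach_position]
    species += [("HP", 0.115)] * len(aro_h)                   # 19..21

    ring = [0, 1, 2, 3, 4]
    bonds = [(a, b) for a, b in zip(ring, ring[1:] + ring[:1])]
    bonds.append((attach_position, 5))
    cp = [5, 6, 7, 8, 9]
    bonds += [(a, b) for a, b in zip(cp, cp[1:] + cp[:1])]
    bonds.append((5, 10))
    h = 11
    for c in (6, 7, 8, 9):
        bonds += [(c, h), (c, h + 1)]
        h += 2
    for hp, c in zip(range(19, 19 + len(aro_h)), aro_h):
        bonds.append((c, hp))
    return _assemble(label, species, bonds, coordinates=None)


def _harmonic_pair(spring_constant=100.0, rest_length=1.5):
    atoms = [
        AtomRecord(0, "Ar", "P0", 0.0, 0.0, 0.0),
        AtomRecord(1, "Ar", "P1", 0.0, 0.0, 0.0),
    ]
    bonds = [(0, 1)]
    terms = [BondedTerm("bond", (0, 1), spring_constant, rest_length)]
    coords = np.array([[0.0, 0.0, 0.0], [rest_length, 0.0, 0.0]])
    return build_system(atoms, bonds, terms, label="harmonic_pair",
                        coordinates=coords)


def bath_coordinates(n_bath: int, radius: float, seed: int) -> np.ndarray:
    """Deterministic Fibonacci-sphere shell with seeded jitter."""
    rng = np.random.default_rng(seed)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for k in range(n_bath):
        z = 1.0 - 2.0 * (k + 0.5) / n_bath
        r = math.sqrt(max(0.0, 1.0 - z * z))
        th = golden * k
        pts.append([radius * r * math.cos(th), radius * r * math.sin(th),
                    radius * z])
    return np.array(pts) + rng.uniform(-0.25, 0.25, size=(n_bath, 3))


def with_bath(system: MolecularSystem, bath_coords: np.ndarray,
              epsilon: float = 0.1, sigma: float = 3.0,
              trap_k: float = 0.2) -> MolecularSystem:
    """Append neutral LJ bath particles and a confining trap to a system.

    The solute keeps its indices; bath particles are unbonded and
    uncharged, so the solute's net charge is untouched.
    """
    if system.coordinates is None:
        raise ValidationError(
            f"system {system.label!r} needs coordinates before embedding")
    n0 = system.n_atoms
    atoms = list(system.atoms)
    for k, _ in enumerate(bath_coords):
        atoms.append(AtomRecord(n0 + k, "Ar", f"AR{k}", 0.0, epsilon, sigma))
    coords = np.vstack([system.coordinates, np.asarray(bath_coords)])
    return build_system(atoms, system.bonds, system.terms,
                        label=f"{system.label}+bath",
                        coordinates=coords, trap_k=trap_k)


def make_fixture(name: str, seed: int = 0, **kwargs) -> MolecularSystem:
    """Build a named fixture deterministically.

    ``seed`` only matters for ``lj_bath`` (bath-shell jitter); molecular
    fixtures are identical for every seed by construction.
    """
    if name == "methane_like":
        return _methane()
    if name == "ethane_like":
        return _ethane()
    if name == "methanol_like":
        return _methanol()
    if name == "toluene_like":
        return _toluene()
    if name == "cyclopentyl_like":
        return _cyclopentane()
    if name == "cpi2_like":
        return _cpi(1, "cpi2_like")
    if name == "cpi7_like":
        return _cpi(2, "cpi7_like")
    if name == "harmonic_pair":
        return _harmonic_pair(**kwargs)
    if name == "lj_bath":
        solute = kwargs.pop("solute", "methane_like")
        if isinstance(solute, str):
            solute = make_fixture(solute)
        n_bath = kwargs.pop("n_bath", 20)
        radius = kwargs.pop("radius", None)
        if radius is None:
            extent = float(np.max(np.linalg.norm(solute.coordinates, axis=1)))
            radius = extent + kwargs.get("sigma", 3.0) + 1.0
        coords = bath_coordinates(n_bath, radius, seed)
        return with_bath(solute, coords,
                         epsilon=kwargs.pop("epsilon", 0.1),
                         sigma=kwargs.pop("sigma", 3.0),
                         trap_k=kwargs.pop("trap_k", 0.2))
    raise ValidationError(f"unknown fixture {name!r}")


def make_analytic(spring_constants, centers=()) -> AnalyticSystem:
    """Analytic harmonic reference with a closed-form free energy."""
    return AnalyticSystem(spring_constants=tuple(spring_constants),
                          centers=tuple(centers))
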