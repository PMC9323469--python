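"""Common-core discovery between two molecules.

The *common core* (CC) is the maximum connected common substructure under a
user-selected atom matching criterion, with the additional constraint that no
ring may be matched partially.  Relative free energies between two molecules
are computed as differences of the legs mutating each molecule into this
shared core.

The search is an exact McGregor-style branch-and-bound over *induced*
connected common subgraph mappings: a pair list is grown by adding
correspondences adjacent to the current mapping, branching over every
consistent partner of the smallest candidate atom of A plus the branch that
excludes that atom, with an upper bound pruning subtrees that cannot beat the
incumbent.  Ties between equally large solutions are broken by the
lexicographically smallest sorted index list in A, then in B — output is
fully deterministic.

After discovery, :func:`insert_junction_particle` designates the dummy-region
atom bonded to the CC as the junction LJ particle X, which keeps one
interacting atom between the core and the dummy region and thereby turns a
triple junction into the benign terminal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Tuple

from .molecular_model import (
    AtomRecord,
    BondedTerm,
    MolecularSystem,
    ValidationError,
    rings,
)

__all__ = [
    "MatchCriterion",
    "CommonCoreMap",
    "XParams",
    "NoCommonCoreError",
    "UnsupportedTopologyError",
    "find_common_core",
    "classify_junction",
    "insert_junction_particle",
    "target_cc_state",
]


class NoCommonCoreError(ValueError):
    """No pair of atoms matches under the given criterion."""


class UnsupportedTopologyError(ValueError):
    """Dummy-region topology outside the supported cases."""


_MODES = ("element", "element_and_degree", "full_type")


@dataclass(frozen=True)
class MatchCriterion:
    """Atom matching criterion for the substructure search.

    ``element``             same chemical element
    ``element_and_degree``  same element and same number of bonded neighbours
    ``full_type``           same element, degree, and LJ parameters
                            (a force-field-type-level match)
    ``forbid_ring_partial`` when True (default) every ring of either molecule
                            is matched completely or not at all
    """

    mode: str = "element"
    forbid_ring_partial: bool = True

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValidationError(
                f"match mode must be one of {_MODES}, got {self.mode!r}"
            )


@dataclass(frozen=True)
class XParams:
    """LJ parameters and charge of the junction particle X.

    Defaults are the conventional junction-particle values: a well depth of
    0.15 kcal/mol (stored as a magnitude), sigma of 1.5 A, zero charge.
    They are configuration, not constants.
    """

    epsilon: float = 0.15
    sigma: float = 1.5
    charge: float = 0.0


@dataclass(frozen=True)
class CommonCoreMap:
    """Atom-level bijection between the common cores of two systems."""

    pairs: tuple                      # ordered ((iA, iB), ...), sorted by iA
    cc_atoms_a: frozenset
    cc_atoms_b: frozenset
    dummy_region_a: frozenset
    dummy_region_b: frozenset
    label_a: str = ""
    label_b: str = ""
    junction_a: Optional[int] = None
    junction_b: Optional[int] = None
    template_a: Optional[int] = None
    template_b: Optional[int] = None
    x_params: Optional[XParams] = None

    def mirrored(self) -> "CommonCoreMap":
        return CommonCoreMap(
            pairs=tuple(sorted((b, a) for a, b in self.pairs)),
            cc_atoms_a=self.cc_atoms_b,
            cc_atoms_b=self.cc_atoms_a,
            dummy_region_a=self.dummy_region_b,
            dummy_region_b=self.dummy_region_a,
            label_a=self.label_b,
            label_b=self.label_a,
            junction_a=self.junction_b,
            junction_b=self.junction_a,
            template_a=self.template_b,
            template_b=self.template_a,
            x_params=self.x_params,
        )

    def side(self, label: str) -> str:
        if label == self.label_a:
            return "a"
        if label == self.label_b:
            return "b"
        raise ValidationError(
            f"system {label!r} is neither side of this map "
            f"({self.label_a!r}, {self.label_b!r})"
        )


def _compat(criterion: MatchCriterion, A: MolecularSystem, B: MolecularSystem
            ) -> Callable[[int, int], bool]:
    deg_a = {i: len(A.neighbors(i)) for i in range(A.n_atoms)}
    deg_b = {i: len(B.neighbors(i)) for i in range(B.n_atoms)}

    def ok(a: int, b: int) -> bool:
        ra, rb = A.atoms[a], B.atoms[b]
        if ra.element != rb.element:
            return False
        if criterion.mode == "element":
            return True
        if deg_a[a] != deg_b[b]:
            return False
        if criterion.mode == "element_and_degree":
            return True
        return (
            abs(ra.lj_epsilon - rb.lj_epsilon) <= 1e-9
            and abs(ra.lj_sigma - rb.lj_sigma) <= 1e-9
        )

    return ok


def _ring_ok(ring_sets, mapped) -> bool:
    for ring in ring_sets:
        hit = len(ring & mapped)
        if 0 < hit < len(ring):
            return False
    return True


def find_common_core(A: MolecularSystem, B: MolecularSystem,
                     criterion: MatchCriterion = MatchCriterion()) -> CommonCoreMap:
    """Maximum connected induced common subgraph of A and B.

    Deterministic; raises :class:`NoCommonCoreError` when no atom of A
    matches any atom of B under the criterion.
    """
    for name, s in (("A", A), ("B", B)):
        if not s.is_connected():
            raise ValidationError(f"system {name} ({s.label!r}) is not connected")

    ok = _compat(criterion, A, B)
    adj_a = {i: A.neighbors(i) for i in range(A.n_atoms)}
    adj_b = {i: B.neighbors(i) for i in range(B.n_atoms)}
    rings_a = rings(A) if criterion.forbid_ring_partial else ()
    rings_b = rings(B) if criterion.forbid_ring_partial else ()

    candidates_exist = any(
        ok(a, b) for a in range(A.n_atoms) for b in range(B.n_atoms)
    )
    if not candidates_exist:
        raise NoCommonCoreError(
            f"no atom of {A.label!r} matches any atom of {B.label!r} under "
            f"criterion {criterion.mode!r}"
        )

    best: dict = {"size": 0, "key": None, "pairs": None}

    def record(mapping: Dict[int, int]) -> None:
        if not mapping:
            return
        mapped_a = frozenset(mapping)
        mapped_b = frozenset(mapping.values())
        if criterion.forbid_ring_partial and not (
            _ring_ok(rings_a, mapped_a) and _ring_ok(rings_b, mapped_b)
        ):
            return
        size = len(mapping)
        key = (
            tuple(sorted(mapping)),
            tuple(mapping[a] for a in sorted(mapping)),
        )
        if size > best["size"] or (size == best["size"] and
                                   (best["key"] is None or key < best["key"])):
            best["size"] = size
            best["key"] = key
            best["pairs"] = tuple(sorted(mapping.items()))

    def extend(mapping: Dict[int, int], excluded_a: frozenset) -> None:
        record(mapping)
        mapped_a = set(mapping)
        mapped_b = set(mapping.values())
        if mapping:
            frontier_a = sorted(
                set().union(*(adj_a[a] for a in mapped_a))
                - mapped_a - set(excluded_a)
            )
        else:
            frontier_a = [a for a in range(A.n_atoms) if a not in excluded_a]
        # upper bound: current size plus every A atom still eligible,
        # capped by the number of unmapped B atoms
        eligible = A.n_atoms - len(mapped_a) - len(excluded_a)
        bound = len(mapping) + min(eligible, B.n_atoms - len(mapped_b))
        if bound < best["size"] or not frontier_a:
            return
        a_star = frontier_a[0]
        partners = []
        for b in range(B.n_atoms):
            if b in mapped_b or not ok(a_star, b):
                continue
            consistent = True
            for a2, b2 in mapping.items():
                if (a_star in adj_a[a2]) != (b in adj_b[b2]):
                    consistent = False
                    break
            if consistent and mapping and not any(
                b in adj_b[b2] for b2 in mapped_b
            ):
                # keep the mapped image of B connected as well
                consistent = False
            if consistent:
                partners.append(b)
        for b in partners:
            mapping[a_star] = b
            extend(mapping, excluded_a)
            del mapping[a_star]
        extend(mapping, excluded_a | {a_star})

    extend({}, frozenset())

    if best["pairs"] is None:
        raise NoCommonCoreError(
            f"no ring-preserving common core between {A.label!r} and {B.label!r}"
        )

    pairs = best["pairs"]
    cc_a = frozenset(a for a, _ in pairs)
    cc_b = frozenset(b for _, b in pairs)
    return CommonCoreMap(
        pairs=pairs,
        cc_atoms_a=cc_a,
        cc_atoms_b=cc_b,
        dummy_region_a=frozenset(range(A.n_atoms)) - cc_a,
        dummy_region_b=frozenset(range(B.n_atoms)) - cc_b,
        label_a=A.label,
        label_b=B.label,
    )


_JUNCTION_KIND = {1: "terminal", 2: "double", 3: "triple"}


def classify_junction(system: MolecularSystem, cc_atoms: frozenset) -> Dict[int, str]:
    """Classify every physical-dummy attachment point of the system.

    Returns ``{attachment atom index: kind}`` where the kind is determined by
    the attachment atom's number of CC neighbours (1/2/3 -> terminal /
    double / triple).  An empty dict means no dummy region exists ("none").
    """
    cc_atoms = frozenset(cc_atoms)
    if not cc_atoms:
        raise ValidationError("cc_atoms must be non-empty")
    g = system.graph()
    sub = g.subgraph(cc_atoms)
    import networkx as nx

    if not nx.is_connected(sub):
        raise ValidationError("CC-induced subgraph is not connected")
    out: Dict[int, str] = {}
    for a in sorted(cc_atoms):
        nbrs = system.neighbors(a)
        if nbrs - cc_atoms:
            n_cc = len(nbrs & cc_atoms)
            try:
                out[a] = _JUNCTION_KIND[n_cc]
            except KeyError:
                raise UnsupportedTopologyError(
                    f"attachment atom {a} has {n_cc} CC neighbours; only "
                    "terminal/double/triple junctions are classified"
                ) from None
    return out


def _single_region(system: MolecularSystem, cc_atoms: frozenset):
    """The one dummy region, its X atom, and its CC attachment atom."""
    import networkx as nx

    non_cc = set(range(system.n_atoms)) - cc_atoms
    if not non_cc:
        return None
    g = system.graph()
    components = [frozenset(c) for c in nx.connected_components(g.subgraph(non_cc))]
    if len(components) != 1:
        raise UnsupportedTopologyError(
            f"system {system.label!r} has {len(components)} dummy regions; "
            "exactly one is supported"
        )
    region = components[0]
    attachments = set()
    x_candidates = set()
    for r in region:
        cc_nbrs = system.neighbors(r) & cc_atoms
        if cc_nbrs:
            attachments |= cc_nbrs
            x_candidates.add(r)
    if len(attachments) != 1:
        raise UnsupportedTopologyError(
            f"dummy region of {system.label!r} attaches through "
            f"{len(attachments)} CC atoms (ring-spanning mutation)"
        )
    if len(x_candidates) != 1:
        raise UnsupportedTopologyError(
            f"dummy region of {system.label!r} has {len(x_candidates)} atoms "
            "bonded to the CC; the junction particle must be unique"
        )
    return region, next(iter(x_candidates)), next(iter(attachments))


def _default_template(system: MolecularSystem, cc_atoms: frozenset,
                      x_atom: int, attachment: int) -> int:
    """The 'corresponding hydrogen' rule: a CC hydrogen on the attachment atom.

    When X itself is a hydrogen its own bonded parameters are already the
    template (identity substitution).
    """
    if system.atoms[x_atom].element == "H":
        return x_atom
    hydrogens = sorted(
        i for i in (system.neighbors(attachment) & cc_atoms)
        if system.atoms[i].element == "H"
    )
    if not hydrogens:
        raise UnsupportedTopologyError(
            f"system {system.label!r}: no CC hydrogen on attachment atom "
            f"{attachment} to serve as bonded-parameter template; designate "
            "one explicitly"
        )
    return hydrogens[0]


def _template_lookup(system: MolecularSystem, cc_atoms: frozenset,
                     x_atom: int, attachment: int, template: int,
                     term: BondedTerm) -> BondedTerm:
    """Parameters for a term involving X, taken from the template atom.

    Substitutes X -> template in the atom tuple and looks the resulting term
    up in the system.  When the template already appears in the term (which
    would produce a degenerate tuple) another equivalent CC hydrogen on the
    attachment atom is used instead.
    """
    candidates = [template] + sorted(
        i for i in (system.neighbors(attachment) & cc_atoms)
        if system.atoms[i].element == "H" and i != template
    )
    by_key = {}
    for t in system.terms:
        by_key.setdefault((t.kind, t.canonical_atoms()), t)
    for tpl in candidates:
        if tpl == x_atom:  # identity substitution: keep the term as is
            return term
        if tpl in term.atoms:
            continue
        subst = tuple(tpl if i == x_atom else i for i in term.atoms)
        probe = min(subst, subst[::-1])
        hit = by_key.get((term.kind, probe))
        if hit is not None:
            if term.kind == "dihedral" and hit.multiplicity != term.multiplicity:
                continue
            return BondedTerm(term.kind, term.atoms, hit.force_constant,
                              hit.equilibrium, term.multiplicity)
    # the attachment atom may carry too few hydrogens for a direct
    # substitution (e.g. a single H on a ring CH); fall back to any
    # all-core term with the same element pattern, which in the reference
    # core molecule is the term the substitution would have produced
    elements = [system.atoms[template if i == x_atom else i].element
                for i in term.atoms]
    probe_el = min(tuple(elements), tuple(elements[::-1]))
    for t in sorted(
        (t for t in system.terms if t.kind == term.kind
         and all(i in cc_atoms for i in t.atoms)),
        key=lambda t: t.atoms,
    ):
        el = tuple(system.atoms[i].element for i in t.atoms)
        if min(el, el[::-1]) != probe_el:
            continue
        if term.kind == "dihedral" and t.multiplicity != term.multiplicity:
            continue
        return BondedTerm(term.kind, term.atoms, t.force_constant,
                          t.equilibrium, term.multiplicity)
    raise UnsupportedTopologyError(
        f"system {system.label!r}: no template parameters found for "
        f"{term.kind} term {term.atoms} involving the junction atom"
    )


def target_cc_state(system: MolecularSystem, cc_atoms: frozenset,
                    scaled_atoms: frozenset, x_atom: int, attachment: int,
                    template: int, x_params: XParams) -> MolecularSystem:
    """The fully mutated target state of one system.

    Charges of ``scaled_atoms`` (dummy region plus X) are zero with the full
    deficit compensated on the attachment atom; dummy-region LJ parameters
    are off; X carries ``x_params``; bonded terms involving X and CC atoms
    only take their template values.  Bonded terms that involve any dummy
    atom are retained unmodified — they contribute an additive, cancelling
    term to the partition function.
    """
    import math

    deficit = math.fsum(system.atoms[i].charge for i in scaled_atoms)
    new_atoms = []
    for a in system.atoms:
        if a.index == x_atom:
            new_atoms.append(replace(
                a, name="X", charge=x_params.charge,
                lj_epsilon=x_params.epsilon, lj_sigma=x_params.sigma))
        elif a.index in scaled_atoms:
            new_atoms.append(replace(a, charge=0.0, lj_epsilon=0.0, lj_sigma=0.0))
        elif a.index == attachment:
            new_atoms.append(replace(a, charge=a.charge + deficit))
        else:
            new_atoms.append(a)

    cc_with_x = cc_atoms | {x_atom}
    new_terms = []
    for t in system.terms:
        if x_atom in t.atoms and all(i in cc_with_x for i in t.atoms):
            new_terms.append(_template_lookup(
                system, cc_atoms, x_atom, attachment, template, t))
        else:
            new_terms.append(t)
    out = system.with_atoms(new_atoms).with_terms(new_terms)
    out.label = system.label
    return out


def insert_junction_particle(
    ccmap: CommonCoreMap,
    A: MolecularSystem,
    B: MolecularSystem,
    x_params: XParams = XParams(),
    template_a: Optional[int] = None,
    template_b: Optional[int] = None,
) -> Tuple[CommonCoreMap, MolecularSystem, MolecularSystem]:
    """Designate the junction particle X in both systems.

    Returns the updated map (CC grown by the matched pair X_A <-> X_B, dummy
    regions shrunk accordingly) together with the two fully mutated target CC
    states.  Raises :class:`UnsupportedTopologyError` for multi-region or
    ring-spanning dummy topologies, and when only one side has a dummy
    region (the X_A <-> X_B pairing would be undefined).
    """
    if A.label != ccmap.label_a or B.label != ccmap.label_b:
        raise ValidationError("systems do not match the map's labels")

    reg_a = _single_region(A, ccmap.cc_atoms_a)
    reg_b = _single_region(B, ccmap.cc_atoms_b)
    if (reg_a is None) != (reg_b is None):
        missing = "A" if reg_a is None else "B"
        raise UnsupportedTopologyError(
            f"system {missing} has no dummy region; cannot pair junction atoms"
        )
    if reg_a is None:
        return ccmap, A, B

    region_a, x_a, attach_a = reg_a
    region_b, x_b, attach_b = reg_b
    tpl_a = _default_template(A, ccmap.cc_atoms_a, x_a, attach_a) \
        if template_a is None else template_a
    tpl_b = _default_template(B, ccmap.cc_atoms_b, x_b, attach_b) \
        if template_b is None else template_b

    new_map = CommonCoreMap(
        pairs=tuple(sorted(ccmap.pairs + ((x_a, x_b),))),
        cc_atoms_a=ccmap.cc_atoms_a | {x_a},
        cc_atoms_b=ccmap.cc_atoms_b | {x_b},
        dummy_region_a=ccmap.dummy_region_a - {x_a},
        dummy_region_b=ccmap.dummy_region_b - {x_b},
        label_a=ccmap.label_a,
        label_b=ccmap.label_b,
        junction_a=x_a,
        junction_b=x_b,
        template_a=tpl_a,
        template_b=tpl_b,
        x_params=x_params,
    )
    # scaled charges: the pre-insertion dummy region, which still includes X
    target_a = target_cc_state(
        A, ccmap.cc_atoms_a, frozenset(ccmap.dummy_region_a),
        x_a, attach_a, tpl_a, x_params)
    target_b = target_cc_state(
        B, ccmap.cc_atoms_b, frozenset(ccmap.dummy_region_b),
        x_b, attach_b, tpl_b, x_params)
    return new_map, target_a, target_b
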