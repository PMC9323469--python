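"""Generation of the alchemical path from a physical end-state to the CC.

The path always mutates in the same order:

1. *elec* — partial charges of all atoms outside the common core (including
   the junction particle X) are scaled linearly to zero over equally spaced
   multipliers.  Whenever the scaled molecule would carry a non-integer net
   charge, the full deficit is placed on the physical CC atom bonded to X,
   so the total charge of every state equals the end-state total exactly.
2. *vdw* — serial atom insertion: LJ parameters are turned off *binarily*
   (no fractional LJ scaling exists anywhere in this code path).  All
   dummy-region hydrogens go in one stage, then heavy atoms at one or two
   per stage, peeled from the outside in (farthest graph distance from the
   CC first).  The retyping of the junction atom to the X parameters is the
   last vdw-stage action.
3. *cc_adjust* — bonded terms involving X are interpolated linearly from
   their end-state values to the target-CC (template) values.

Stages that would be no-ops (no nonzero non-CC charge, no differing bonded
term) are omitted, so e.g. a methane-like end-state yields exactly one elec
stage, one vdw stage (the single H -> X change) and no cc_adjust stages.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import networkx as nx

from . import charmm, io as state_io
from .common_core import CommonCoreMap, XParams, target_cc_state
from .molecular_model import (
    BondedTerm,
    MolecularSystem,
    ValidationError,
    net_charge,
)

__all__ = [
    "ScheduleConfig",
    "IntermediateState",
    "MutationPath",
    "OrderingViolationError",
    "UnsupportedInterpolationError",
    "plan_path",
    "apply_charge_stage",
    "apply_vdw_stage",
    "interpolate_cc_parameters",
    "write_state",
    "write_path",
]

STAGE_ORDER = ("endpoint", "elec", "vdw", "cc_adjust", "cc_target")


class OrderingViolationError(ValueError):
    """An atom's LJ parameters were touched before its charge was removed."""


class UnsupportedInterpolationError(ValueError):
    """Bonded terms of source and target cannot be interpolated."""


@dataclass(frozen=True)
class ScheduleConfig:
    """Stage counts of the alchemical schedule.

    n_elec_stages              states used to scale non-CC charges to zero
    heavy_atoms_per_vdw_stage  1 or 2 heavy atoms turned off per vdw stage
    n_cc_adjust_stages         states interpolating X's bonded parameters
    """

    n_elec_stages: int = 5
    heavy_atoms_per_vdw_stage: int = 2
    n_cc_adjust_stages: int = 5

    def __post_init__(self) -> None:
        if self.n_elec_stages < 0:
            raise ValidationError("n_elec_stages must be >= 0")
        if self.heavy_atoms_per_vdw_stage not in (1, 2):
            raise ValidationError("heavy_atoms_per_vdw_stage must be 1 or 2")
        if self.n_cc_adjust_stages < 0:
            raise ValidationError("n_cc_adjust_stages must be >= 0")


@dataclass(frozen=True)
class IntermediateState:
    """One fully parameterized state along the path."""

    system: MolecularSystem
    stage: str
    scale: float
    altered_atoms: frozenset
    state_index: int

    def __post_init__(self) -> None:
        if self.stage not in STAGE_ORDER:
            raise ValidationError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class MutationPath:
    states: tuple
    source_label: str
    target_label: str

    def __len__(self) -> int:
        return len(self.states)

    def stage_counts(self) -> dict:
        out = {s: 0 for s in STAGE_ORDER}
        for st in self.states:
            out[st.stage] += 1
        return out


# ---------------------------------------------------------------------------
# elementary stage operations


def apply_charge_stage(
    state: IntermediateState,
    multiplier: float,
    *,
    reference: MolecularSystem,
    scaled_atoms: frozenset,
    compensation_atom: int,
) -> IntermediateState:
    """Scale the charges of ``scaled_atoms`` to ``multiplier`` times their
    value in the *reference* (physical end-state) system.

    The compensation charge is recomputed from scratch against the reference
    total at every stage — never accumulated — so the state total matches
    the end-state total exactly regardless of the stage history.
    """
    if not (0.0 <= multiplier <= 1.0):
        raise ValidationError(f"charge multiplier {multiplier} outside [0, 1]")
    target_total = net_charge(reference)
    sys0 = state.system
    new_atoms = list(sys0.atoms)
    altered = set()
    for i in sorted(scaled_atoms):
        q = reference.atoms[i].charge * multiplier
        if q != new_atoms[i].charge:
            altered.add(i)
        new_atoms[i] = replace(new_atoms[i], charge=q)
    # solve for the compensating charge so the total is conserved exactly
    others = math.fsum(
        a.charge for a in new_atoms if a.index != compensation_atom
    )
    comp = target_total - others
    if comp != new_atoms[compensation_atom].charge:
        altered.add(compensation_atom)
        new_atoms[compensation_atom] = replace(
            new_atoms[compensation_atom], charge=comp)
    return IntermediateState(
        system=sys0.with_atoms(new_atoms),
        stage="elec",
        scale=multiplier,
        altered_atoms=frozenset(altered),
        state_index=state.state_index + 1,
    )


def apply_vdw_stage(
    state: IntermediateState,
    atoms_off: Iterable,
    *,
    cc_atoms: Optional[frozenset] = None,
    scale: float = 0.0,
) -> IntermediateState:
    """Turn the LJ parameters of ``atoms_off`` exactly to zero (binary SAI).

    Every listed atom must already carry zero charge (charges are removed
    before vdW) and must not belong to the CC.
    """
    atoms_off = frozenset(int(i) for i in atoms_off)
    sys0 = state.system
    for i in atoms_off:
        if not (0 <= i < sys0.n_atoms):
            raise ValidationError(f"apply_vdw_stage: unknown atom {i}")
        if cc_atoms is not None and i in cc_atoms:
            raise OrderingViolationError(
                f"atom {i} belongs to the common core and cannot be turned off"
            )
        if sys0.atoms[i].charge != 0.0:
            raise OrderingViolationError(
                f"atom {i} still carries charge {sys0.atoms[i].charge}; "
                "charges must be removed before LJ turn-off"
            )
    new_atoms = [
        replace(a, lj_epsilon=0.0, lj_sigma=0.0) if a.index in atoms_off else a
        for a in sys0.atoms
    ]
    return IntermediateState(
        system=sys0.with_atoms(new_atoms),
        stage="vdw",
        scale=scale,
        altered_atoms=atoms_off,
        state_index=state.state_index + 1,
    )


def interpolate_cc_parameters(
    state: IntermediateState,
    target: MolecularSystem,
    scale: float,
    *,
    junction: int,
    source: Optional[MolecularSystem] = None,
    stage: str = "cc_adjust",
) -> IntermediateState:
    """Linearly mix bonded terms involving the junction atom towards target.

    Each term's numeric parameters become ``(1-scale)*source + scale*target``
    where ``source`` defaults to the current state.  Terms must correspond
    one-to-one (same kind and atom tuple); differing dihedral multiplicities
    are refused rather than guessed.
    """
    if not (0.0 <= scale <= 1.0):
        raise ValidationError(f"interpolation scale {scale} outside [0, 1]")
    src = source if source is not None else state.system
    tgt_by_key = {}
    for t in target.terms:
        if junction in t.atoms:
            tgt_by_key[(t.kind, t.canonical_atoms())] = t
    src_keys = {
        (t.kind, t.canonical_atoms()) for t in src.terms if junction in t.atoms
    }
    if src_keys != set(tgt_by_key):
        raise UnsupportedInterpolationError(
            "bonded terms involving the junction atom do not correspond "
            f"one-to-one: source has {sorted(src_keys)}, target has "
            f"{sorted(tgt_by_key)}"
        )
    new_terms = []
    altered = set()
    for t_src, t_cur in zip(src.terms, state.system.terms):
        key = (t_src.kind, t_src.canonical_atoms())
        if junction not in t_src.atoms:
            new_terms.append(t_cur)
            continue
        t_tgt = tgt_by_key[key]
        if t_src.kind == "dihedral" and t_src.multiplicity != t_tgt.multiplicity:
            raise UnsupportedInterpolationError(
                f"dihedral {t_src.atoms}: multiplicity "
                f"{t_src.multiplicity} != {t_tgt.multiplicity}"
            )
        k = (1.0 - scale) * t_src.force_constant + scale * t_tgt.force_constant
        eq = (1.0 - scale) * t_src.equilibrium + scale * t_tgt.equilibrium
        new = BondedTerm(t_src.kind, t_src.atoms, k, eq, t_src.multiplicity)
        if (new.force_constant, new.equilibrium) != (
            t_cur.force_constant, t_cur.equilibrium
        ):
            altered |= set(t_src.atoms)
        new_terms.append(new)
    return IntermediateState(
        system=state.system.with_terms(new_terms),
        stage=stage,
        scale=scale,
        altered_atoms=frozenset(altered),
        state_index=state.state_index + 1,
    )


# ---------------------------------------------------------------------------
# path planning


def _graph_distance_from_cc(system: MolecularSystem, cc_atoms: frozenset) -> dict:
    g = system.graph()
    dist = {}
    lengths = nx.multi_source_dijkstra_path_length(g, set(cc_atoms))
    for i in range(system.n_atoms):
        dist[i] = lengths.get(i, math.inf)
    return dist


def plan_path(system: MolecularSystem, ccmap: CommonCoreMap,
              schedule: ScheduleConfig = ScheduleConfig()) -> MutationPath:
    """Plan the full ordered state sequence for one side of a molecule pair.

    The side is resolved from the system's label against the map.  The map
    must already carry the junction particle (see
    :func:`ccsai.common_core.insert_junction_particle`).
    """
    side = ccmap.side(system.label)
    if side == "a":
        cc = ccmap.cc_atoms_a
        region = ccmap.dummy_region_a
        x_atom = ccmap.junction_a
        template = ccmap.template_a
    else:
        cc = ccmap.cc_atoms_b
        region = ccmap.dummy_region_b
        x_atom = ccmap.junction_b
        template = ccmap.template_b
    if x_atom is None:
        raise ValidationError(
            "the map carries no junction particle; call "
            "insert_junction_particle before plan_path"
        )
    x_params = ccmap.x_params or XParams()
    scaled_atoms = frozenset(region | {x_atom})
    attachment_candidates = system.neighbors(x_atom) & (cc - {x_atom})
    if len(attachment_candidates) == 1:
        attachment = next(iter(attachment_candidates))
    elif not attachment_candidates and not any(
        system.atoms[i].charge != 0.0 for i in scaled_atoms
    ):
        # nonbonded-only dummy region (e.g. a free LJ particle in a trap):
        # no charge to compensate, so no attachment atom is needed
        attachment = None
    else:
        raise ValidationError(
            f"junction atom {x_atom} must have exactly one CC neighbour, "
            f"found {sorted(attachment_candidates)}"
        )
    target = target_cc_state(system, cc - {x_atom}, scaled_atoms, x_atom,
                             attachment, template, x_params)

    states = [IntermediateState(
        system=system, stage="endpoint", scale=1.0,
        altered_atoms=frozenset(), state_index=0)]

    # --- elec ------------------------------------------------------------
    any_charge = any(system.atoms[i].charge != 0.0 for i in scaled_atoms)
    if any_charge:
        if schedule.n_elec_stages == 0:
            raise ValidationError(
                "schedule has zero elec stages but non-CC charges are nonzero"
            )
        n = schedule.n_elec_stages
        for j in range(1, n + 1):
            m = 1.0 - j / n
            states.append(apply_charge_stage(
                states[-1], m, reference=system,
                scaled_atoms=scaled_atoms, compensation_atom=attachment))

    # --- vdw -------------------------------------------------------------
    live = [i for i in sorted(region)
            if system.atoms[i].lj_epsilon != 0.0 or system.atoms[i].lj_sigma != 0.0]
    hydrogens = [i for i in live if system.atoms[i].element == "H"]
    heavies = [i for i in live if system.atoms[i].element != "H"]
    dist = _graph_distance_from_cc(system, cc)
    heavies.sort(key=lambda i: (-dist[i], i))  # peel from the outside in
    per = schedule.heavy_atoms_per_vdw_stage
    heavy_chunks = [heavies[k:k + per] for k in range(0, len(heavies), per)]
    vdw_batches = ([hydrogens] if hydrogens else []) + heavy_chunks
    if not vdw_batches:
        vdw_batches = [[]]  # the X retyping still needs its own stage
    n_vdw = len(vdw_batches)
    for j, batch in enumerate(vdw_batches, start=1):
        st = apply_vdw_stage(states[-1], batch, cc_atoms=cc, scale=j / n_vdw)
        if j == n_vdw:
            # X retyping is the last vdw-stage action
            new_atoms = list(st.system.atoms)
            xa = new_atoms[x_atom]
            retyped = replace(xa, name="X", charge=xa.charge,
                              lj_epsilon=x_params.epsilon,
                              lj_sigma=x_params.sigma)
            new_atoms[x_atom] = retyped
            st = IntermediateState(
                system=st.system.with_atoms(new_atoms),
                stage="vdw", scale=st.scale,
                altered_atoms=st.altered_atoms | {x_atom},
                state_index=st.state_index)
        states.append(st)

    # --- cc_adjust -------------------------------------------------------
    needs_adjust = False
    tgt_by_key = {(t.kind, t.canonical_atoms()): t for t in target.terms}
    for t in system.terms:
        if x_atom in t.atoms:
            tt = tgt_by_key[(t.kind, t.canonical_atoms())]
            if (abs(tt.force_constant - t.force_constant) > 1e-12
                    or abs(tt.equilibrium - t.equilibrium) > 1e-12):
                needs_adjust = True
                break
    if needs_adjust:
        n = schedule.n_cc_adjust_stages
        if n == 0:
            raise ValidationError(
                "bonded terms involving X differ from the target but the "
                "schedule has zero cc_adjust stages"
            )
        for j in range(1, n + 1):
            stage = "cc_target" if j == n else "cc_adjust"
            states.append(interpolate_cc_parameters(
                states[-1], target, j / n, junction=x_atom,
                source=system, stage=stage))

    return MutationPath(
        states=tuple(states),
        source_label=system.label,
        target_label=target.label,
    )


# ---------------------------------------------------------------------------
# output


def write_state(state: IntermediateState, directory: str,
                formats: Sequence[str] = ("portable",)) -> None:
    """Write one state to ``directory`` (portable file, optional CHARMM)."""
    os.makedirs(directory, exist_ok=True)
    for fmt in formats:
        if fmt == "portable":
            state_io.write_portable(
                state.system, os.path.join(directory, "system.txt"))
        elif fmt == "psf":
            charmm.write_psf(state.system, os.path.join(directory, "system.psf"))
        elif fmt == "rtf":
            charmm.write_rtf(state.system, os.path.join(directory, "system.rtf"))
        elif fmt == "prm":
            charmm.write_prm(state.system, os.path.join(directory, "system.prm"))
        else:
            raise ValidationError(f"unknown output format {fmt!r}")


def write_path(path: MutationPath, directory: str,
               formats: Sequence[str] = ("portable",)) -> None:
    """Write every state to ``state_<k>/`` plus an ordered index manifest."""
    os.makedirs(directory, exist_ok=True)
    manifest = []
    for st in path.states:
        sub = os.path.join(directory, f"state_{st.state_index}")
        write_state(st, sub, formats)
        manifest.append({
            "state_index": st.state_index,
            "stage": st.stage,
            "scale": st.scale,
            "altered_atoms": sorted(st.altered_atoms),
            "directory": f"state_{st.state_index}",
        })
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump({
            "source": path.source_label,
            "target": path.target_label,
            "states": manifest,
        }, fh, indent=2)
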