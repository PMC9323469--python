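"""Alchemical path generation: ordering, conservation, end-state equivalence."""

import math

import numpy as np
import pytest

from ccsai import (
    AtomRecord,
    BondedTerm,
    IntermediateState,
    ScheduleConfig,
    ValidationError,
    XParams,
    apply_charge_stage,
    apply_vdw_stage,
    build_system,
    find_common_core,
    insert_junction_particle,
    interpolate_cc_parameters,
    net_charge,
    plan_path,
)
from ccsai.io import read_portable
from ccsai.mutation_path import (
    STAGE_ORDER,
    OrderingViolationError,
    UnsupportedInterpolationError,
    write_path,
    write_state,
)
from ccsai.common_core import classify_junction
from ccsai import make_fixture

from _oracles import parse_psf


import functools


@functools.lru_cache(maxsize=None)
def _prepared(name_a, name_b):
    a, b = make_fixture(name_a), make_fixture(name_b)
    m = find_common_core(a, b)
    m2, _, _ = insert_junction_particle(m, a, b, XParams())
    return a, b, m2


PAIRS = [
    ("methane_like", "ethane_like"),
    ("methane_like", "methanol_like"),
    ("methane_like", "toluene_like"),
    ("cpi2_like", "cpi7_like"),
]


class TestPlanPath:
    def test_methane_path_is_one_elec_one_vdw(self):
        a, b, m = _prepared("methane_like", "ethane_like")
        path = plan_path(a, m, ScheduleConfig(1, 1, 3))
        assert [s.stage for s in path.states] == ["endpoint", "elec", "vdw"]

    def test_toluene_path_has_all_stage_groups(self):
        a, b, m = _prepared("methane_like", "toluene_like")
        path = plan_path(b, m, ScheduleConfig(
            n_elec_stages=3, heavy_atoms_per_vdw_stage=2,
            n_cc_adjust_stages=4))
        counts = path.stage_counts()
        assert counts["endpoint"] == 1
        assert counts["elec"] == 3
        # 5 ring hydrogens in one step, 5 dummy ring carbons at <= 2 per step
        assert counts["vdw"] == 1 + math.ceil(5 / 2)
        assert counts["cc_adjust"] + counts["cc_target"] == 4

    def test_heavy_stage_count_with_one_per_stage(self):
        a, b, m = _prepared("methane_like", "toluene_like")
        path = plan_path(b, m, ScheduleConfig(2, 1, 2))
        assert path.stage_counts()["vdw"] == 1 + 5

    def test_path_length_arithmetic(self):
        # 1 endpoint + n_elec + (1 + ceil(n_heavy/per)) + n_cc_adjust
        a, b, m = _prepared("methane_like", "toluene_like")
        for per, n_elec, n_cc in [(1, 2, 3), (2, 4, 1)]:
            path = plan_path(b, m, ScheduleConfig(n_elec, per, n_cc))
            assert len(path) == 1 + n_elec + (1 + math.ceil(5 / per)) + n_cc

    def test_zero_elec_stages_with_charges_rejected(self):
        a, b, m = _prepared("methane_like", "ethane_like")
        with pytest.raises(ValidationError, match="zero elec"):
            plan_path(b, m, ScheduleConfig(0, 1, 3))

    def test_hydrogens_first_then_outermost_heavies(self):
        a, b, m = _prepared("methane_like", "toluene_like")
        path = plan_path(b, m, ScheduleConfig(1, 1, 2))
        vdw = [s for s in path.states if s.stage == "vdw"]
        first = vdw[0].altered_atoms
        assert all(b.atoms[i].element == "H" for i in first)
        # heavies are peeled farthest-from-CC first: the para carbon (4)
        # precedes the ortho carbons (2, 6)
        heavy_order = [i for s in vdw[1:] for i in sorted(s.altered_atoms)
                       if b.atoms[i].element != "H"]
        assert heavy_order.index(4) < heavy_order.index(2)
        assert heavy_order.index(4) < heavy_order.index(6)

    def test_deterministic(self):
        a, b, m = _prepared("methane_like", "ethane_like")
        p1 = plan_path(b, m, ScheduleConfig(2, 1, 2))
        p2 = plan_path(b, m, ScheduleConfig(2, 1, 2))
        for s1, s2 in zip(p1.states, p2.states):
            assert s1.system.atoms == s2.system.atoms
            assert s1.system.terms == s2.system.terms


class TestPathInvariants:
    @pytest.mark.parametrize("name_a,name_b", PAIRS)
    def test_charge_conserved_at_every_state(self, name_a, name_b):
        a, b, m = _prepared(name_a, name_b)
        for system in (a, b):
            total = net_charge(system)
            path = plan_path(system, m, ScheduleConfig(3, 2, 3))
            for state in path.states:
                assert abs(net_charge(state.system) - total) <= 1e-12

    @pytest.mark.parametrize("name_a,name_b", PAIRS)
    def test_stage_order_is_monotone(self, name_a, name_b):
        a, b, m = _prepared(name_a, name_b)
        for system in (a, b):
            path = plan_path(system, m, ScheduleConfig(3, 2, 3))
            ranks = [STAGE_ORDER.index(s.stage) for s in path.states]
            assert ranks == sorted(ranks)

    @pytest.mark.parametrize("name_a,name_b", PAIRS)
    def test_monotone_charges_and_lj(self, name_a, name_b):
        a, b, m = _prepared(name_a, name_b)
        for system, side in ((a, "a"), (b, "b")):
            x = m.junction_a if side == "a" else m.junction_b
            cc = m.cc_atoms_a if side == "a" else m.cc_atoms_b
            comp_candidates = system.neighbors(x) & (cc - {x})
            comp = next(iter(comp_candidates))
            path = plan_path(system, m, ScheduleConfig(3, 2, 3))
            for prev, cur in zip(path.states, path.states[1:]):
                for i in range(system.n_atoms):
                    if i != comp:
                        assert abs(cur.system.atoms[i].charge) <= \
                            abs(prev.system.atoms[i].charge) + 1e-12
                    if prev.system.atoms[i].lj_epsilon == 0.0 and i != x:
                        assert cur.system.atoms[i].lj_epsilon == 0.0

    @pytest.mark.parametrize("name_a,name_b", PAIRS)
    def test_end_state_cc_equivalence(self, name_a, name_b):
        """Both molecules' final states carry identical core parameters —
        the precondition for dummy-atom cancellation in the cycle."""
        a, b, m = _prepared(name_a, name_b)
        fa = plan_path(a, m, ScheduleConfig(3, 2, 3)).states[-1].system
        fb = plan_path(b, m, ScheduleConfig(3, 2, 3)).states[-1].system
        a2b = dict(m.pairs)
        for ia, ib in m.pairs:
            ra, rb = fa.atoms[ia], fb.atoms[ib]
            assert ra.charge == pytest.approx(rb.charge, abs=1e-12)
            assert ra.lj_epsilon == pytest.approx(rb.lj_epsilon, abs=1e-12)
            assert ra.lj_sigma == pytest.approx(rb.lj_sigma, abs=1e-12)
        cc_with_x_a = m.cc_atoms_a
        terms_a = {
            (t.kind, tuple(sorted(a2b[i] for i in t.atoms))):
            (t.force_constant, t.equilibrium)
            for t in fa.terms if all(i in cc_with_x_a for i in t.atoms)
        }
        terms_b = {
            (t.kind, tuple(sorted(t.atoms))): (t.force_constant, t.equilibrium)
            for t in fb.terms if all(i in m.cc_atoms_b for i in t.atoms)
        }
        assert set(terms_a) == set(terms_b)
        for key, (k1, eq1) in terms_a.items():
            k2, eq2 = terms_b[key]
            assert k1 == pytest.approx(k2, abs=1e-10)
            assert eq1 == pytest.approx(eq2, abs=1e-10)

    @pytest.mark.parametrize("name_a,name_b", PAIRS)
    def test_terminal_junction_after_insertion(self, name_a, name_b):
        a, b, m = _prepared(name_a, name_b)
        for system, cc in ((a, m.cc_atoms_a), (b, m.cc_atoms_b)):
            kinds = classify_junction(system, cc)
            assert set(kinds.values()) <= {"terminal"}


class TestStageOperations:
    def _toy_state(self):
        # connecting atom 0.20; scaled region {1, 2, 3} sums to -0.20
        atoms = [
            AtomRecord(0, "C", "C0", 0.20, 0.1, 3.0),   # connecting atom
            AtomRecord(1, "C", "X", 0.05, 0.1, 3.0),    # junction
            AtomRecord(2, "O", "O2", -0.45, 0.15, 3.0), # dummy region
            AtomRecord(3, "H", "H3", 0.20, 0.02, 2.0),  # dummy region
        ]
        bonds = [(0, 1), (1, 2), (2, 3)]
        system = build_system(atoms, bonds, [], label="toy")
        return IntermediateState(system=system, stage="endpoint", scale=1.0,
                                 altered_atoms=frozenset(), state_index=0)

    def test_multiplier_one_is_identity(self):
        st = self._toy_state()
        out = apply_charge_stage(st, 1.0, reference=st.system,
                                 scaled_atoms=frozenset({1, 2, 3}),
                                 compensation_atom=0)
        assert [a.charge for a in out.system.atoms] == \
            [a.charge for a in st.system.atoms]

    def test_zero_sum_region_needs_no_compensation(self):
        # scaled region {1, 2, 3} sums to zero: the connecting atom (a
        # cationic toy, so the molecule total stays an integer) is untouched
        atoms = [
            AtomRecord(0, "C", "C0", 1.0, 0.1, 3.0),
            AtomRecord(1, "C", "X", 0.05, 0.1, 3.0),
            AtomRecord(2, "O", "O2", -0.25, 0.15, 3.0),
            AtomRecord(3, "H", "H3", 0.20, 0.02, 2.0),
        ]
        system = build_system(atoms, [(0, 1), (1, 2), (2, 3)], [],
                              label="toy0")
        st0 = IntermediateState(system=system, stage="endpoint", scale=1.0,
                                altered_atoms=frozenset(), state_index=0)
        out = apply_charge_stage(st0, 0.0, reference=system,
                                 scaled_atoms=frozenset({1, 2, 3}),
                                 compensation_atom=0)
        assert out.system.atoms[0].charge == 1.0
        for i in (1, 2, 3):
            assert out.system.atoms[i].charge == 0.0
        assert net_charge(out.system) == net_charge(system)

    def test_compensation_lands_on_connecting_atom(self):
        st = self._toy_state()
        # scaled-region sum is 0.05 - 0.45 + 0.20 = -0.20; connecting 0.20
        out = apply_charge_stage(st, 0.0, reference=st.system,
                                 scaled_atoms=frozenset({1, 2, 3}),
                                 compensation_atom=0)
        assert out.system.atoms[0].charge == pytest.approx(0.0, abs=1e-15)
        assert net_charge(out.system) == pytest.approx(net_charge(st.system),
                                                       abs=1e-15)

    def test_multiplier_out_of_range(self):
        st = self._toy_state()
        with pytest.raises(ValidationError, match="outside"):
            apply_charge_stage(st, 1.5, reference=st.system,
                               scaled_atoms=frozenset(), compensation_atom=0)

    def test_vdw_empty_set_is_identity(self):
        st = self._toy_state()
        out = apply_vdw_stage(st, [])
        assert out.system.atoms == st.system.atoms

    def test_vdw_requires_zero_charge(self):
        st = self._toy_state()
        with pytest.raises(OrderingViolationError, match="charge"):
            apply_vdw_stage(st, [2])

    def test_vdw_rejects_cc_atoms(self):
        st = self._toy_state()
        with pytest.raises(OrderingViolationError, match="common core"):
            apply_vdw_stage(st, [0], cc_atoms=frozenset({0, 1}))

    def test_vdw_turns_off_binarily(self):
        st = self._toy_state()
        zeroed = apply_charge_stage(st, 0.0, reference=st.system,
                                    scaled_atoms=frozenset({2, 3}),
                                    compensation_atom=0)
        out = apply_vdw_stage(zeroed, [2, 3])
        for i in (2, 3):
            assert out.system.atoms[i].lj_epsilon == 0.0
            assert out.system.atoms[i].lj_sigma == 0.0
            assert out.system.atoms[i].is_dummy

    def test_interpolation_endpoints_and_midpoint(self):
        atoms = [AtomRecord(i, "C", f"C{i}", 0.0, 0.1, 3.0) for i in range(2)]
        src = build_system(
            atoms, [(0, 1)], [BondedTerm("bond", (0, 1), 300.0, 1.50)],
            label="src")
        tgt = build_system(
            atoms, [(0, 1)], [BondedTerm("bond", (0, 1), 340.0, 1.10)],
            label="tgt")
        st = IntermediateState(system=src, stage="vdw", scale=1.0,
                               altered_atoms=frozenset(), state_index=0)
        assert interpolate_cc_parameters(
            st, tgt, 0.0, junction=1).system.terms[0].force_constant == 300.0
        assert interpolate_cc_parameters(
            st, tgt, 1.0, junction=1).system.terms[0].force_constant == 340.0
        mid = interpolate_cc_parameters(st, tgt, 0.5, junction=1)
        assert mid.system.terms[0].force_constant == 320.0
        assert mid.system.terms[0].equilibrium == pytest.approx(1.30)

    def test_interpolation_refuses_multiplicity_mismatch(self):
        atoms = [AtomRecord(i, "C", f"C{i}", 0.0, 0.1, 3.0) for i in range(4)]
        bonds = [(0, 1), (1, 2), (2, 3)]
        src = build_system(atoms, bonds,
                           [BondedTerm("dihedral", (0, 1, 2, 3), 1.0, 0.0, 3)],
                           label="src")
        tgt = build_system(atoms, bonds,
                           [BondedTerm("dihedral", (0, 1, 2, 3), 1.0, 0.0, 2)],
                           label="tgt")
        st = IntermediateState(system=src, stage="vdw", scale=1.0,
                               altered_atoms=frozenset(), state_index=0)
        with pytest.raises(UnsupportedInterpolationError, match="multiplicity"):
            interpolate_cc_parameters(st, tgt, 0.5, junction=3)


class TestWriteState:
    def test_portable_round_trip(self, tmp_path):
        a, b, m = _prepared("methane_like", "ethane_like")
        path = plan_path(b, m, ScheduleConfig(2, 1, 2))
        state = path.states[2]
        write_state(state, str(tmp_path / "s"), formats=("portable",))
        back = read_portable(tmp_path / "s" / "system.txt")
        assert back.atoms == state.system.atoms
        assert back.terms == state.system.terms

    def test_psf_charges_match_per_stage_values(self, tmp_path):
        a, b, m = _prepared("methane_like", "ethane_like")
        path = plan_path(b, m, ScheduleConfig(2, 1, 2))
        state = path.states[1]    # a partially discharged elec stage
        write_state(state, str(tmp_path / "s"),
                    formats=("portable", "psf", "rtf", "prm"))
        atoms, _ = parse_psf(str(tmp_path / "s" / "system.psf"))
        assert len(atoms) == state.system.n_atoms
        for rec, atom in zip(atoms, state.system.atoms):
            assert rec["charge"] == pytest.approx(atom.charge, abs=5e-7)

    def test_manifest_lists_states_in_order(self, tmp_path):
        import json

        a, b, m = _prepared("methane_like", "ethane_like")
        path = plan_path(b, m, ScheduleConfig(2, 1, 2))
        write_path(path, str(tmp_path))
        with open(tmp_path / "manifest.json") as fh:
            manifest = json.load(fh)
        assert [s["state_index"] for s in manifest["states"]] == \
            list(range(len(path)))
        assert manifest["states"][0]["stage"] == "endpoint"
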