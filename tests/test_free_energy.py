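"""Estimators: frame selection, MBAR/BAR, overlap, cycle arithmetic."""

import math
import warnings

import numpy as np
import pytest

from ccsai import (
    AtomRecord,
    NonbondedOptions,
    SamplerConfig,
    ValidationError,
    build_system,
    ddg_from_cycle,
    make_analytic,
    overlap_matrix,
    propagate_error,
    reduced_potentials,
    sample,
    select_frames,
    solve_bar,
    solve_mbar,
)
from ccsai.free_energy import (
    ConvergenceError,
    ReducedPotentialMatrix,
    reduced_potentials_from_frames,
)
from ccsai.sampling import KB, Trajectory

from _oracles import reference_mbar

T = 303.15


def _harmonic_matrix(k_list, n_per_state, seed, centers=None):
    """Exactly sampled reduced-potential matrix for harmonic states."""
    rng = np.random.default_rng(seed)
    systems = [make_analytic([k], centers=[0.0 if centers is None
                                           else centers[i]])
               for i, k in enumerate(k_list)]
    xs = [s.sample(n_per_state, T, rng) for s in systems]
    x = np.vstack(xs)
    u = np.vstack([s.reduced_potential(x, T) for s in systems])
    return ReducedPotentialMatrix(
        u=u, counts=[n_per_state] * len(k_list), temperature=T), systems


class TestSelectFrames:
    def test_production_protocol_rule(self):
        assert len(select_frames(20000, 0.25, 3)) == 5000

    def test_identity_selection(self):
        np.testing.assert_array_equal(select_frames(7, 0.0, 1), np.arange(7))

    def test_hand_enumerated_case(self):
        np.testing.assert_array_equal(select_frames(10, 0.5, 2), [5, 7, 9])

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ValidationError, match="empty"):
            select_frames(0, 0.0, 1)

    def test_parameter_validation(self):
        with pytest.raises(ValidationError):
            select_frames(10, 1.0, 1)
        with pytest.raises(ValidationError):
            select_frames(10, 0.0, 0)


class TestReducedPotentials:
    def _pair_system(self, label="pair"):
        atoms = [AtomRecord(i, "Ar", f"P{i}", 0.0, 0.2, 3.0)
                 for i in range(2)]
        return build_system(atoms, [], [], label=label,
                            coordinates=np.array([[0.0, 0.0, 0.0],
                                                  [3.4, 0.0, 0.0]]),
                            trap_k=0.5)

    def test_single_state_row_is_beta_u(self):
        from ccsai import potential_energy

        s = self._pair_system()
        traj = sample(s, SamplerConfig(algorithm="metropolis", n_steps=500,
                                       save_interval=50, seed=1))
        m = reduced_potentials([traj], [s], NonbondedOptions(), T)
        beta = 1.0 / (KB * T)
        expect = [beta * potential_energy(s, fr) for fr in traj.frames]
        np.testing.assert_allclose(m.u[0], expect, rtol=1e-12)

    def test_dummy_only_difference_gives_identical_rows(self):
        s_on = self._pair_system()
        atoms = [AtomRecord(0, "Ar", "P0", 0.0, 0.2, 3.0),
                 AtomRecord(1, "Ar", "P1", 0.0, 0.2, 3.0),
                 AtomRecord(2, "C", "DU", 0.0, 0.0, 0.0)]
        s_dummy = build_system(atoms, [], [], label="pair+dummy",
                               coordinates=np.zeros((3, 3)), trap_k=None)
        rng = np.random.default_rng(0)
        frames = rng.normal(0, 2, (20, 3, 3))
        atoms2 = list(atoms)
        atoms2[2] = AtomRecord(2, "O", "DU2", 0.0, 0.0, 0.0)
        s_dummy2 = build_system(atoms2, [], [], label="pair+dummy2")
        m = reduced_potentials_from_frames(
            frames, [10, 10], [s_dummy, s_dummy2], NonbondedOptions(), T)
        np.testing.assert_array_equal(m.u[0], m.u[1])

    def test_shape_and_merged_equivalence(self):
        s = self._pair_system()
        trajs = [sample(s, SamplerConfig(algorithm="metropolis", n_steps=300,
                                         save_interval=50, seed=k))
                 for k in range(3)]
        m1 = reduced_potentials(trajs, [s, s, s], NonbondedOptions(), T)
        assert m1.u.shape == (3, sum(t.n_frames for t in trajs))
        merged = np.concatenate([t.frames for t in trajs])
        m2 = reduced_potentials_from_frames(
            merged, [t.n_frames for t in trajs], [s, s, s],
            NonbondedOptions(), T)
        np.testing.assert_array_equal(m1.u, m2.u)

    def test_atom_count_mismatch_names_both(self, methane):
        s = self._pair_system()
        traj = sample(s, SamplerConfig(algorithm="metropolis", n_steps=100,
                                       save_interval=50, seed=1))
        with pytest.raises(ValidationError, match="methane_like"):
            reduced_potentials([traj], [methane], NonbondedOptions(), T)


class TestSolveMbar:
    def test_identical_states_give_zero(self):
        m, _ = _harmonic_matrix([50.0, 50.0, 50.0], 300, seed=2)
        r = solve_mbar(m)
        np.testing.assert_allclose(r.f_k, 0.0, atol=5e-9)
        assert r.converged
        assert np.all(np.diag(r.uncertainties) == 0.0)

    def test_harmonic_closed_form(self):
        m, _ = _harmonic_matrix([25.0, 100.0], 5000, seed=3)
        r = solve_mbar(m)
        exact = 0.5 * math.log(4.0)
        assert abs(r.f_k[1] - exact) < 3.0 * r.uncertainties[0, 1]

    def test_translation_invariance(self):
        m, _ = _harmonic_matrix([25.0, 50.0, 100.0], 400, seed=4)
        r0 = solve_mbar(m)
        shifted = ReducedPotentialMatrix(
            u=m.u + np.array([[0.0], [2.5], [0.0]]), counts=m.counts,
            temperature=T)
        r1 = solve_mbar(shifted)
        delta = r1.f_k - r0.f_k
        np.testing.assert_allclose(delta, [0.0, 2.5, 0.0], atol=1e-6)

    def test_bar_equals_mbar_at_two_states(self):
        m, _ = _harmonic_matrix([25.0, 100.0], 2000, seed=5)
        r = solve_mbar(m, tolerance=1e-12)
        n = m.counts[0]
        w_f = m.u[1, :n] - m.u[0, :n]
        w_r = m.u[0, n:] - m.u[1, n:]
        assert solve_bar(w_f, w_r) == pytest.approx(r.f_k[1], abs=1e-7)

    def test_agreement_with_reference_minimizer(self, rng):
        for trial in range(10):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(50, 200))
            counts = rng.integers(20, n + 1, size=k)
            u = rng.normal(0, 1, (k, int(counts.sum()))) \
                + rng.normal(0, 2, (k, 1))
            m = ReducedPotentialMatrix(u=u, counts=counts, temperature=T)
            r = solve_mbar(m, tolerance=1e-12)
            ref = reference_mbar(u, counts)
            np.testing.assert_allclose(r.f_k, ref, atol=1e-6)

    def test_nonconvergence_carries_residual(self):
        m, _ = _harmonic_matrix([25.0, 100.0], 200, seed=6)
        with pytest.raises(ConvergenceError, match="residual"):
            solve_mbar(m, tolerance=1e-15, max_iterations=2)

    def test_empty_state_rejected(self):
        u = np.zeros((2, 10))
        with pytest.raises(ValidationError):
            solve_mbar(ReducedPotentialMatrix(u=u, counts=[10, 0],
                                              temperature=T))

    def test_path_additivity_mbar_vs_pairwise_bar(self):
        m, _ = _harmonic_matrix([25.0, 50.0, 100.0], 3000, seed=7)
        r = solve_mbar(m)
        n = m.counts[0]
        slices = [slice(0, n), slice(n, 2 * n), slice(2 * n, 3 * n)]
        bar_sum = 0.0
        for k in (0, 1):
            w_f = m.u[k + 1, slices[k]] - m.u[k, slices[k]]
            w_r = m.u[k, slices[k + 1]] - m.u[k + 1, slices[k + 1]]
            bar_sum += solve_bar(w_f, w_r)
        se = r.uncertainties[0, 2]
        assert abs(r.f_k[2] - bar_sum) < 3.0 * se


class TestOverlapMatrix:
    def test_identical_states_give_uniform_rows(self):
        m, _ = _harmonic_matrix([50.0, 50.0], 500, seed=8)
        r = solve_mbar(m)
        o = overlap_matrix(m, r)
        np.testing.assert_allclose(o, 0.5 + np.zeros((2, 2)), atol=0.05)

    def test_rows_sum_to_one(self):
        m, _ = _harmonic_matrix([25.0, 50.0, 100.0], 400, seed=9)
        o = overlap_matrix(m, solve_mbar(m))
        np.testing.assert_allclose(o.sum(axis=1), 1.0, atol=1e-10)

    def test_disjoint_wells_have_no_overlap_and_warn(self):
        m, _ = _harmonic_matrix([200.0, 200.0], 400, seed=10,
                                centers=[0.0, 30.0])
        r = solve_mbar(m)
        with pytest.warns(RuntimeWarning, match="overlap"):
            o = overlap_matrix(m, r)
        assert o[0, 1] < 1e-6


class TestCycleArithmetic:
    def test_all_zero_legs(self):
        c = ddg_from_cycle((0, 0), (0, 0), (0, 0), (0, 0))
        assert c.ddg == 0.0 and c.sd == 0.0

    def test_identical_molecules_cancel_exactly(self):
        legs = ((1.23, 0.1), (-4.5, 0.2))
        c = ddg_from_cycle(legs[0], legs[1], legs[0], legs[1])
        assert c.ddg == 0.0

    def test_antisymmetry_under_exchange(self):
        a = ((1.0, 0.3), (2.5, 0.4))
        b = ((-0.7, 0.1), (1.1, 0.2))
        fwd = ddg_from_cycle(a[0], a[1], b[0], b[1])
        rev = ddg_from_cycle(b[0], b[1], a[0], a[1])
        assert fwd.ddg == -rev.ddg
        assert fwd.sd == rev.sd

    def test_three_molecule_cycle_closure(self):
        legs = {name: ((hash(name) % 7 - 3) * 0.37, 0.1)
                for name in "abc"}
        solv = {name: ((hash(name) % 5 - 2) * 0.21, 0.1)
                for name in "abc"}
        ab = ddg_from_cycle(legs["a"], solv["a"], legs["b"], solv["b"]).ddg
        bc = ddg_from_cycle(legs["b"], solv["b"], legs["c"], solv["c"]).ddg
        ac = ddg_from_cycle(legs["a"], solv["a"], legs["c"], solv["c"]).ddg
        assert ab + bc == pytest.approx(ac, abs=1e-15)

    def test_gaussian_propagation(self, rng):
        assert propagate_error([3.0, 4.0]) == 5.0
        assert propagate_error([0.0, 0.0, 0.0, 0.0]) == 0.0
        sds = rng.uniform(0, 2, 6)
        assert propagate_error(sds) == pytest.approx(
            propagate_error(sds[::-1]), rel=1e-15)
        with pytest.raises(ValidationError, match="negative"):
            propagate_error([-1.0])
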