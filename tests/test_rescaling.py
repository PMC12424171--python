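import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hoprescale import (
    AtomicSystem,
    ContractError,
    ContributionSet,
    ElectronicSnapshot,
    TrajectoryState,
    total_energy,
)
from hoprescale.rescaling import (
    RescaleError,
    RescaleSpec,
    attempt_hop,
    available_kinetic_nacv,
    available_kinetic_weighted,
    normalized_weights,
    rescale_along_nacv,
    rescale_thresholded,
    rescale_uniform,
    rescale_weighted,
    select_significant_atoms,
)
from conftest import random_system


def one_atom(v=(2.0, 0.0, 0.0), mass=1.0):
    return AtomicSystem(["A"], [mass], np.zeros((1, 3)), [list(v)])


def gamma_scan_oracle(system, d, n_grid=200001):
    """Brute-force 1-D maximization of the kinetic energy freed along d."""
    d = np.asarray(d, float).reshape(-1, 3)
    E0 = system.kinetic_energy()

    def released(gamma):
        v = system.velocities - gamma * d / system.masses[:, None]
        return E0 - 0.5 * np.sum(system.masses * np.einsum("ij,ij->i", v, v))

    scale = np.abs(np.sum(system.velocities * d)) / np.sum(d * d / system.masses[:, None]) + 1.0
    grid = np.linspace(-6 * scale, 6 * scale, n_grid)
    return max(released(g) for g in grid)


class TestUniform:
    def test_halving_kinetic_energy(self):
        res = rescale_uniform(one_atom(), 1.0)
        assert res.accepted
        assert np.allclose(res.velocities, [[np.sqrt(2.0), 0.0, 0.0]])

    def test_identity(self, rng):
        system = random_system(rng)
        res = rescale_uniform(system, system.kinetic_energy())
        assert np.allclose(res.velocities, system.velocities, atol=1e-18)

    def test_negative_target_frustrates(self, rng):
        system = random_system(rng)
        res = rescale_uniform(system, -0.1)
        assert res.outcome == "frustrated"
        assert np.array_equal(res.velocities, system.velocities)

    def test_at_rest_raises(self):
        system = one_atom(v=(0.0, 0.0, 0.0))
        with pytest.raises(RescaleError):
            rescale_uniform(system, 0.5)


class TestNormalizedWeights:
    def test_hand_example(self):
        c, w = normalized_weights(np.array([3.0, 4.0]))
        assert np.allclose(c, [0.6, 0.8])
        assert np.allclose(w, [0.36, 0.64])

    def test_single_atom(self):
        c, w = normalized_weights(np.array([5.0]))
        assert np.allclose(c, [1.0]) and np.allclose(w, [1.0])

    def test_uniform_contributions(self):
        c, w = normalized_weights(np.ones(4))
        assert np.allclose(c, 0.5) and np.allclose(w, 0.25)

    def test_zero_contributions_raise(self):
        with pytest.raises(RescaleError):
            normalized_weights(np.zeros(3))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=8).filter(lambda q: sum(q) > 0))
    def test_weights_sum_to_one(self, q):
        _, w = normalized_weights(np.array(q))
        assert abs(w.sum() - 1.0) < 1e-12


class TestWeightedReservoir:
    def test_only_weighted_atoms_count(self):
        system = AtomicSystem(["A", "B"], [1.0, 1.0], np.zeros((2, 3)),
                              [[2.0, 0, 0], [9.0, 9.0, 9.0]])
        assert available_kinetic_weighted(np.array([1.0, 0.0]), system) == pytest.approx(2.0)

    def test_zero_velocities(self, rng):
        system = random_system(rng, zero_velocity=True)
        w = np.ones(system.n_atoms) / system.n_atoms
        assert available_kinetic_weighted(w, system) == 0.0

    def test_spectators_with_zero_weight_change_nothing(self, rng):
        system = random_system(rng, n_atoms=3)
        w = np.array([0.2, 0.5, 0.3])
        base = available_kinetic_weighted(w, system)
        grown = AtomicSystem(
            system.labels + [f"S{i}" for i in range(10)],
            np.concatenate([system.masses, np.full(10, 1000.0)]),
            np.vstack([system.positions, np.zeros((10, 3))]),
            np.vstack([system.velocities, rng.normal(0, 1e-2, (10, 3))]),
        )
        w_grown = np.concatenate([w, np.zeros(10)])
        assert available_kinetic_weighted(w_grown, grown) == base

    def test_monotone_in_speed_and_weight(self, rng):
        system = random_system(rng, n_atoms=4)
        w = np.array([0.4, 0.3, 0.2, 0.1])
        base = available_kinetic_weighted(w, system)
        faster = system.copy()
        faster.velocities[2] *= 2.0
        assert available_kinetic_weighted(w, faster) >= base
        w_up = w.copy()
        w_up[2] += 0.1
        assert available_kinetic_weighted(w_up, system) >= base


class TestWeightedRescale:
    def test_alpha_zero_reduces_to_uniform(self, rng):
        system = random_system(rng, n_atoms=4)
        _, w = normalized_weights(rng.uniform(0.1, 1.0, 4))
        E_new = 0.7 * system.kinetic_energy()
        res_w = rescale_weighted(system, w, 0.0, E_new)
        res_u = rescale_uniform(system, E_new)
        assert np.allclose(res_w.velocities, res_u.velocities, atol=1e-12)

    def test_single_atom_any_alpha_is_uniform(self):
        system = one_atom()
        res = rescale_weighted(system, np.array([1.0]), 0.9, 1.0)
        assert np.allclose(res.velocities, [[np.sqrt(2.0), 0.0, 0.0]])

    def test_two_atom_hand_oracle(self):
        # step-by-step evaluation: f = (1.14, 0.86), then global renormalization
        system = AtomicSystem(["A", "B"], [1.0, 1.0], np.zeros((2, 3)),
                              [[1.0, 0, 0], [1.0, 0, 0]])
        w = np.array([0.64, 0.36])
        res = rescale_weighted(system, w, 1.0, 1.0)
        f = np.array([1.14, 0.86])
        N = np.sqrt(1.0 / (0.5 * np.sum((f * 1.0) ** 2)))
        assert np.allclose(res.velocities[:, 0], f * N)
        speeds = np.linalg.norm(res.velocities, axis=1)
        assert speeds[0] / speeds[1] == pytest.approx(1.14 / 0.86)
        E_after = 0.5 * np.sum(speeds**2)
        assert E_after == pytest.approx(1.0, abs=1e-12)

    def test_prefactor_is_irrelevant_after_normalization(self, rng):
        # any positive constant prefactor of f is absorbed by the global factor
        system = random_system(rng, n_atoms=3)
        _, w = normalized_weights(rng.uniform(0.1, 1.0, 3))
        E_new = 1.2 * system.kinetic_energy()  # downward hop: never frustrated
        res = rescale_weighted(system, w, 0.8, E_new)
        assert res.accepted
        alphaterm = 1.0 + 0.8 * (w - w.mean())
        f_arbitrary = 7.3 * alphaterm  # different prefactor, same direction
        E_star = 0.5 * np.sum(system.masses * (f_arbitrary * np.linalg.norm(system.velocities, axis=1)) ** 2)
        v_expected = system.velocities * (f_arbitrary * np.sqrt(E_new / E_star))[:, None]
        assert np.allclose(res.velocities, v_expected, atol=1e-14)

    def test_pathological_alpha_raises(self, rng):
        system = random_system(rng, n_atoms=3)
        w = np.array([0.98, 0.01, 0.01])
        with pytest.raises(RescaleError):
            rescale_weighted(system, w, 5.0, system.kinetic_energy())

    def test_frustrated_by_weighted_reservoir(self):
        # total KE is plenty, but the weighted reservoir is not
        system = AtomicSystem(["A", "B"], [1.0, 1.0], np.zeros((2, 3)),
                              [[1.0, 0, 0], [10.0, 0, 0]])
        w = np.array([1.0, 0.0])
        E_old = system.kinetic_energy()  # 50.5
        res = rescale_weighted(system, w, 0.0, E_old - 1.0)  # gap 1.0 > reservoir 0.5
        assert res.outcome == "frustrated"
        assert np.array_equal(res.velocities, system.velocities)


class TestThresholded:
    def test_selection_hand_example(self):
        idx = select_significant_atoms(np.array([1.0, 0.4, 0.2]), 0.30)
        assert set(idx) == {0, 1}

    def test_threshold_zero_selects_all_positive(self):
        idx = select_significant_atoms(np.array([0.5, 0.0, 0.1]), 0.0)
        assert set(idx) == {0, 2}

    def test_threshold_one_keeps_argmax(self):
        idx = select_significant_atoms(np.array([0.5, 1.0, 0.2]), 1.0)
        assert set(idx) == {1}

    def test_all_zero_raises(self):
        with pytest.raises(RescaleError):
            select_significant_atoms(np.zeros(3), 0.3)

    def test_full_subset_is_uniform(self, rng):
        system = random_system(rng, n_atoms=4)
        delta = 0.3 * system.kinetic_energy()
        res_t = rescale_thresholded(system, np.arange(4), delta)
        res_u = rescale_uniform(system, system.kinetic_energy() - delta)
        assert np.allclose(res_t.velocities, res_u.velocities, atol=1e-14)

    def test_subset_hand_oracle(self):
        system = AtomicSystem(["A", "B"], [1.0, 1.0], np.zeros((2, 3)),
                              [[2.0, 0, 0], [2.0, 0, 0]])
        res = rescale_thresholded(system, np.array([0]), 1.0)
        assert np.allclose(res.velocities[0], [np.sqrt(2.0), 0.0, 0.0])
        assert np.array_equal(res.velocities[1], system.velocities[1])

    def test_insufficient_subset_reservoir_frustrates(self):
        system = AtomicSystem(["A", "B"], [1.0, 1.0], np.zeros((2, 3)),
                              [[1.0, 0, 0], [5.0, 0, 0]])
        res = rescale_thresholded(system, np.array([0]), 1.0)  # subset KE 0.5 < 1.0
        assert res.outcome == "frustrated"


class TestNACV:
    def test_collinear_single_atom_gives_full_kinetic(self):
        system = one_atom()
        assert available_kinetic_nacv(system, [[1.0, 0, 0]]) == pytest.approx(2.0)

    def test_perpendicular_gives_zero(self):
        system = one_atom(v=(0.0, 2.0, 0.0))
        assert available_kinetic_nacv(system, [[1.0, 0, 0]]) == pytest.approx(0.0)

    def test_matches_gamma_scan_oracle(self, rng):
        for _ in range(20):
            system = random_system(rng, n_atoms=3)
            d = rng.normal(size=(3, 3))
            expected = gamma_scan_oracle(system, d, n_grid=40001)
            assert available_kinetic_nacv(system, d) == pytest.approx(expected, abs=1e-8)

    def test_zero_direction_raises(self, rng):
        with pytest.raises(RescaleError):
            available_kinetic_nacv(random_system(rng), np.zeros((1, 3)))

    def test_zero_gap_leaves_velocities(self, rng):
        system = random_system(rng, n_atoms=2)
        res = rescale_along_nacv(system, rng.normal(size=(2, 3)), 0.0)
        assert np.allclose(res.velocities, system.velocities, atol=1e-15)

    def test_single_atom_closed_form_root(self):
        system = one_atom()
        res = rescale_along_nacv(system, [[1.0, 0, 0]], 1.0)
        assert np.allclose(res.velocities, [[np.sqrt(2.0), 0.0, 0.0]], atol=1e-12)

    def test_atoms_outside_direction_untouched(self, rng):
        system = random_system(rng, n_atoms=2)
        d = np.zeros((2, 3))
        d[0] = [1.0, 0.5, 0.0]
        res = rescale_along_nacv(system, d, -0.01)
        assert np.array_equal(res.velocities[1], system.velocities[1])

    def test_frustrated_when_projection_insufficient(self):
        system = one_atom(v=(0.1, 0.0, 0.0))
        res = rescale_along_nacv(system, [[1.0, 0, 0]], 1.0)
        assert res.outcome == "frustrated"
        assert np.array_equal(res.velocities, system.velocities)


def make_hop_setup(system, delta_E, q=None, d=None, active=0):
    """Two-state snapshot + state for hop attempts with gap delta_E."""
    energies = np.sort([0.0, delta_E]) if active == 0 else np.sort([delta_E, 0.0])
    lo = float(energies[0])
    n = system.n_atoms
    if q is None:
        q = np.ones(n)
    nacv = None
    if d is not None:
        nacv = np.zeros((2, 2, n, 3))
        nacv[0, 1] = d
        nacv[1, 0] = -np.asarray(d)
    snap = ElectronicSnapshot(
        energies=energies,
        gradients=np.zeros((2, n, 3)),
        nacv=nacv,
        contributions={(0, 1): ContributionSet(q=np.asarray(q, float), mode="direct")},
    )
    active_idx = int(np.argmin(np.abs(energies - (0.0 if active == 0 else delta_E))))
    C = np.zeros(2, complex)
    # active state has energy 0 by construction of `energies`
    active_idx = int(np.flatnonzero(energies == 0.0)[0])
    C[active_idx] = 1.0
    state = TrajectoryState(0.0, system, active_idx, C)
    return state, snap, 1 - active_idx


class TestAttemptHop:
    @pytest.mark.parametrize("scheme", ["v_full", "d", "v_w", "v_t"])
    def test_downward_hop_always_accepted(self, rng, scheme):
        system = random_system(rng, n_atoms=3)
        state, snap, target = make_hop_setup(system, -0.05, d=rng.normal(size=(3, 3)))
        E_before = total_energy(state, snap)
        E_kin_before = system.kinetic_energy()
        ev = attempt_hop(state, snap, target, RescaleSpec(scheme, alpha=0.5))
        assert ev.outcome == "accepted"
        assert total_energy(state, snap) == pytest.approx(E_before, abs=1e-9)
        assert state.system.kinetic_energy() == pytest.approx(E_kin_before + 0.05, abs=1e-9)

    @pytest.mark.parametrize("scheme", ["v_full", "d", "v_w", "v_t"])
    def test_gap_above_total_kinetic_frustrates_everywhere(self, rng, scheme):
        system = random_system(rng, n_atoms=3)
        gap = 2.0 * system.kinetic_energy() + 0.1
        state, snap, target = make_hop_setup(system, gap, d=rng.normal(size=(3, 3)))
        v_before = system.velocities.copy()
        ev = attempt_hop(state, snap, target, RescaleSpec(scheme, alpha=0.5))
        assert ev.outcome == "frustrated"
        assert np.array_equal(state.system.velocities, v_before)
        assert state.active_state == ev.from_state

    def test_weighted_reservoir_splits_schemes(self):
        # spectator-rich system: total KE covers the gap, weighted KE does not
        system = AtomicSystem(
            ["C", "S"], [1.0, 1.0], np.zeros((2, 3)), [[1.0, 0, 0], [10.0, 0, 0]]
        )
        q = np.array([1.0, 0.0])
        gap = 1.0  # chromophore KE 0.5 < gap < total KE 50.5
        state_f, snap_f, target_f = make_hop_setup(system.copy(), gap, q=q)
        ev_full = attempt_hop(state_f, snap_f, target_f, RescaleSpec("v_full"))
        state_w, snap_w, target_w = make_hop_setup(system.copy(), gap, q=q)
        ev_w = attempt_hop(state_w, snap_w, target_w, RescaleSpec("v_w", alpha=1.0))
        assert ev_full.outcome == "accepted"
        assert ev_w.outcome == "frustrated"

    def test_zero_contributions_fall_back_to_uniform(self, rng, caplog):
        system = random_system(rng, n_atoms=2)
        state, snap, target = make_hop_setup(system, -0.01, q=np.zeros(2))
        with caplog.at_level("WARNING"):
            ev = attempt_hop(state, snap, target, RescaleSpec("v_w", alpha=1.0))
        assert ev.outcome == "accepted"
        assert "falling back" in caplog.text

    def test_missing_nacv_is_configuration_error(self, rng):
        system = random_system(rng, n_atoms=2)
        state, snap, target = make_hop_setup(system, -0.01)
        with pytest.raises(ContractError):
            attempt_hop(state, snap, target, RescaleSpec("d"))

    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        scheme=st.sampled_from(["v_full", "d", "v_w", "v_t"]),
        gap_scale=st.floats(-2.0, 2.0),
        alpha=st.floats(0.0, 1.0),
    )
    def test_energy_conservation_property(self, seed, scheme, gap_scale, alpha):
        """Every accepted hop conserves total energy to 1e-9 hartree."""
        rng = np.random.default_rng(seed)
        system = random_system(rng)
        n = system.n_atoms
        gap = gap_scale * max(system.kinetic_energy(), 1e-6)
        state, snap, target = make_hop_setup(
            system, gap, q=rng.uniform(0.0, 1.0, n), d=rng.normal(size=(n, 3))
        )
        E_before = total_energy(state, snap)
        v_before = state.system.velocities.copy()
        ev = attempt_hop(state, snap, target, RescaleSpec(scheme, alpha=alpha))
        if ev.outcome == "accepted":
            assert abs(total_energy(state, snap) - E_before) <= 1e-9
        else:
            assert np.array_equal(state.system.velocities, v_before)


class TestSizeConsistency:
    """Appending zero-contribution spectators must not change the physics
    for the weighted, thresholded and NACV schemes — and must change it
    for uniform rescaling (the documented defect)."""

    def _augment(self, system, rng, n_spec=4):
        return AtomicSystem(
            system.labels + [f"S{i}" for i in range(n_spec)],
            np.concatenate([system.masses, np.full(n_spec, 2000.0)]),
            np.vstack([system.positions, rng.normal(0, 5, (n_spec, 3))]),
            np.vstack([system.velocities, rng.normal(0, 5e-3, (n_spec, 3))]),
        )

    def test_weighted_reservoir_unchanged(self, rng):
        core = random_system(rng, n_atoms=3)
        q = rng.uniform(0.1, 1.0, 3)
        _, w = normalized_weights(q)
        grown = self._augment(core, rng)
        _, w_grown = normalized_weights(np.concatenate([q, np.zeros(4)]))
        assert available_kinetic_weighted(w_grown, grown) == available_kinetic_weighted(w, core)

    @pytest.mark.parametrize("scheme,alpha", [("v_w", 1.0), ("v_t", 0.0), ("d", 0.0)])
    def test_decisions_and_core_velocities_bit_identical(self, rng, scheme, alpha):
        core = random_system(rng, n_atoms=3)
        q = rng.uniform(0.1, 1.0, 3)
        d = rng.normal(size=(3, 3))
        gap = 0.8 * core.kinetic_energy()
        state_c, snap_c, target_c = make_hop_setup(core.copy(), gap, q=q, d=d)
        ev_core = attempt_hop(state_c, snap_c, target_c, RescaleSpec(scheme, alpha=alpha))

        grown = self._augment(core, rng)
        q_grown = np.concatenate([q, np.zeros(4)])
        d_grown = np.vstack([d, np.zeros((4, 3))])
        state_g, snap_g, target_g = make_hop_setup(grown, gap, q=q_grown, d=d_grown)
        ev_grown = attempt_hop(state_g, snap_g, target_g, RescaleSpec(scheme, alpha=alpha))

        assert ev_core.outcome == ev_grown.outcome
        assert np.array_equal(state_g.system.velocities[:3], state_c.system.velocities)
        # spectator velocities untouched by the hop
        assert np.array_equal(state_g.system.velocities[3:], grown.velocities[3:] if ev_grown.outcome == "frustrated" else state_g.system.velocities[3:])

    def test_uniform_flips_frustrated_to_accepted(self, rng):
        core = random_system(rng, n_atoms=2)
        gap = 1.5 * core.kinetic_energy()  # frustrated for the core alone
        state_c, snap_c, target_c = make_hop_setup(core.copy(), gap)
        assert attempt_hop(state_c, snap_c, target_c, RescaleSpec("v_full")).outcome == "frustrated"

        grown = self._augment(core, rng)
        while grown.kinetic_energy() <= gap:  # ensure the spectators cover the gap
            grown.velocities[2:] *= 2.0
        state_g, snap_g, target_g = make_hop_setup(grown, gap)
        assert attempt_hop(state_g, snap_g, target_g, RescaleSpec("v_full")).outcome == "accepted"
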