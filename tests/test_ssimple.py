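import numpy as np
import pytest
from scipy import optimize

from ssipkit.formats import PhaseSpec
from ssipkit.ssimple import (
    ConvergenceError,
    ModelConstants,
    association_constant,
    association_matrix,
    build_phase_state,
    contact_matrix,
    load_solvent_library,
    solvation_energy,
    solve_speciation,
    make_phase_state,
    transfer_energy,
)


def make_state(epsilons, theta, temperature=298.0, solve=True):
    state = make_phase_state(epsilons, theta, temperature)
    if solve:
        solve_speciation(state)
    return state

RT298 = 8.3145e-3 * 298.0
K_NEUTRAL = float(np.exp(5.6 / RT298))  # ~9.5844: pure van der Waals contact


class TestAssociationConstant:
    def test_neutral_pair_closed_form(self):
        assert association_constant(0.0, 0.0, 298.0) == pytest.approx(
            K_NEUTRAL, rel=1e-12)
        assert K_NEUTRAL == pytest.approx(9.5844, abs=1e-3)

    def test_same_sign_polar_term_is_dropped(self):
        # repulsive pairs misalign into a pure van der Waals contact
        assert association_constant(2.0, 3.0, 298.0) == pytest.approx(
            K_NEUTRAL, rel=1e-12)
        assert association_constant(-1.5, -4.0, 298.0) == pytest.approx(
            K_NEUTRAL, rel=1e-12)

    def test_opposite_sign_pair_closed_form(self):
        expected = np.exp((5.6 + 6.0) / RT298)
        assert association_constant(2.0, -3.0, 298.0) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(107.956, abs=0.01)

    def test_symmetry_and_matrix_agreement(self):
        eps = np.array([-2.0, 0.0, 1.5, 3.0])
        K = association_matrix(eps, 298.0)
        np.testing.assert_allclose(K, K.T)
        for i in range(len(eps)):
            for j in range(len(eps)):
                assert K[i, j] == pytest.approx(
                    association_constant(eps[i], eps[j], 298.0), rel=1e-12)

    def test_same_sign_value_independent_of_magnitude(self):
        vals = [association_constant(a, b, 310.0)
                for a, b in [(0.1, 0.2), (5.0, 9.0), (-3.0, -8.0)]]
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[1] == pytest.approx(vals[2], rel=1e-12)


class TestBuildPhaseState:
    def test_pure_water_concentrations(self, solvent_library):
        state = build_phase_state(PhaseSpec(298.0, [("water", 1.0)]),
                                  solvent_library)
        c_water = 1.0 / 0.01807  # 55.34 M
        np.testing.assert_allclose(state.theta, c_water / 300.0, rtol=1e-12)
        assert state.theta.sum() == pytest.approx(4 * c_water / 300.0)
        assert state.theta_e == pytest.approx(1.0 - 4 * c_water / 300.0)

    def test_dilute_gas_limit(self, solvent_library):
        library = dict(solvent_library)
        library["thin"] = (np.array([0.0]), 1e6)  # enormous molar volume
        state = build_phase_state(PhaseSpec(298.0, [("thin", 1.0)]), library)
        assert state.theta.sum() < 1e-5
        assert state.theta_e == pytest.approx(1.0, abs=1e-5)

    def test_mixture_thetas_proportional_to_mole_fraction(self, solvent_library):
        spec = PhaseSpec(298.0, [("water", 0.75), ("ethanol", 0.25)])
        state = build_phase_state(spec, solvent_library)
        vbar = 0.75 * 0.01807 + 0.25 * 0.05847
        c_mix = 1.0 / vbar
        water_theta = state.theta[:4]
        ethanol_theta = state.theta[4:]
        np.testing.assert_allclose(water_theta, 0.75 * c_mix / 300.0, rtol=1e-12)
        np.testing.assert_allclose(ethanol_theta, 0.25 * c_mix / 300.0, rtol=1e-12)

    def test_unknown_component(self, solvent_library):
        with pytest.raises(KeyError, match="benzene"):
            build_phase_state(PhaseSpec(298.0, [("benzene", 1.0)]),
                              solvent_library)

    def test_over_packing_is_an_error(self, solvent_library):
        library = dict(solvent_library)
        library["dense"] = (np.zeros(10), 0.001)  # 10 sites at 1000 M
        with pytest.raises(ValueError, match="over-packed"):
            build_phase_state(PhaseSpec(298.0, [("dense", 1.0)]), library)


class TestSolveSpeciation:
    def test_single_species_matches_quadratic_closed_form(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            theta = rng.uniform(0.01, 0.9)
            K = 10 ** rng.uniform(-1, 3)
            state = make_state([0.0], [theta], solve=False)
            state.K = np.array([[K]])
            solve_speciation(state)
            oracle = (-1.0 + np.sqrt(1.0 + 4.0 * K * theta)) / (2.0 * K)
            assert state.f[0] == pytest.approx(oracle, abs=1e-8)

    def test_no_binding_means_all_free(self):
        state = make_state([1.0, -2.0], [0.3, 0.4], solve=False)
        state.K = np.zeros((2, 2))
        solve_speciation(state)
        np.testing.assert_allclose(state.f, state.theta, atol=1e-12)

    def test_two_species_against_dense_root_finder(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            theta = rng.uniform(0.05, 0.45, size=2)
            K = 10 ** rng.uniform(0, 3, size=(2, 2))
            K = (K + K.T) / 2.0
            state = make_state([0.0, 0.0], theta, solve=False)
            state.K = K
            solve_speciation(state)

            def balance(f):
                return theta - f * (1.0 + K @ f)

            sol = optimize.root(balance, theta)
            assert np.max(np.abs(balance(sol.x))) < 1e-10
            np.testing.assert_allclose(state.f, sol.x, atol=1e-8)

    def test_solution_independent_of_damping(self, solvent_library):
        spec = PhaseSpec(298.0, [("water", 1.0)])
        s1 = build_phase_state(spec, solvent_library)
        s2 = build_phase_state(spec, solvent_library)
        solve_speciation(s1, damping=0.2)
        solve_speciation(s2, damping=0.8)
        np.testing.assert_allclose(s1.f, s2.f, atol=1e-8)

    def test_non_convergence_reports_residual_history(self):
        state = make_state([0.0], [0.5], solve=False)
        with pytest.raises(ConvergenceError) as err:
            solve_speciation(state, tol=1e-30, max_iter=5)
        assert len(err.value.residuals) == 5


class TestContactMatrix:
    def test_mass_conservation_random_phases(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(1, 6)
            eps = rng.uniform(-5, 5, size=n)
            theta = rng.uniform(0.01, 0.9 / n, size=n)
            state = make_state(eps, theta)
            contacts = contact_matrix(state)
            np.testing.assert_allclose(contacts, contacts.T)
            recovered = state.f + contacts.sum(axis=1) + np.diag(contacts)
            np.testing.assert_allclose(recovered, state.theta, atol=1e-9)

    def test_single_species_identity(self):
        state = make_state([0.0], [0.5])
        contacts = contact_matrix(state)
        assert 2 * contacts[0, 0] + state.f[0] == pytest.approx(0.5, abs=1e-9)

    def test_zero_binding_means_zero_contacts(self):
        state = make_state([0.0, 0.0], [0.2, 0.3], solve=False)
        state.K = np.zeros((2, 2))
        solve_speciation(state)
        np.testing.assert_allclose(contact_matrix(state), 0.0, atol=1e-12)

    def test_unsolved_state_is_an_error(self):
        state = make_state([0.0], [0.5], solve=False)
        with pytest.raises(ValueError, match="not solved"):
            contact_matrix(state)


class TestSolvationEnergy:
    def test_empty_phase_is_the_zero_reference(self, gas_state):
        for eps in (-8.0, -1.0, 0.0, 2.5, 5.0):
            assert solvation_energy(eps, gas_state) == 0.0

    def test_nonpolar_dense_phase_solvates_a_neutral_probe(self):
        # all-neutral solvent at water-like packing: K ~ 9.58 contacts
        # outweigh the lost void reference, so dG_solv < 0
        state = make_state([0.0] * 4, [0.1845] * 4)
        assert solvation_energy(0.0, state) < 0.0

    def test_monotone_in_probe_strength_for_acceptor_solvent(self):
        state = make_state([-3.0, -3.0], [0.3, 0.3])
        probes = np.linspace(0.0, 5.0, 26)
        energies = [solvation_energy(e, state) for e in probes]
        assert np.all(np.diff(energies) <= 1e-12)

    def test_gas_limit_for_any_probe(self):
        for eps in (-5.0, 0.0, 4.0):
            state = make_state([2.0, -2.0], [1e-12, 1e-12])
            assert solvation_energy(eps, state) == pytest.approx(0.0, abs=1e-6)

    def test_unsolved_state_is_an_error(self):
        state = make_state([0.0], [0.5], solve=False)
        with pytest.raises(ValueError, match="not solved"):
            solvation_energy(0.0, state)


class TestTransferEnergy:
    def test_identical_phases_transfer_nothing(self, water_state):
        assert transfer_energy(1.0, water_state, water_state) == pytest.approx(0.0)

    def test_antisymmetric_under_phase_swap(self, water_state, mix_state):
        fwd = transfer_energy(-2.0, water_state, mix_state)
        back = transfer_energy(-2.0, mix_state, water_state)
        assert fwd == pytest.approx(-back, rel=1e-12)

    def test_gas_to_dense_equals_solvation(self, gas_state):
        dense = make_state([0.0] * 4, [0.1845] * 4)
        assert transfer_energy(0.0, gas_state, dense) == pytest.approx(
            solvation_energy(0.0, dense), rel=1e-12)

    def test_temperature_mismatch(self):
        a = make_state([0.0], [0.2], temperature=298.0)
        b = make_state([0.0], [0.2], temperature=310.0)
        with pytest.raises(ValueError, match="temperature mismatch"):
            transfer_energy(0.0, a, b)


class TestSolventLibrary:
    def test_round_trip_through_directory(self, tmp_path, solvent_library):
        from ssipkit.synthetic import write_example_library
        write_example_library(tmp_path)
        library = load_solvent_library(tmp_path)
        assert set(library) == {"water", "ethanol"}
        eps_w, vm_w = library["water"]
        np.testing.assert_allclose(
            np.sort(eps_w), np.sort(solvent_library["water"][0].epsilons),
            atol=1e-6)
        assert vm_w == pytest.approx(0.01807)


def test_constants_defaults():
    constants = ModelConstants()
    assert constants.e_vdw == -5.6
    assert constants.c_max == 300.0
    assert constants.v_ssip == 5.0
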