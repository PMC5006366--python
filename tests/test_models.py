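"""Model construction, right-hand sides, simulation and trajectory utilities."""

import io

import numpy as np
import pytest

from robokin.models import (ControlProfile, ModelStructureError, Trajectory,
                            case1_model, case2_model, evaluate_rhs, get_model,
                            load_model, model_from_dict, model_to_dict,
                            save_model, simulate, simulate_batch,
                            threshold_time)


class TestRightHandSide:
    def test_case1_single_active_enzyme(self, case1):
        # v1 = k1 S1 e1 = 1 feeds S2 only; other fluxes are zero
        d = evaluate_rhs(case1, [1, 0, 0, 0, 0], [1, 0, 0], [1, 1, 1])
        np.testing.assert_allclose(d, [0, 1, 0, 0, 0])

    def test_case2_michaelis_menten_half_saturation(self, case2):
        # S2 = K_M = 1 mM, e2 = 1 mM: v2 = kcat/2
        x = np.zeros(9)
        x[case2.state_names.index("S2")] = 1.0
        x[case2.state_names.index("e2")] = 1.0
        d = evaluate_rhs(case2, x, np.zeros(4), [1, 1, 0.5])
        assert d[case2.state_names.index("S2")] == pytest.approx(-0.5)
        assert d[case2.state_names.index("S3")] == pytest.approx(0.5)
        assert d[case2.state_names.index("S4")] == pytest.approx(0.5)

    def test_case2_enzyme_balance(self, case2):
        d = evaluate_rhs(case2, np.zeros(9), [0.5, 0, 0, 0], [1, 1, 0.5])
        e_idx = [case2.state_names.index(f"e{i}") for i in range(1, 5)]
        np.testing.assert_allclose(d[e_idx], [0.5, 0, 0, 0])

    def test_dimension_mismatch_raises(self, case1):
        with pytest.raises(ModelStructureError):
            evaluate_rhs(case1, [1, 0, 0], [1, 0, 0], [1, 1, 1])
        with pytest.raises(ModelStructureError):
            evaluate_rhs(case1, [1, 0, 0, 0, 0], [1, 0], [1, 1, 1])


class TestFixtures:
    def test_case1_bookkeeping(self, case1):
        assert case1.n_x == 5  # S1..S4 + accumulation integrator
        assert case1.control_ub[0] == pytest.approx(1.0)  # E_T = 1 mM
        np.testing.assert_allclose(case1.theta_nominal, [1, 1, 1])
        assert case1.t_f == 10.0

    def test_case2_bookkeeping(self, case2):
        assert case2.n_x == 9  # S2..S5 + e1..e4 + cost integrator
        np.testing.assert_allclose(case2.theta_nominal, [1.0, 1.0, 0.5])
        assert case2.terminal_constraints[0].bound == pytest.approx(0.675)
        assert case2.constants["S1"] == pytest.approx(1.0)

    def test_buffered_species_have_zero_row(self, case1):
        row = case1.stoichiometry[case1.species.index("S1")]
        assert np.all(row == 0)

    def test_registry(self):
        assert get_model("case1").name == "case1"
        with pytest.raises(KeyError):
            get_model("nope")


class TestSimulation:
    def test_zero_controls_freeze_case1(self, case1):
        cp = ControlProfile.constant([0, 0, 0], 10.0, 5)
        traj = simulate(case1, cp, [1.3, 0.8, 1.1])
        np.testing.assert_allclose(traj.states, np.tile(case1.x0, (len(traj.times), 1)),
                                   atol=1e-10)

    def test_case1_linear_filling_of_s2(self, case1):
        cp = ControlProfile.constant([1, 0, 0], 1.0, 2)
        traj = simulate(case1, cp, [1, 1, 1])
        assert traj.terminal("S2") == pytest.approx(1.0, abs=1e-7)

    def test_case2_enzyme_decay_closed_form(self, case2):
        case2.x0[case2.state_names.index("e1")] = 0.7
        cp = ControlProfile.constant([0, 0, 0, 0], 2.0, 4)
        traj = simulate(case2, cp, case2.theta_nominal)
        assert traj.terminal("e1") == pytest.approx(0.7 * np.exp(-0.5 * 2.0), rel=1e-6)

    def test_mass_accounting_case1(self, case1):
        # d(S2+S3+S4)/dt = v1 >= 0 under non-negative controls
        cp = ControlProfile.constant([0.5, 0.3, 0.2], 10.0, 5)
        traj = simulate(case1, cp, [1, 1, 1])
        total = traj.state("S2") + traj.state("S3") + traj.state("S4")
        assert np.all(np.diff(total) >= -1e-9)
        assert np.all(traj.states[:, :4] >= -1e-9)  # concentrations stay non-negative

    def test_buffered_substrate_constant(self, case1):
        cp = ControlProfile.constant([0.6, 0.2, 0.2], 10.0, 3)
        traj = simulate(case1, cp, [1, 1, 1])
        np.testing.assert_allclose(traj.state("S1"), 1.0, atol=1e-12)

    def test_tolerance_convergence(self, case1):
        cp = ControlProfile.constant([0.4, 0.3, 0.3], 10.0, 4)
        t1 = simulate(case1, cp, [1, 1, 1], rtol=1e-6, atol=1e-8)
        t2 = simulate(case1, cp, [1, 1, 1], rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(t1.states[-1] - t2.states[-1])) < 1e-5

    def test_batch_matches_adaptive_integrator(self, case1):
        cp = ControlProfile.constant([0.4, 0.3, 0.3], 10.0, 10)
        thetas = np.array([[1, 1, 1], [1.2, 0.9, 1.1], [0.7, 1.3, 0.8]])
        batch = simulate_batch(case1, cp, thetas)
        for i, th in enumerate(thetas):
            ref = simulate(case1, cp, th, output_times=np.array([10.0]))
            np.testing.assert_allclose(batch[i], ref.states[-1], atol=5e-7)


class TestThresholdTime:
    def test_interpolated_crossing(self):
        traj = Trajectory(np.array([0.0, 1.0, 2.0]),
                          np.array([[0.0], [0.5], [1.5]]), ["S4"])
        assert threshold_time(traj, "S4", 1.0) == pytest.approx(1.5)

    def test_already_above_and_never_reached(self):
        up = Trajectory(np.array([0.0, 1.0]), np.array([[2.0], [2.0]]), ["S4"])
        assert threshold_time(up, "S4", 1.0) == 0.0
        low = Trajectory(np.array([0.0, 1.0]), np.array([[0.1], [0.2]]), ["S4"])
        assert threshold_time(low, "S4", 1.0) is None

    def test_unknown_species(self):
        traj = Trajectory(np.array([0.0]), np.array([[0.0]]), ["S4"])
        with pytest.raises(KeyError):
            threshold_time(traj, "S9", 1.0)


class TestSerialization:
    @pytest.mark.parametrize("factory", [case1_model, case2_model])
    def test_yaml_round_trip(self, factory, tmp_path):
        model = factory()
        path = tmp_path / "model.yaml"
        save_model(model, path)
        clone = load_model(path)
        assert model_to_dict(model) == model_to_dict(clone)
        # the round-tripped model produces the same dynamics
        x = np.linspace(0.2, 1.0, model.n_x)
        u = np.full(model.n_u, 0.1)
        np.testing.assert_allclose(evaluate_rhs(model, x, u, model.theta_nominal),
                                   evaluate_rhs(clone, x, u, clone.theta_nominal))

    def test_trajectory_tables(self, case1, tmp_path):
        cp = ControlProfile.constant([0.5, 0.3, 0.2], 2.0, 2)
        traj = simulate(case1, cp, [1, 1, 1], output_times=np.linspace(0, 2, 5))
        tidy = traj.to_frame()
        assert set(tidy.columns) == {"time", "state", "value"}
        assert len(tidy) == 5 * case1.n_x
        wide = traj.to_wide_frame()
        assert list(wide.columns[:1]) == ["time"]
        traj.write_csv(tmp_path / "traj.csv")
        assert (tmp_path / "traj.csv").exists()


class TestControlProfile:
    def test_grid_must_increase(self):
        with pytest.raises(ModelStructureError):
            ControlProfile(np.array([0.0, 1.0, 1.0]), np.zeros((2, 1)))

    def test_value_lookup(self):
        cp = ControlProfile(np.array([0.0, 1.0, 2.0]), np.array([[0.1], [0.9]]))
        assert cp.value_at(0.5)[0] == 0.1
        assert cp.value_at(1.5)[0] == 0.9
        assert cp.t_f == 2.0
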