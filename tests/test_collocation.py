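"""Radau collocation: nodes, quadrature, transcription structure, small solves."""

import numpy as np
import pytest

from robokin.collocation import (CollocationGrid, System, TranscribedNLP,
                                 element_step, lagrange_diff_matrix,
                                 radau_nodes, radau_weights, rollout,
                                 solve_nlp, solve_ocp, transcribe)


class TestRadauNodes:
    def test_cubic_node_positions(self):
        np.testing.assert_allclose(radau_nodes(3), [0.15505102572168, 0.64494897427832, 1.0],
                                   atol=1e-10)

    def test_endpoint_included(self):
        for d in (1, 2, 3, 4):
            assert radau_nodes(d)[-1] == pytest.approx(1.0)

    def test_quadrature_exactness(self):
        # 3-point Radau quadrature is exact through degree 2*3 - 2 = 4
        tau, w = radau_nodes(3), radau_weights(3)
        assert w.sum() == pytest.approx(1.0)
        for deg in range(5):
            assert w @ tau ** deg == pytest.approx(1.0 / (deg + 1), abs=1e-12)

    def test_differentiation_rows_sum_to_zero(self):
        D = lagrange_diff_matrix(3)
        np.testing.assert_allclose(D.sum(axis=1), 0.0, atol=1e-12)

    def test_invalid_degree(self):
        with pytest.raises(ValueError):
            radau_nodes(0)


def _decay_system():
    return System(f=lambda x, u, t: -x, jac=lambda x, u, t: -np.eye(1),
                  n=1, x0=np.array([1.0]))


class TestElementStepping:
    def test_exponential_decay_high_order(self):
        # 3-stage Radau IIA is order 5: 10 elements resolve e^-1 to ~1e-9
        grid = CollocationGrid(10, t_f=1.0)
        ro = rollout([_decay_system()], grid, np.zeros((10, 1)), 1.0)
        assert ro.terminal_states[0][0] == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_single_element_step_matches_rollout(self):
        grid = CollocationGrid(1, t_f=0.3)
        X = element_step(_decay_system(), grid, np.array([1.0]), np.zeros(1), 0.3)
        assert X[-1, 0] == pytest.approx(np.exp(-0.3), abs=1e-6)  # order-5 local error

    def test_nonlinear_element_newton(self):
        # logistic x' = x (1 - x): closed-form solution
        sys_ = System(f=lambda x, u, t: x * (1 - x),
                      jac=lambda x, u, t: np.array([[1 - 2 * x[0]]]),
                      n=1, x0=np.array([0.1]))
        grid = CollocationGrid(20, t_f=4.0)
        ro = rollout([sys_], grid, np.zeros((20, 1)), 4.0)
        expected = 1.0 / (1.0 + 9.0 * np.exp(-4.0))
        assert ro.terminal_states[0][0] == pytest.approx(expected, abs=1e-8)


class _LinearOCP:
    """min int u^2 with x' = u, x(0) = 0, x(1) = 1 (optimal: u = 1, cost 1)."""

    n_u = 1
    control_lb = np.array([-5.0])
    control_ub = np.array([5.0])
    fixed_initial_controls = None
    t_f = 1.0
    t_f_free = False
    t_f_bounds = None

    def __init__(self):
        self.systems = [System(
            f=lambda x, u, t: np.array([u[0], u[0] ** 2]),
            jac=lambda x, u, t: np.zeros((2, 2)), n=2, x0=np.zeros(2))]

    def objective(self, terms, u, tf):
        return terms[0][1]

    def terminal_margins(self, terms, tf):
        return np.array([terms[0][0] - 1.0, 1.0 - terms[0][0]])

    def path_margins(self, x, u):
        return None


class _QuadraticOCP:
    """Convex QP: min (u - 0.3)^2 summed over elements, closed-form optimum."""

    n_u = 1
    control_lb = np.array([0.0])
    control_ub = np.array([1.0])
    fixed_initial_controls = None
    t_f = 1.0
    t_f_free = False
    t_f_bounds = None

    def __init__(self):
        self.systems = [System(
            f=lambda x, u, t: np.array([(u[0] - 0.3) ** 2]),
            jac=lambda x, u, t: np.zeros((1, 1)), n=1, x0=np.zeros(1))]

    def objective(self, terms, u, tf):
        return terms[0][0]

    def terminal_margins(self, terms, tf):
        return np.empty(0)

    def path_margins(self, x, u):
        return None


class TestTranscription:
    def test_structural_counts(self):
        nlp = transcribe(_LinearOCP(), CollocationGrid(10, t_f=1.0))
        assert nlp.n_continuity_constraints == 9 * 2
        assert nlp.n_collocation_constraints == 10 * 3 * 2
        assert nlp.n_initial_conditions == 2

    def test_continuity_count_matches_formula(self):
        # 10 elements, 9 dynamic states -> 81 continuity equations
        class Nine(_LinearOCP):
            def __init__(self):
                self.systems = [System(f=lambda x, u, t: np.zeros(9),
                                       jac=lambda x, u, t: np.zeros((9, 9)),
                                       n=9, x0=np.zeros(9))]

        nlp = transcribe(Nine(), CollocationGrid(10, t_f=1.0))
        assert nlp.n_continuity_constraints == 81

    def test_reduced_point_satisfies_simultaneous_residuals(self):
        nlp = transcribe(_LinearOCP(), CollocationGrid(5, t_f=1.0))
        z = nlp.pack(np.full((5, 1), 0.7))
        w = nlp.simultaneous_from_rollout(z)
        assert len(w) == nlp.n_decision
        res = nlp.residuals(w)
        assert len(res) == (nlp.n_collocation_constraints
                            + nlp.n_continuity_constraints
                            + nlp.n_initial_conditions)
        np.testing.assert_allclose(res, 0.0, atol=1e-9)


class TestSolve:
    def test_linear_ocp_closed_form(self):
        sol = solve_ocp(_LinearOCP(), n_elements=10, refine_from=None)
        assert sol.success
        assert sol.objective == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(sol.controls.values, 1.0, atol=1e-5)

    def test_convex_qp_matches_analytic_optimum(self):
        sol = solve_ocp(_QuadraticOCP(), n_elements=4, refine_from=None)
        assert sol.objective == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sol.controls.values, 0.3, atol=1e-5)

    def test_unsupported_strategy_rejected(self):
        nlp = transcribe(_LinearOCP(), CollocationGrid(4, t_f=1.0))
        with pytest.raises(ValueError):
            solve_nlp(nlp, strategy="multiple_shooting")

    def test_grid_refinement_converged(self):
        """Doubling the element count barely moves the Case 1 nominal optimum."""
        from robokin.backoff import BackoffPolicy
        from robokin.models import case1_model
        from robokin.robust import assemble_robust_ocp
        from robokin.uncertainty import UncertaintySpec

        model = case1_model()
        spec = UncertaintySpec("normal", model.theta_nominal, rel_std=0.2)
        ocp = assemble_robust_ocp(model, "nominal", spec, BackoffPolicy(alpha=0.0))
        coarse = solve_ocp(ocp, n_elements=10, refine_from=None)
        fine = solve_ocp(ocp, n_elements=20, refine_from=10)
        assert coarse.success and fine.success
        assert abs(fine.objective - coarse.objective) < 1e-3
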