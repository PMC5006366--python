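"""Sigma points, PCE bases, sensitivity systems and their moment formulas."""

import math

import numpy as np
import pytest

from robokin.models import ControlProfile, case1_model, case2_model
from robokin.uncertainty import (UncertaintySpec, augmented_state_count,
                                 build_pce_basis, build_sensitivity_system,
                                 generate_sigma_points, linearized_moments,
                                 pce_moments, pce_term_count, propagate,
                                 sigma_point_moments, select_sampling_points)


@pytest.fixture()
def spec3():
    return UncertaintySpec("normal", np.ones(3), rel_std=0.2)


class TestSigmaPoints:
    def test_count_and_kappa(self, spec3):
        sps = generate_sigma_points(spec3)
        assert sps.points.shape == (7, 3)
        assert sps.kappa == 0.0  # kappa = 3 - n_theta

    def test_diagonal_closed_form(self, spec3):
        sps = generate_sigma_points(spec3)
        np.testing.assert_allclose(sps.points[1], [1 + math.sqrt(0.12), 1, 1])

    def test_weighted_moments_reproduce_inputs(self, spec3):
        sps = generate_sigma_points(spec3)
        w = sps.weights
        np.testing.assert_allclose(w @ sps.points, spec3.theta_nom, atol=1e-14)
        dev = sps.points - spec3.theta_nom
        np.testing.assert_allclose((dev.T * w) @ dev, spec3.cov, atol=1e-14)

    def test_zero_covariance_degenerates_to_nominal(self):
        spec = UncertaintySpec("normal", np.ones(2), cov=np.zeros((2, 2)))
        sps = generate_sigma_points(spec)
        np.testing.assert_allclose(sps.points, 1.0)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            UncertaintySpec("normal", np.ones(2),
                            cov=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_moments_constant_and_affine(self, spec3):
        sps = generate_sigma_points(spec3)
        m, v = sigma_point_moments(np.full(7, 4.2), sps.kappa)
        assert (m, v) == (pytest.approx(4.2), pytest.approx(0.0))
        m, v = sigma_point_moments(sps.points[:, 0], sps.kappa)
        assert m == pytest.approx(1.0)
        assert v == pytest.approx(0.04)

    def test_second_order_exactness_on_square(self, spec3):
        # E[theta_1^2] = 1 + sigma^2 for a Gaussian
        sps = generate_sigma_points(spec3)
        m, _ = sigma_point_moments(sps.points[:, 0] ** 2, sps.kappa)
        assert m == pytest.approx(1.0 + 0.04)

    def test_wrong_value_count(self, spec3):
        with pytest.raises(ValueError):
            sigma_point_moments(np.zeros(6), 0.0)


class TestSensitivitySystem:
    def test_augmented_counts(self):
        assert build_sensitivity_system(case1_model()).n_x == 20
        assert build_sensitivity_system(case2_model()).n_x == 36

    def test_initial_sensitivity_rate(self):
        # d/dt (dS2/dk1) = S1 e1 = 1 at t = 0 with e = (1, 0, 0)
        sys_ = build_sensitivity_system(case1_model())
        d = sys_.f(sys_.x0, np.array([1.0, 0.0, 0.0]))
        assert d[sys_.state_names.index("S_S2_k1")] == pytest.approx(1.0)

    def test_linear_system_variance_closed_form(self):
        # x' = theta, x(0) = 0, R = x(T): Var = T^2 sigma^2
        from robokin.models import (ExtraState, NetworkModel, simulate)

        model = NetworkModel(
            name="linfix", species=[], stoichiometry=np.zeros((0, 0)),
            rate_laws=[], control_names=["u"], param_names=["theta"],
            theta_nominal=np.array([1.0]), x0=np.array([0.0]),
            extra_states=[ExtraState("x", "theta")], t_f=3.0)
        sys_ = build_sensitivity_system(model)
        cp = ControlProfile.constant([0.0], 3.0, 1)
        traj = simulate(sys_, cp, model.theta_nominal)
        E, V = linearized_moments(traj.states[-1], sys_, np.array([[0.25]]),
                                  state="x")
        assert E == pytest.approx(3.0)
        assert V == pytest.approx(9.0 * 0.25)

    def test_zero_covariance(self, spec3):
        sys_ = build_sensitivity_system(case1_model())
        cp = ControlProfile.constant([0.3, 0.3, 0.3], 5.0, 1)
        from robokin.models import simulate

        traj = simulate(sys_, cp, np.ones(3))
        E, V = linearized_moments(traj.states[-1], sys_, np.zeros((3, 3)),
                                  state="S4")
        assert V == 0.0


class TestPCEBasis:
    def test_term_counts(self):
        assert pce_term_count(3, 1) == 4
        assert pce_term_count(3, 2) == 10

    def test_hermite_norms(self, spec3):
        basis = build_pce_basis(spec3, 2)
        # E[He_2^2] = 2! = 2 for pure second-order terms
        for idx, norm in zip(basis.indices, basis.norms):
            if sorted(idx) == [0, 0, 2]:
                assert norm == pytest.approx(2.0)
        assert basis.indices[0] == (0, 0, 0)

    @pytest.mark.parametrize("family,order", [("normal", 1), ("normal", 2),
                                              ("uniform", 1), ("uniform", 2)])
    def test_orthogonality_under_gauss_quadrature(self, family, order):
        spec = UncertaintySpec(family, np.ones(2), rel_std=0.1)
        basis = build_pce_basis(spec, order)
        # Gauss rule of order 2p + 2 in each dimension
        npts = order + 2
        if family == "normal":
            x, w = np.polynomial.hermite_e.hermegauss(npts)
            w = w / w.sum()
        else:
            x, w = np.polynomial.legendre.leggauss(npts)
            x, w = x * math.sqrt(3.0), w / w.sum()
        X1, X2 = np.meshgrid(x, x)
        W = np.outer(w, w).ravel()
        pts = np.column_stack([X1.ravel(), X2.ravel()])
        Phi = basis.eval_basis(pts)
        G = (Phi * W) @ Phi.T
        np.testing.assert_allclose(G, np.diag(basis.norms), atol=1e-8)

    def test_sampling_point_counts_and_nominal_inclusion(self, spec3):
        b1 = build_pce_basis(spec3, 1)
        assert b1.n_s == 4
        # odd order: design symmetric around the nominal point
        assert np.allclose(b1.points_xi.mean(axis=0), 0.0, atol=0.51)
        b2 = build_pce_basis(spec3, 2)
        assert b2.n_s == 10
        assert any(np.allclose(p, spec3.theta_nom) for p in b2.points_theta)

    def test_sigma_points_subset_of_pce2_design(self, spec3):
        sps = generate_sigma_points(spec3)
        b2 = build_pce_basis(spec3, 2)
        pce_pts = {tuple(np.round(p, 10)) for p in b2.points_theta}
        for p in sps.points:
            assert tuple(np.round(p, 10)) in pce_pts

    def test_degenerate_covariance_rejected(self):
        spec = UncertaintySpec("normal", np.ones(3), cov=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            build_pce_basis(spec, 2)

    def test_regression_constant_and_square(self, spec3):
        basis = build_pce_basis(spec3, 2)
        m, v, a = pce_moments(np.full(basis.n_s, 3.3), basis)
        assert m == pytest.approx(3.3)
        assert v == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(a[1:], 0.0, atol=1e-10)
        # R = xi_1^2 = He_2(xi_1) + 1: coefficients (1, ..., 1 on He_2), Var = 2
        vals = basis.points_xi[:, 0] ** 2
        m, v, a = pce_moments(vals, basis)
        assert m == pytest.approx(1.0)
        assert v == pytest.approx(2.0)

    def test_polynomial_reproduction_zero_residual(self, spec3):
        basis = build_pce_basis(spec3, 2)
        rng = np.random.default_rng(3)
        coeff = rng.normal(size=basis.L)
        vals = coeff @ basis.Lambda  # a degree-2 polynomial sampled at the design
        _, _, a = pce_moments(vals, basis)
        np.testing.assert_allclose(basis.Lambda.T @ a, vals, atol=1e-9)


class TestAugmentedStateBookkeeping:
    @pytest.mark.parametrize("technique,expected", [
        ("nominal", 9), ("linearization", 36), ("sigma_points", 63),
        ("pce1", 36), ("pce2", 90)])
    def test_case2_counts(self, technique, expected):
        assert augmented_state_count(technique, 9, 3) == expected

    def test_case1_follows_the_generic_formulas(self):
        assert augmented_state_count("linearization", 5, 3) == 20
        assert augmented_state_count("sigma_points", 5, 3) == 35
        assert augmented_state_count("pce2", 5, 3) == 50


class TestPropagationCollapse:
    def test_all_techniques_collapse_without_uncertainty(self):
        """Zero covariance: every technique returns (nominal value, 0)."""
        model = case1_model()
        zero = UncertaintySpec("normal", model.theta_nominal, rel_std=0.0)
        cp = ControlProfile.constant([0.4, 0.3, 0.3], 10.0, 2)
        ref = None
        for technique in ("nominal", "linearization", "sigma_points"):
            res = propagate(model, cp, zero, technique, quantities=["S4"])
            E, V = res.quantities["S4"]
            assert V == pytest.approx(0.0, abs=1e-12)
            if ref is None:
                ref = E
            assert E == pytest.approx(ref, rel=1e-7)  # integrator tolerance

    def test_linearization_requires_normal_family(self):
        model = case1_model()
        spec = UncertaintySpec("uniform", model.theta_nominal, rel_std=0.2)
        cp = ControlProfile.constant([0.4, 0.3, 0.3], 10.0, 1)
        with pytest.raises(ValueError):
            propagate(model, cp, spec, "linearization")


class TestVarianceAgainstMonteCarlo:
    def test_exponential_growth_fixture(self):
        """x' = theta x: technique variances approach the MC variance as
        the spread shrinks (3 MC standard errors at 1e5 samples)."""
        from robokin.models import ExtraState, NetworkModel, simulate_batch

        model = NetworkModel(
            name="expfix", species=[], stoichiometry=np.zeros((0, 0)),
            rate_laws=[], control_names=["u"], param_names=["theta"],
            theta_nominal=np.array([0.5]), x0=np.array([1.0]),
            extra_states=[ExtraState("x", "theta * x")], t_f=2.0)
        cp = ControlProfile.constant([0.0], 2.0, 1)
        rel = 0.02  # small spread: curvature terms negligible
        spec = UncertaintySpec("normal", model.theta_nominal, rel_std=rel)
        rng = np.random.default_rng(11)
        thetas = spec.theta_nom + rng.standard_normal((100_000, 1)) * spec.std
        xT = simulate_batch(model, cp, thetas, substeps_per_element=60)[:, 0]
        mc_var = float(np.var(xT, ddof=1))
        se_var = math.sqrt(np.mean((xT - xT.mean()) ** 4) - mc_var ** 2) \
            / math.sqrt(len(xT))
        for technique in ("linearization", "sigma_points", "pce1", "pce2"):
            res = propagate(model, cp, spec, technique, quantities=["x"])
            assert res.quantities["x"][1] == pytest.approx(mc_var, abs=3 * se_var)
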