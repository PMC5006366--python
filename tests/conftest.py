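"""Shared fixtures; the expensive case-study solves are session-scoped."""

import numpy as np
import pytest

from robokin import (BackoffPolicy, UncertaintySpec, case1_model, case2_model)
from robokin.collocation import solve_ocp
from robokin.robust import assemble_robust_ocp, solve_robust

MC_SEED = 0  # fixed up front for every stochastic check in the suite


@pytest.fixture()
def case1():
    return case1_model()


@pytest.fixture()
def case2():
    return case2_model()


@pytest.fixture()
def spec_case1(case1):
    return UncertaintySpec("normal", case1.theta_nominal, rel_std=0.2)


@pytest.fixture()
def spec_case2(case2):
    return UncertaintySpec("normal", case2.theta_nominal, rel_std=0.1)


@pytest.fixture(scope="session")
def case1_nominal_solution():
    model = case1_model()
    spec = UncertaintySpec("normal", model.theta_nominal, rel_std=0.2)
    ocp = assemble_robust_ocp(model, "nominal", spec, BackoffPolicy(alpha=0.0))
    return solve_ocp(ocp, n_elements=30, refine_from=10)


@pytest.fixture(scope="session")
def case2_nominal_solution():
    model = case2_model()
    spec = UncertaintySpec("normal", model.theta_nominal, rel_std=0.1)
    ocp = assemble_robust_ocp(model, "nominal", spec, BackoffPolicy(alpha=0.0),
                              objective="enzymatic_cost")
    return solve_ocp(ocp, n_elements=30, refine_from=10)


@pytest.fixture(scope="session")
def case1_linearization_solution(case1_nominal_solution):
    model = case1_model()
    spec = UncertaintySpec("normal", model.theta_nominal, rel_std=0.2)
    sol, prop = solve_robust(model, "linearization", spec,
                             BackoffPolicy(alpha=1.96), n_elements=30,
                             warm_start=case1_nominal_solution)
    return sol, prop
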