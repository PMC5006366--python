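"""Assembly of robustified optimal control problems.

A :class:`RobustOCP` couples a kinetic network model with an uncertainty
specification, a propagation technique and a backoff policy.  The technique's
augmented dynamics (forward sensitivities, or state replicas at the sigma /
PCE sampling points, all sharing one control trajectory) become the dynamic
constraints of the optimization problem; designated terminal chance
constraints are replaced by their backed-off form

    0 >= -(E[c] - alpha sqrt(Var[c]) - c_min)

and robustified objectives by E[J] + alpha g(Var[J]) where g is either the
standard deviation or (as an alternative penalty form) the variance itself.
Control bounds and non-probabilistic constraints pass through unchanged.
With alpha = 0 and zero covariance the problem reduces exactly to the
nominal formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import sympy as sp

from .backoff import BackoffPolicy, robustify_constraint, robustify_objective
from .collocation import Solution, System, model_system, solve_ocp
from .models import NetworkModel
from .uncertainty import (PropagationResult, SensitivitySystem, UncertaintySpec,
                          augmented_state_count, build_pce_basis,
                          build_sensitivity_system, generate_sigma_points,
                          pce_moments, sigma_point_moments, TECHNIQUES)

_SQRT_EPS = 1e-16  # keeps sqrt(Var) differentiable when the variance vanishes


@dataclass
class RobustOCP:
    """Robustified OCP implementing the transcription protocol."""

    model: NetworkModel
    technique: str
    spec: UncertaintySpec
    policy: BackoffPolicy
    objective_name: str | None = None  # which model objective to minimize
    t_f_free: bool = False

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; one of {TECHNIQUES}")
        if self.technique == "linearization" and self.spec.family != "normal":
            raise ValueError("the linearization technique assumes a normal "
                             "parametric uncertainty distribution")
        if self.spec.n_theta != self.model.n_theta:
            raise ValueError("uncertainty spec and model disagree on n_theta")
        terminal_objs = [o for o in self.model.objectives if o.kind == "terminal"]
        if self.objective_name is None:
            if not terminal_objs:
                raise ValueError("model declares no terminal objective")
            self.objective_name = terminal_objs[-1].name
        self._objective = next(o for o in self.model.objectives
                               if o.name == self.objective_name)
        if self._objective.kind == "final_time" and not self.t_f_free:
            raise ValueError("minimizing the final time requires t_f_free=True")
        self._build_evaluators()

    # -- protocol surface --------------------------------------------------

    @property
    def n_u(self) -> int:
        return self.model.n_u

    @property
    def control_lb(self) -> np.ndarray:
        return self.model.control_lb

    @property
    def control_ub(self) -> np.ndarray:
        return self.model.control_ub

    @property
    def fixed_initial_controls(self):
        return self.model.fixed_initial_controls

    @property
    def t_f(self) -> float:
        return self.model.t_f

    @property
    def t_f_bounds(self):
        return self.model.t_f_bounds or (1e-2, self.model.t_f)

    @cached_property
    def systems(self) -> list[System]:
        """Augmented/replicated subsystems sharing the control trajectory."""
        m, spec = self.model, self.spec
        if self.technique == "nominal":
            return [model_system(m, spec.theta_nom, "nominal")]
        if self.technique == "linearization":
            self._sens = build_sensitivity_system(m, spec.theta_nom)
            return [model_system(self._sens, spec.theta_nom, "sensitivity")]
        if self.technique == "sigma_points":
            self._sigma = generate_sigma_points(spec)
            return [model_system(m, th, f"sigma_{i}")
                    for i, th in enumerate(self._sigma.points)]
        p = int(self.technique[-1])
        self._basis = build_pce_basis(spec, p)
        return [model_system(m, th, f"pce_{i}")
                for i, th in enumerate(self._basis.points_theta)]

    @property
    def n_dynamic_states(self) -> int:
        return sum(s.n for s in self.systems)

    # -- moment machinery --------------------------------------------------

    def _build_evaluators(self) -> None:
        m = self.model
        x_syms, _, _ = m.symbols()
        self._exprs: dict[str, tuple] = {}
        tracked = [(c.expr, c) for c in m.terminal_constraints]
        tracked += [(o.expr, o) for o in m.objectives if o.kind == "terminal"]
        for text, _src in tracked:
            if text in self._exprs:
                continue
            e = m.expression(text)
            g = sp.lambdify((x_syms,), e, modules="numpy")
            grad = sp.lambdify((x_syms,), [sp.diff(e, s) for s in x_syms],
                               modules="numpy")
            self._exprs[text] = (g, grad)

    def _moments(self, text: str, terminal_states: Sequence[np.ndarray]
                 ) -> tuple[float, float]:
        """(E, Var) of a terminal expression under the assembled technique."""
        g, grad = self._exprs[text]
        if self.technique == "nominal":
            return float(g(terminal_states[0])), 0.0
        if self.technique == "linearization":
            x, S = self._sens.split(terminal_states[0])
            gx = np.array([float(v) for v in grad(x)])
            gS = gx @ S
            return float(g(x)), max(float(gS @ self.spec.cov @ gS), 0.0)
        values = np.array([float(g(x)) for x in terminal_states])
        if self.technique == "sigma_points":
            return sigma_point_moments(values, self._sigma.kappa)
        mean, var, _ = pce_moments(values, self._basis)
        return mean, var

    def propagation_result(self, terminal_states: Sequence[np.ndarray]
                           ) -> PropagationResult:
        """Technique moments of every tracked terminal quantity."""
        out = PropagationResult(self.technique, {},
                                n_states=self.n_dynamic_states)
        for text in self._exprs:
            out.quantities[text] = self._moments(text, terminal_states)
        return out

    # -- objective / constraints ------------------------------------------

    def _robust_objective_value(self, obj, terminal_states, t_f: float) -> float:
        if obj.kind == "final_time":
            return float(t_f)
        E, Var = self._moments(obj.expr, terminal_states)
        if not obj.robustify or self.technique == "nominal":
            return E
        return robustify_objective(E, Var, self.policy.alpha,
                                   self.policy.objective_form)

    def objective(self, terminal_states, controls, t_f: float) -> float:
        return self._robust_objective_value(self._objective, terminal_states, t_f)

    def objective_values(self, terminal_states, t_f: float) -> list[float]:
        """All (robustified) objective values, in model declaration order."""
        return [self._robust_objective_value(o, terminal_states, t_f)
                for o in self.model.objectives]

    def terminal_margins(self, terminal_states, t_f: float) -> np.ndarray:
        margins = []
        for c in self.model.terminal_constraints:
            E, Var = self._moments(c.expr, terminal_states)
            if c.chance and self.technique != "nominal":
                backoff = self.policy.alpha * math.sqrt(max(Var, 0.0) + _SQRT_EPS)
                val = E - backoff if c.direction == "ge" else E + backoff
            else:
                val = E
            margins.append(val - c.bound if c.direction == "ge" else c.bound - val)
        return np.asarray(margins)

    def path_margins(self, x_node: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Deterministic path constraints on the nominal subsystem trajectory."""
        m = self.model
        if self.technique == "linearization":
            x_node = x_node[: m.n_x]
        vals = []
        for c in m.path_constraints:
            g = self._path_fn(c.expr)
            v = float(g(x_node, u))
            vals.append(c.bound - v if c.direction == "le" else v - c.bound)
        return np.asarray(vals)

    def _path_fn(self, text: str):
        cache = self.__dict__.setdefault("_path_cache", {})
        if text not in cache:
            x_syms, u_syms, _ = self.model.symbols()
            e = self.model.expression(text)
            cache[text] = sp.lambdify((x_syms, u_syms), e, modules="numpy")
        return cache[text]


def assemble_robust_ocp(model: NetworkModel, technique: str, spec: UncertaintySpec,
                        policy: BackoffPolicy, objective: str | None = None,
                        t_f_free: bool = False) -> RobustOCP:
    """Build the robustified OCP for one propagation technique.

    The augmented dynamic state count follows the technique:
    (n_theta + 1) n_x for linearization, (2 n_theta + 1) n_x for sigma
    points and (n_theta + p)! / (n_theta! p!) n_x for PCE of order p.
    """
    ocp = RobustOCP(model, technique, spec, policy, objective_name=objective,
                    t_f_free=t_f_free)
    expected = augmented_state_count(technique, model.n_x, spec.n_theta)
    if technique not in ("pce1", "pce2") and ocp.n_dynamic_states != expected:
        raise AssertionError("augmented state bookkeeping mismatch")
    return ocp


def solve_robust(model: NetworkModel, technique: str, spec: UncertaintySpec,
                 policy: BackoffPolicy, n_elements: int = 30,
                 objective: str | None = None, warm_start: Solution | None = None,
                 tol: float = 1e-8, max_iter: int = 400,
                 refine_from: int | None = 10) -> tuple[Solution, PropagationResult]:
    """Assemble and solve; robust solves are warm-started from the nominal one.

    Returns the solution together with the technique's propagated
    (E, Var) of the tracked terminal quantities at the optimum.
    """
    ocp = assemble_robust_ocp(model, technique, spec, policy, objective=objective)
    if technique != "nominal" and warm_start is None:
        nominal = assemble_robust_ocp(model, "nominal", spec, policy,
                                      objective=objective)
        warm_start = solve_ocp(nominal, n_elements=n_elements, tol=tol,
                               max_iter=max_iter, refine_from=refine_from)
    z0 = None
    if warm_start is not None:
        from .collocation import CollocationGrid, transcribe

        nlp = transcribe(ocp, CollocationGrid(n_elements, t_f=ocp.t_f))
        if warm_start.controls.n_elements == n_elements:
            u0 = warm_start.controls.values
        else:
            grid = CollocationGrid(n_elements, t_f=ocp.t_f)
            tmid = (np.concatenate([[0.0], np.cumsum(grid.fractions)])[:-1]
                    + 0.5 * grid.fractions) * warm_start.t_f
            u0 = np.vstack([warm_start.controls.value_at(t) for t in tmid])
        z0 = nlp.pack(u0, warm_start.t_f)
        sol = solve_ocp(ocp, n_elements=n_elements, tol=tol, max_iter=max_iter,
                        z0=z0, refine_from=None)
    else:
        sol = solve_ocp(ocp, n_elements=n_elements, tol=tol, max_iter=max_iter,
                        refine_from=refine_from)
    prop = ocp.propagation_result(sol.terminal_states)
    return sol, prop
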