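"""Bi-objective Pareto fronts by Normal Boundary Intersection (NBI).

NBI scalarizes a two-objective problem into a series of single-objective
subproblems: after computing the two anchor points (each minimizing one
objective alone), evenly spaced points on the line segment between the
anchors (the convex hull of individual minima, CHIM) are pushed toward the
Pareto surface along a quasi-normal direction.  Each subproblem maximizes
the travelled distance subject to the original constraints; the inequality
variant used here (the attained objective vector must lie on the far side of
the moving point) is robust when the front is non-convex near the anchors.
Objectives are normalized to the anchor bounding box before the geometry is
set up, since the raw objectives carry heterogeneous units (e.g. seconds
versus mM s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize


class ParetoError(RuntimeError):
    pass


class BiobjectiveProblem:
    """Protocol: static or transcribed problem with two objectives.

    Implementations provide ``n_z``, ``bounds`` (sequence of (lb, ub)),
    ``z0``, ``objectives(z) -> (f1, f2)`` and optionally
    ``constraint_margins(z)`` (feasible iff >= 0).
    """

    n_z: int
    bounds: Sequence[tuple[float, float]]
    z0: np.ndarray

    def objectives(self, z: np.ndarray) -> tuple[float, float]:  # pragma: no cover
        raise NotImplementedError

    def constraint_margins(self, z: np.ndarray) -> np.ndarray | None:
        return None


@dataclass
class ParetoPoint:
    beta: float
    objectives: np.ndarray
    z: np.ndarray
    success: bool
    message: str = ""


@dataclass
class ParetoFront:
    anchors: list[ParetoPoint]
    points: list[ParetoPoint]
    technique: str = ""
    alpha: float = 0.0

    def objective_array(self, only_successful: bool = True) -> np.ndarray:
        pts = [p for p in self.points if p.success or not only_successful]
        return np.array([p.objectives for p in pts])

    def is_nondominated(self, tol: float = 1e-9) -> bool:
        F = self.objective_array()
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j and np.all(F[j] <= F[i] - tol) :
                    return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"beta_nbi": p.beta, "J1": p.objectives[0], "J2": p.objectives[1],
              "status": "ok" if p.success else p.message} for p in self.points])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _solve_scalar(problem: BiobjectiveProblem, fun, z0, extra_cons=(),
                  extra_var: tuple[float, tuple[float, float]] | None = None,
                  tol: float = 1e-8, max_iter: int = 300):
    """Minimize fun over the problem's feasible set (optionally + one scalar)."""
    bounds = list(problem.bounds)
    if extra_var is not None:
        z0 = np.append(z0, extra_var[0])
        bounds.append(extra_var[1])
    cons = []
    if problem.constraint_margins(problem.z0) is not None:
        nz = problem.n_z
        cons.append({"type": "ineq",
                     "fun": lambda w: problem.constraint_margins(w[:nz])})
    cons.extend(extra_cons)
    return minimize(fun, z0, method="SLSQP", bounds=bounds, constraints=cons,
                    options={"maxiter": max_iter, "ftol": tol})


def anchor_points(problem: BiobjectiveProblem, tol: float = 1e-8,
                  max_iter: int = 300) -> list[ParetoPoint]:
    """Individual minima of each objective over the common feasible set."""
    starts = getattr(problem, "starts", lambda: [np.asarray(problem.z0, dtype=float)])()
    anchors = []
    for i in (0, 1):
        best = None
        for z0 in starts:
            res = _solve_scalar(problem, lambda z, i=i: problem.objectives(z)[i],
                                np.asarray(z0, dtype=float),
                                tol=tol, max_iter=max_iter)
            if best is None or (res.success and
                                (not best.success or res.fun < best.fun)):
                best = res
            if best.success and len(starts) == 1:
                break
        F = np.asarray(problem.objectives(best.x), dtype=float)
        anchors.append(ParetoPoint(beta=float(1 - i), objectives=F,
                                   z=np.asarray(best.x), success=bool(best.success),
                                   message=str(best.message)))
    return anchors


def nbi_front(problem: BiobjectiveProblem, n_points: int = 10,
              anchors: list[ParetoPoint] | None = None, tol: float = 1e-8,
              max_iter: int = 300, technique: str = "", alpha: float = 0.0
              ) -> ParetoFront:
    """Pareto front with ``n_points`` evenly spaced NBI subproblems.

    Subproblem weight beta runs from 1 (first-objective anchor) to 0; the two
    end points are the anchors themselves.  Failed subproblems are recorded
    with their solver message and excluded from the default objective array.
    """
    if n_points < 2:
        raise ParetoError("a front needs at least the two anchor points")
    if anchors is None:
        anchors = anchor_points(problem, tol=tol, max_iter=max_iter)
    FA = np.array([a.objectives for a in anchors])  # (2, 2)
    span = np.abs(FA[1] - FA[0])
    scale = np.where(span > 1e-12, span, 1.0)
    ref = FA.min(axis=0)

    def norm(F):
        return (np.asarray(F) - ref) / scale

    A = np.array([norm(a.objectives) for a in anchors])
    direction = -np.ones(2) / np.sqrt(2.0)  # quasi-normal toward the utopia point
    nz = problem.n_z
    points: list[ParetoPoint] = [anchors[0]]
    z_prev = anchors[0].z
    betas = np.linspace(1.0, 0.0, n_points)
    for beta in betas[1:-1]:
        chim = beta * A[0] + (1.0 - beta) * A[1]

        def nbi_margin(w, chim=chim):
            F = norm(problem.objectives(w[:nz]))
            target = chim + w[-1] * direction
            return target - F  # require F <= chim + d * n_hat componentwise

        res = _solve_scalar(problem, lambda w: -w[-1], z_prev,
                            extra_cons=[{"type": "ineq", "fun": nbi_margin}],
                            extra_var=(0.0, (-2.0, 5.0)),
                            tol=tol, max_iter=max_iter)
        z = res.x[:nz]
        points.append(ParetoPoint(beta=float(beta),
                                  objectives=np.asarray(problem.objectives(z)),
                                  z=np.asarray(z), success=bool(res.success),
                                  message=str(res.message)))
        if res.success:
            z_prev = z
    points.append(anchors[1])
    points.sort(key=lambda p: p.objectives[0])
    return ParetoFront(anchors=anchors, points=points, technique=technique,
                       alpha=alpha)


# --------------------------------------------------------------------------
# adapter: robustified OCP -> bi-objective problem


class OCPBiobjective(BiobjectiveProblem):
    """View a two-objective robustified OCP as a static NBI problem.

    The decision vector is the reduced transcription vector (controls per
    element, plus t_f when free); objectives are the robustified objective
    values in model declaration order.
    """

    def __init__(self, ocp, n_elements: int = 10, z0: np.ndarray | None = None):
        from .collocation import (CollocationGrid, _default_guess,
                                  _sequential_guess, transcribe)

        if len(ocp.model.objectives) != 2:
            raise ParetoError("NBI front generation requires exactly two objectives; "
                              f"model {ocp.model.name!r} declares "
                              f"{len(ocp.model.objectives)}")
        self.ocp = ocp
        self.nlp = transcribe(ocp, CollocationGrid(n_elements, t_f=ocp.t_f))
        lb, ub = self.nlp.control_bounds()
        self.bounds = list(zip(lb, ub))
        if self.nlp.t_f_free:
            self.bounds.append(tuple(ocp.t_f_bounds))
        self.n_z = len(self.bounds)
        if z0 is None:
            z0 = _default_guess(self.nlp)
        self.z0 = np.asarray(z0, dtype=float)
        self._seq = _sequential_guess(self.nlp)

    def starts(self) -> list[np.ndarray]:
        out = [self.z0]
        if self._seq is not None:
            out.append(np.asarray(self._seq, dtype=float))
        return out

    def objectives(self, z):
        ro = self.nlp._rollout(z)
        _, t_f = self.nlp.unpack(z)
        vals = self.ocp.objective_values(ro.terminal_states, t_f)
        return float(vals[0]), float(vals[1])

    def constraint_margins(self, z):
        return self.nlp.inequality_margins(z)

    def control_profile(self, z):
        from .models import ControlProfile

        u, t_f = self.nlp.unpack(z)
        b = np.concatenate([[0.0], np.cumsum(self.nlp.grid.fractions)]) * t_f
        return ControlProfile(b, u)
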