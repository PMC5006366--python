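"""Orthogonal collocation transcription of optimal control problems.

States and controls are fully discretized on finite elements.  Within each
element the state is interpolated by a cubic Lagrange polynomial through the
element start point and three collocation points placed at the right Radau
roots; the ODE is enforced at the collocation points (collocation
constraints) and element junctions are tied by continuity constraints.
Controls are piecewise constant per element.  The resulting NLP is solved
with a sequential-quadratic-programming solver (scipy's SLSQP).

Two solve strategies operate on the same discretization:

* ``simultaneous`` -- all node states are decision variables and the
  collocation/continuity equations enter as equality constraints (the
  classical full-discretization NLP; practical here for small systems).
* ``reduced`` (default) -- the collocation equations are eliminated element
  by element with Newton's method (the scheme is exactly the 3-stage Radau
  IIA implicit Runge-Kutta method, order 5), leaving the control parameters
  (and optionally t_f) as the only decision variables.  This keeps the NLP
  dense-solver friendly for the replicated/augmented systems of the
  robustified problems.

An OCP is anything exposing the small protocol consumed by
:func:`transcribe`: ``systems`` (list of :class:`System` sharing one control
trajectory), control bounds, optional fixed first-element controls, a scalar
``objective(terminal_states, controls, t_f)``, vector-valued
``terminal_margins(terminal_states, t_f)`` and ``path_margins(x, u)``
(feasible iff >= 0), and the final-time settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import roots_jacobi


class TranscriptionError(ValueError):
    pass


class SolverError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Radau points and Lagrange differentiation


def radau_nodes(degree: int = 3) -> np.ndarray:
    """Right Radau collocation points on (0, 1], including the endpoint 1.

    The interior points are the roots of the Jacobi polynomial
    P_{degree-1}^{(1,0)} mapped to (0, 1); the induced quadrature is exact for
    polynomials up to degree 2*degree - 2.
    """
    if degree < 1:
        raise TranscriptionError("collocation degree must be >= 1")
    if degree == 1:
        return np.array([1.0])
    x, _ = roots_jacobi(degree - 1, 1.0, 0.0)
    return np.concatenate([np.sort((x + 1.0) / 2.0), [1.0]])


def radau_weights(degree: int = 3) -> np.ndarray:
    """Quadrature weights on [0, 1] associated with the Radau nodes."""
    tau = radau_nodes(degree)
    # solve the moment equations sum_k w_k tau_k^m = 1/(m+1)
    V = np.vander(tau, degree, increasing=True).T
    rhs = 1.0 / np.arange(1, degree + 1)
    return np.linalg.solve(V, rhs)


def lagrange_diff_matrix(degree: int = 3) -> np.ndarray:
    """Derivatives of the Lagrange basis through {0} + Radau nodes.

    Returns D of shape (degree, degree + 1): D[k, j] = l_j'(tau_k) where
    l_j are the Lagrange polynomials through the points (0, tau_1..tau_degree)
    and tau_k runs over the collocation points.  Rows of the full basis
    derivative sum to zero (differentiating the constant 1).
    """
    pts = np.concatenate([[0.0], radau_nodes(degree)])
    n = len(pts)
    D = np.zeros((degree, n))
    for j in range(n):
        for k in range(1, n):
            # l_j'(tau_k) = sum_{m != j} 1/(tau_j - tau_m) prod_{i != j,m} ...
            s = 0.0
            for m in range(n):
                if m == j:
                    continue
                p = 1.0 / (pts[j] - pts[m])
                for i in range(n):
                    if i in (j, m):
                        continue
                    p *= (pts[k] - pts[i]) / (pts[j] - pts[i])
                s += p
            D[k - 1, j] = s
    return D


# --------------------------------------------------------------------------
# grid and systems


@dataclass
class CollocationGrid:
    """Finite-element grid with per-element Radau collocation nodes."""

    n_elements: int
    t_f: float = 1.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise TranscriptionError("need at least one finite element")
        self.tau = radau_nodes(self.degree)
        self.D = lagrange_diff_matrix(self.degree)
        self.fractions = np.full(self.n_elements, 1.0 / self.n_elements)

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.fractions)]) * self.t_f

    def node_times(self, t_f: float | None = None) -> np.ndarray:
        """All collocation node times, shape (n_elements, degree)."""
        t_f = self.t_f if t_f is None else t_f
        b = np.concatenate([[0.0], np.cumsum(self.fractions)]) * t_f
        return b[:-1, None] + np.diff(b)[:, None] * self.tau[None, :]


class System(NamedTuple):
    """One replicated/augmented dynamic subsystem sharing the control trajectory."""

    f: Callable  # f(x, u, t) -> dx/dt
    jac: Callable  # df/dx (x, u, t) -> (n, n)
    n: int
    x0: np.ndarray
    label: str = ""


def model_system(model, theta, label: str = "") -> System:
    """Wrap a model (or augmented system) with parameters baked in."""
    theta = np.asarray(theta, dtype=float)
    f, jac = model.f, model.jac_x
    return System(
        f=lambda x, u, t, _f=f, _th=theta: _f(x, u, _th, t),
        jac=lambda x, u, t, _j=jac, _th=theta: _j(x, u, _th, t),
        n=model.n_x,
        x0=np.array(model.x0, dtype=float),
        label=label or getattr(model, "name", ""),
    )


# --------------------------------------------------------------------------
# element stepping (reduced strategy): Newton on the collocation equations


def element_step(system: System, grid: CollocationGrid, x_start: np.ndarray,
                 u: np.ndarray, h: float, t0: float = 0.0,
                 tol: float = 1e-12, max_iter: int = 25) -> np.ndarray:
    """Solve one element's collocation equations; returns node states (degree, n).

    This is the 3-stage Radau IIA step: find X_k with
    sum_j D[k, j] X_j = h f(X_k, u) for k = 1..degree, X_0 = x_start.
    """
    d, n = grid.degree, system.n
    D0 = grid.D[:, 0]
    Dc = grid.D[:, 1:]
    kronD = np.kron(Dc, np.eye(n))
    X = np.tile(x_start, (d, 1))
    t_nodes = t0 + h * grid.tau
    for _ in range(max_iter):
        F = np.stack([system.f(X[k], u, t_nodes[k]) for k in range(d)])
        R = (Dc @ X + np.outer(D0, x_start) - h * F).ravel()
        if np.max(np.abs(R)) < tol:
            break
        J = kronD.copy()
        for k in range(d):
            J[k * n:(k + 1) * n, k * n:(k + 1) * n] -= h * system.jac(X[k], u, t_nodes[k])
        X = X - np.linalg.solve(J, R).reshape(d, n)
    else:
        R = (Dc @ X + np.outer(D0, x_start)
             - h * np.stack([system.f(X[k], u, t_nodes[k]) for k in range(d)])).ravel()
        if np.max(np.abs(R)) > 1e-6:
            raise SolverError(f"element Newton iteration failed (|R|={np.max(np.abs(R)):.2e})")
    return X


@dataclass
class Rollout:
    """Node states from sequentially eliminated collocation equations."""

    node_states: list[np.ndarray]  # per system: (n_elements, degree, n)
    terminal_states: list[np.ndarray]  # per system: (n,)
    t_f: float


def rollout(systems: Sequence[System], grid: CollocationGrid,
            control_values: np.ndarray, t_f: float) -> Rollout:
    """Propagate every subsystem through all elements under shared controls."""
    h = np.diff(np.concatenate([[0.0], np.cumsum(grid.fractions)])) * t_f
    starts = np.concatenate([[0.0], np.cumsum(h)])
    nodes, terms = [], []
    for sys_ in systems:
        X_el = np.empty((grid.n_elements, grid.degree, sys_.n))
        x = np.array(sys_.x0, dtype=float)
        for e in range(grid.n_elements):
            X = element_step(sys_, grid, x, control_values[e], h[e], starts[e])
            X_el[e] = X
            x = X[-1]  # Radau: last node is the element end
        nodes.append(X_el)
        terms.append(x)
    return Rollout(nodes, terms, t_f)


# --------------------------------------------------------------------------
# transcription


@dataclass
class TranscribedNLP:
    """Finite-dimensional NLP obtained from an OCP on a collocation grid."""

    ocp: object
    grid: CollocationGrid

    def __post_init__(self) -> None:
        self.systems: list[System] = list(self.ocp.systems)
        self.n_dynamic_states = sum(s.n for s in self.systems)
        self.n_u = int(self.ocp.n_u)
        ne = self.grid.n_elements
        self.n_controls = ne * self.n_u
        self.t_f_free = bool(getattr(self.ocp, "t_f_free", False))
        self._cache: dict[bytes, Rollout] = {}

    # ---- structural bookkeeping (simultaneous form) ----------------------

    @property
    def n_collocation_constraints(self) -> int:
        return self.grid.n_elements * self.grid.degree * self.n_dynamic_states

    @property
    def n_continuity_constraints(self) -> int:
        return (self.grid.n_elements - 1) * self.n_dynamic_states

    @property
    def n_initial_conditions(self) -> int:
        return self.n_dynamic_states

    @property
    def n_decision(self) -> int:
        ne, d = self.grid.n_elements, self.grid.degree
        n_states = self.n_dynamic_states * ne * (d + 1)  # start + nodes per element
        return n_states + self.n_controls + (1 if self.t_f_free else 0)

    # ---- reduced-space evaluation ---------------------------------------

    def control_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        ne = self.grid.n_elements
        lb = np.tile(np.asarray(self.ocp.control_lb, dtype=float), ne)
        ub = np.tile(np.asarray(self.ocp.control_ub, dtype=float), ne)
        fixed = getattr(self.ocp, "fixed_initial_controls", None)
        if fixed is not None:
            lb[: self.n_u] = fixed
            ub[: self.n_u] = fixed
        return lb, ub

    def unpack(self, z: np.ndarray) -> tuple[np.ndarray, float]:
        z = np.asarray(z, dtype=float)
        u = z[: self.n_controls].reshape(self.grid.n_elements, self.n_u)
        t_f = float(z[self.n_controls]) if self.t_f_free else float(self.ocp.t_f)
        return u, t_f

    def pack(self, control_values: np.ndarray, t_f: float | None = None) -> np.ndarray:
        z = np.asarray(control_values, dtype=float).ravel()
        if self.t_f_free:
            z = np.append(z, self.ocp.t_f if t_f is None else t_f)
        return z

    def _rollout(self, z: np.ndarray) -> Rollout:
        key = np.asarray(z, dtype=float).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        u, t_f = self.unpack(z)
        ro = rollout(self.systems, self.grid, u, t_f)
        if len(self._cache) > 8:
            self._cache.pop(next(iter(self._cache)))
        self._cache[key] = ro
        return ro

    def objective(self, z: np.ndarray) -> float:
        ro = self._rollout(z)
        u, t_f = self.unpack(z)
        return float(self.ocp.objective(ro.terminal_states, u, t_f))

    def inequality_margins(self, z: np.ndarray) -> np.ndarray:
        """All inequality margins (terminal + path at every node); feasible >= 0."""
        ro = self._rollout(z)
        u, t_f = self.unpack(z)
        parts = [np.atleast_1d(self.ocp.terminal_margins(ro.terminal_states, t_f))]
        x_nodes = ro.node_states[0]  # path constraints act on the nominal subsystem
        for e in range(self.grid.n_elements):
            for k in range(self.grid.degree):
                m = self.ocp.path_margins(x_nodes[e, k], u[e])
                if m is not None and len(np.atleast_1d(m)):
                    parts.append(np.atleast_1d(m))
        return np.concatenate(parts) if parts else np.empty(0)

    # ---- simultaneous form ----------------------------------------------

    def split_simultaneous(self, w: np.ndarray):
        """Split a simultaneous decision vector into (controls, t_f, starts, nodes)."""
        ne, d = self.grid.n_elements, self.grid.degree
        u = w[: self.n_controls].reshape(ne, self.n_u)
        off = self.n_controls
        t_f = float(self.ocp.t_f)
        if self.t_f_free:
            t_f = float(w[off])
            off += 1
        starts, nodes = [], []
        for sys_ in self.systems:
            s = w[off: off + ne * sys_.n].reshape(ne, sys_.n)
            off += ne * sys_.n
            X = w[off: off + ne * d * sys_.n].reshape(ne, d, sys_.n)
            off += ne * d * sys_.n
            starts.append(s)
            nodes.append(X)
        return u, t_f, starts, nodes

    def residuals(self, w: np.ndarray) -> np.ndarray:
        """Equality residuals: initial conditions, collocation, continuity."""
        u, t_f, starts, nodes = self.split_simultaneous(np.asarray(w, dtype=float))
        ne, d = self.grid.n_elements, self.grid.degree
        h = np.diff(np.concatenate([[0.0], np.cumsum(self.grid.fractions)])) * t_f
        tstart = np.concatenate([[0.0], np.cumsum(h)])
        res = []
        for i, sys_ in enumerate(self.systems):
            res.append(starts[i][0] - sys_.x0)  # initial condition
            for e in range(ne):
                t_nodes = tstart[e] + h[e] * self.grid.tau
                F = np.stack([sys_.f(nodes[i][e, k], u[e], t_nodes[k]) for k in range(d)])
                res.append((self.grid.D[:, 1:] @ nodes[i][e]
                            + np.outer(self.grid.D[:, 0], starts[i][e]) - h[e] * F).ravel())
            for e in range(1, ne):  # continuity
                res.append(starts[i][e] - nodes[i][e - 1, -1])
        return np.concatenate(res)

    def simultaneous_from_rollout(self, z: np.ndarray) -> np.ndarray:
        """Embed a reduced-space point into the simultaneous decision vector."""
        ro = self._rollout(z)
        u, t_f = self.unpack(z)
        parts = [np.asarray(u, dtype=float).ravel()]
        if self.t_f_free:
            parts.append(np.array([t_f]))
        for i, sys_ in enumerate(self.systems):
            starts = np.vstack([sys_.x0[None, :], ro.node_states[i][:-1, -1, :]])
            parts.append(starts.ravel())
            parts.append(ro.node_states[i].ravel())
        return np.concatenate(parts)


def transcribe(ocp, grid: CollocationGrid) -> TranscribedNLP:
    """Discretize an OCP on a collocation grid."""
    if getattr(ocp, "t_f_free", False) and grid.t_f != ocp.t_f:
        grid.t_f = float(ocp.t_f)
    if not getattr(ocp, "t_f_free", False):
        grid.t_f = float(ocp.t_f)
    return TranscribedNLP(ocp, grid)


# --------------------------------------------------------------------------
# solving


@dataclass
class Solution:
    controls: object  # ControlProfile
    t_f: float
    objective: float
    status: str
    success: bool
    n_iter: int
    z: np.ndarray
    terminal_states: list[np.ndarray]
    margins: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Solution(objective={self.objective:.6g}, t_f={self.t_f:.4g}, "
                f"success={self.success}, iterations={self.n_iter})")


def _default_guess(nlp: TranscribedNLP) -> np.ndarray:
    lb, ub = nlp.control_bounds()
    mid = np.where(np.isfinite(ub), 0.5 * (lb + ub), lb + 1.0)
    # respect a total-budget path constraint at mid bounds if one exists
    u0 = mid.reshape(nlp.grid.n_elements, nlp.n_u)
    probe = nlp.ocp.path_margins(nlp.systems[0].x0, u0[-1])
    if probe is not None and np.any(np.atleast_1d(probe) < 0):
        u0 = u0 / nlp.n_u  # scale down controls sharing a sum budget
        u0 = np.clip(u0, lb.reshape(u0.shape), ub.reshape(u0.shape))
    return nlp.pack(u0)


def _sequential_guess(nlp: TranscribedNLP) -> np.ndarray | None:
    """Stage-wise activation guess: control i fully on in the i-th time stage.

    Pathway enzymes are typically activated in their network order at the
    optimum (just-in-time activation), so this start frequently sits in the
    basin of the better local optimum for switching-type problems.
    """
    ne, nu = nlp.grid.n_elements, nlp.n_u
    if nu < 2 or ne < nu:
        return None
    lb, ub = nlp.control_bounds()
    lb = lb.reshape(ne, nu)
    ub = ub.reshape(ne, nu)
    u0 = np.zeros((ne, nu))
    edges = (np.arange(nu + 1) * ne) // nu
    for i in range(nu):
        cap = ub[edges[i]: edges[i + 1], i]
        u0[edges[i]: edges[i + 1], i] = np.where(np.isfinite(cap), cap, 1.0)
    u0 = np.clip(u0, lb, ub)
    return nlp.pack(u0)


def solve_nlp(nlp: TranscribedNLP, z0: np.ndarray | None = None,
              tol: float = 1e-8, max_iter: int = 400,
              strategy: str = "reduced") -> Solution:
    """Solve the transcribed NLP with SLSQP (KKT-type tolerance ``tol``)."""
    if strategy != "reduced":
        raise TranscriptionError("only the reduced strategy is wired into solve_nlp; "
                                 "use the residual interface for simultaneous solves")
    if z0 is None:
        z0 = _default_guess(nlp)
    z0 = np.asarray(z0, dtype=float)
    lb, ub = nlp.control_bounds()
    bounds = list(zip(lb, ub))
    if nlp.t_f_free:
        bounds.append(tuple(nlp.ocp.t_f_bounds))
    cons = [{"type": "ineq", "fun": nlp.inequality_margins}]
    res = minimize(nlp.objective, z0, method="SLSQP", bounds=bounds,
                   constraints=cons, options={"maxiter": max_iter, "ftol": tol})
    u, t_f = nlp.unpack(res.x)
    ro = nlp._rollout(res.x)
    from .models import ControlProfile  # local import to avoid cycles

    bnds = np.concatenate([[0.0], np.cumsum(nlp.grid.fractions)]) * t_f
    profile = ControlProfile(bnds, u)
    margins = nlp.inequality_margins(res.x)
    feasible = bool(np.all(margins >= -1e-6))
    return Solution(controls=profile, t_f=t_f, objective=float(res.fun),
                    status=res.message, success=bool(res.success and feasible),
                    n_iter=int(res.nit), z=np.asarray(res.x),
                    terminal_states=ro.terminal_states, margins=margins)


def solve_ocp(ocp, n_elements: int = 30, tol: float = 1e-8, max_iter: int = 400,
              z0: np.ndarray | None = None, refine_from: int | None = 10) -> Solution:
    """Transcribe and solve an OCP, optionally warm-starting from a coarser grid.

    A coarse solve (``refine_from`` elements) provides the initial control
    profile for the target grid; this continuation markedly improves the
    reliability of the SQP iterations on the switching-type optima these
    pathway problems exhibit.  On the coarse grid both a mid-bound start and
    a sequential-activation start are tried and the better converged solution
    is kept (the problems are multimodal in the control discretization).
    """
    if refine_from and refine_from < n_elements and z0 is None:
        coarse = solve_ocp(ocp, n_elements=refine_from, tol=tol,
                           max_iter=max_iter, refine_from=None)
        grid = CollocationGrid(n_elements, t_f=ocp.t_f)
        nlp = transcribe(ocp, grid)
        # piecewise-constant prolongation of the coarse control profile
        tmid = (np.concatenate([[0.0], np.cumsum(grid.fractions)])[:-1]
                + 0.5 * grid.fractions) * coarse.t_f
        u0 = np.vstack([coarse.controls.value_at(t) for t in tmid])
        z0 = nlp.pack(u0, coarse.t_f)
        return solve_nlp(nlp, z0=z0, tol=tol, max_iter=max_iter)
    grid = CollocationGrid(n_elements, t_f=ocp.t_f)
    nlp = transcribe(ocp, grid)
    if z0 is not None:
        return solve_nlp(nlp, z0=z0, tol=tol, max_iter=max_iter)
    best: Solution | None = None
    starts = [_default_guess(nlp)]
    seq = _sequential_guess(nlp)
    if seq is not None and not np.allclose(seq, starts[0]):
        starts.append(seq)
    for start in starts:
        sol = solve_nlp(nlp, z0=start, tol=tol, max_iter=max_iter)
        if best is None or (sol.success and
                            (not best.success or sol.objective < best.objective)):
            best = sol
    return best
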