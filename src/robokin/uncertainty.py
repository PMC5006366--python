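"""Parametric uncertainty propagation: linearization, sigma points, PCE.

Three techniques estimate the expected value and variance of trajectory
functionals R_k(x(t_f)) under uncertainty in the kinetic parameters theta:

* **Linearization** -- forward sensitivity equations dS/dt = (df/dx) S +
  (df/dtheta), S(0) = 0, integrated alongside the nominal states; the state
  covariance is the first-order propagation P = S Sigma S^T.  Valid for
  normally distributed parameters with small spread relative to the model
  curvature.  Augmented state count: (n_theta + 1) n_x.
* **Sigma points** (unscented transform) -- 2 n_theta + 1 deterministic
  parameter vectors theta_nom and theta_nom +/- columns of
  sqrt((n_theta + kappa) Sigma), with kappa = 3 - n_theta; the model is
  simulated at each point and weighted sample moments are formed.  Exact for
  affine maps, and matched to Gaussian fourth marginal moments by the choice
  of kappa.  Augmented state count: (2 n_theta + 1) n_x.
* **Polynomial chaos expansion (PCE)** of total degree p -- the response is
  regressed onto polynomials orthogonal under the parameter distribution
  (probabilists' Hermite for normal marginals, Legendre for uniform),
  evaluated at n_s = (n_theta + p)! / (n_theta! p!) sampling points; the mean
  is the zeroth coefficient and the variance the norm-weighted sum of squared
  higher coefficients.  Augmented state count: n_s * n_x.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from numpy.polynomial import hermite_e as herm
from numpy.polynomial import legendre as leg

from .models import ControlProfile, NetworkModel, simulate

TECHNIQUES = ("nominal", "linearization", "sigma_points", "pce1", "pce2")


# --------------------------------------------------------------------------
# uncertainty specification


@dataclass
class UncertaintySpec:
    """Distribution family, nominal parameters and covariance.

    ``rel_std`` builds a diagonal covariance with per-parameter standard
    deviation ``rel_std * theta_nom``.  For the uniform family the marginals
    are centred on theta_nom with the same standard deviation, i.e. support
    theta_nom +/- sqrt(3) * std.
    """

    family: str
    theta_nom: np.ndarray
    rel_std: float | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "uniform"):
            raise ValueError(f"unsupported distribution family {self.family!r}")
        self.theta_nom = np.asarray(self.theta_nom, dtype=float)
        if self.cov is None:
            if self.rel_std is None:
                raise ValueError("either rel_std or cov must be given")
            std = self.rel_std * self.theta_nom
            self.cov = np.diag(std ** 2)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.n_theta, self.n_theta):
            raise ValueError("covariance shape must be (n_theta, n_theta)")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.cov)) < -1e-10 * max(1.0, np.max(np.abs(self.cov))):
            raise ValueError("covariance must be positive semidefinite")

    @property
    def n_theta(self) -> int:
        return len(self.theta_nom)

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def psd_sqrt_columns(M: np.ndarray) -> np.ndarray:
    """A matrix square root L with L L^T = M; Cholesky when possible."""
    M = np.asarray(M, dtype=float)
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        if np.min(w) < -1e-10 * max(1.0, np.max(np.abs(M))):
            raise ValueError("matrix has a negative eigenvalue; not PSD") from None
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


# --------------------------------------------------------------------------
# sigma points


@dataclass
class SigmaPointSet:
    points: np.ndarray  # (2 n_theta + 1, n_theta); row 0 is theta_nom
    kappa: float

    @property
    def n_theta(self) -> int:
        return self.points.shape[1]

    @property
    def weights(self) -> np.ndarray:
        n, k = self.n_theta, self.kappa
        w = np.full(2 * n + 1, 1.0 / (2.0 * (n + k)))
        w[0] = k / (n + k)
        return w


def generate_sigma_points(spec: UncertaintySpec) -> SigmaPointSet:
    """Unscented-transform points theta_nom +/- sqrt((n+kappa) Sigma) columns."""
    n = spec.n_theta
    kappa = 3.0 - n
    L = psd_sqrt_columns((n + kappa) * spec.cov)
    pts = np.empty((2 * n + 1, n))
    pts[0] = spec.theta_nom
    for i in range(n):
        pts[1 + i] = spec.theta_nom + L[:, i]
        pts[1 + n + i] = spec.theta_nom - L[:, i]
    return SigmaPointSet(pts, kappa)


def sigma_point_moments(values, kappa: float) -> tuple[float, float]:
    """Weighted mean and variance of R over a sigma-point set."""
    v = np.asarray(values, dtype=float)
    if (len(v) - 1) % 2:
        raise ValueError("expected 2 n_theta + 1 values")
    n = (len(v) - 1) // 2
    denom = n + kappa
    mean = (kappa * v[0] + 0.5 * np.sum(v[1:], axis=0)) / denom
    dev = v - mean
    var = (kappa * dev[0] ** 2 + 0.5 * np.sum(dev[1:] ** 2, axis=0)) / denom
    return float(mean), float(var)


# --------------------------------------------------------------------------
# linearization: forward sensitivity system


class SensitivitySystem:
    """Nominal states augmented with forward sensitivities S = dx/dtheta.

    Quacks like a model for the simulation and transcription layers (``f``,
    ``jac_x`` with controls as the only remaining inputs besides the state;
    the uncertain parameters are fixed at their nominal values).
    """

    def __init__(self, model: NetworkModel, theta_nom: np.ndarray | None = None):
        self.model = model
        theta_nom = model.theta_nominal if theta_nom is None else np.asarray(theta_nom)
        self.theta_nom = theta_nom
        nx, nth = model.n_x, model.n_theta
        self.n_x = (nth + 1) * nx
        x_syms, u_syms, th_syms = model.symbols()
        S = sp.Matrix(nx, nth, lambda i, j: sp.Symbol(f"_S_{i}_{j}"))
        fvec = sp.Matrix(model.rhs_exprs())
        Jx = fvec.jacobian(x_syms)
        Jth = fvec.jacobian(th_syms)
        dS = Jx * S + Jth
        subs = dict(zip(th_syms, [sp.Float(v) for v in theta_nom]))
        exprs = [e.subs(subs) for e in fvec] + [dS[i, j].subs(subs)
                                               for j in range(nth) for i in range(nx)]
        aug_syms = list(x_syms) + [S[i, j] for j in range(nth) for i in range(nx)]
        self.state_names = list(model.state_names) + [
            f"S_{model.state_names[i]}_{model.param_names[j]}"
            for j in range(nth) for i in range(nx)]
        self.control_names = list(model.control_names)
        t = sp.Symbol("t")
        self._f = sp.lambdify((aug_syms, u_syms, t), exprs, modules="numpy")
        Jaug = sp.Matrix(exprs).jacobian(aug_syms)
        self._jac = sp.lambdify((aug_syms, u_syms, t), Jaug, modules="numpy")
        self.x0 = np.concatenate([model.x0, np.zeros(nth * nx)])
        self.n_u = model.n_u

    # model-like surface (theta is ignored: baked at nominal)
    def f(self, x, u, theta=None, t=0.0):
        return np.array([float(v) for v in self._f(x, u, t)])

    def jac_x(self, x, u, theta=None, t=0.0):
        return np.asarray(self._jac(x, u, t), dtype=float)

    def split(self, x_aug: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, S) with S of shape (n_x, n_theta), from an augmented state."""
        nx, nth = self.model.n_x, self.model.n_theta
        x = np.asarray(x_aug)[:nx]
        S = np.asarray(x_aug)[nx:].reshape(nth, nx).T
        return x, S


def build_sensitivity_system(model: NetworkModel,
                             theta_nom: np.ndarray | None = None) -> SensitivitySystem:
    """Augment a model with its forward sensitivity equations."""
    return SensitivitySystem(model, theta_nom)


def linearized_moments(x_aug_terminal, system: SensitivitySystem, Sigma,
                       grad_x: np.ndarray | None = None,
                       value_fn: Callable[[np.ndarray], float] | None = None,
                       state: str | None = None) -> tuple[float, float]:
    """First-order (mean, variance) of R(x(t_f)) from terminal sensitivities.

    ``R`` may be given as a single state name, a gradient row dR/dx together
    with a value function, or default to the identity on one state.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if np.min(np.linalg.eigvalsh(Sigma)) < -1e-10 * max(1.0, np.max(np.abs(Sigma))):
        raise ValueError("Sigma must be positive semidefinite")
    x, S = system.split(np.asarray(x_aug_terminal, dtype=float))
    if state is not None:
        j = system.model.state_names.index(state)
        grad_x = np.eye(system.model.n_x)[j]
        value = x[j]
    else:
        if grad_x is None or value_fn is None:
            raise ValueError("give either `state` or both `grad_x` and `value_fn`")
        value = value_fn(x)
    g = np.asarray(grad_x, dtype=float)
    gS = g @ S
    var = float(gS @ Sigma @ gS)
    return float(value), max(var, 0.0)


# --------------------------------------------------------------------------
# polynomial chaos expansion


def _poly_1d(family: str):
    """(eval(n, xi), norm(n), roots(n)) for the standardized 1-D basis.

    Normal: probabilists' Hermite He_n of a standard normal xi,
    E[He_n^2] = n!.  Uniform: Legendre P_n(xi / sqrt(3)) of xi uniform on
    [-sqrt(3), sqrt(3)] (unit variance), E[P_n^2] = 1 / (2n + 1).
    """
    if family == "normal":
        def ev(n, xi):
            c = np.zeros(n + 1)
            c[n] = 1.0
            return herm.hermeval(xi, c)

        return ev, lambda n: float(math.factorial(n)), \
            lambda n: herm.hermegauss(n)[0] if n else np.array([])
    if family == "uniform":
        def ev(n, xi):
            c = np.zeros(n + 1)
            c[n] = 1.0
            return leg.legval(np.asarray(xi) / math.sqrt(3.0), c)

        return ev, lambda n: 1.0 / (2 * n + 1), \
            lambda n: leg.leggauss(n)[0] * math.sqrt(3.0) if n else np.array([])
    raise ValueError(f"unsupported family {family!r}")


@dataclass
class PCEBasis:
    """Multivariate total-degree orthogonal polynomial basis with design points."""

    family: str
    order: int
    n_theta: int
    indices: list[tuple[int, ...]]  # multi-indices, graded order; indices[0] == 0
    norms: np.ndarray  # E[Phi_j^2], length L
    theta_nom: np.ndarray = field(default=None)  # type: ignore[assignment]
    transform: np.ndarray = field(default=None)  # type: ignore[assignment]  # theta = nom + T xi
    points_xi: np.ndarray = field(default=None)  # type: ignore[assignment]  # (n_s, n_theta)
    Lambda: np.ndarray = field(default=None)  # type: ignore[assignment]  # (L, n_s)

    @property
    def L(self) -> int:
        return len(self.indices)

    @property
    def n_s(self) -> int:
        return 0 if self.points_xi is None else self.points_xi.shape[0]

    @property
    def points_theta(self) -> np.ndarray:
        return self.theta_nom[None, :] + self.points_xi @ self.transform.T

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.Lambda))

    def eval_basis(self, xi: np.ndarray) -> np.ndarray:
        """Phi_j at standardized points; xi (m, n_theta) -> (L, m)."""
        xi = np.atleast_2d(np.asarray(xi, dtype=float))
        ev, _, _ = _poly_1d(self.family)
        out = np.empty((self.L, xi.shape[0]))
        for j, idx in enumerate(self.indices):
            col = np.ones(xi.shape[0])
            for d, n in enumerate(idx):
                if n:
                    col = col * ev(n, xi[:, d])
            out[j] = col
        return out


def _multi_indices(n_theta: int, p: int) -> list[tuple[int, ...]]:
    idx = [t for t in itertools.product(range(p + 1), repeat=n_theta) if sum(t) <= p]
    idx.sort(key=lambda t: (sum(t), t))
    return idx


def pce_term_count(n_theta: int, p: int) -> int:
    return math.comb(n_theta + p, p)


def build_pce_basis(spec: UncertaintySpec, p: int) -> PCEBasis:
    """Family-matched orthogonal basis of total degree <= p with design points."""
    if p < 1:
        raise ValueError("PCE order must be >= 1")
    _, norm1, _ = _poly_1d(spec.family)
    indices = _multi_indices(spec.n_theta, p)
    norms = np.array([np.prod([norm1(n) for n in idx]) for idx in indices])
    basis = PCEBasis(spec.family, p, spec.n_theta, indices, norms,
                     theta_nom=spec.theta_nom, transform=psd_sqrt_columns(spec.cov))
    select_sampling_points(basis, spec)
    return basis


def select_sampling_points(basis: PCEBasis, spec: UncertaintySpec) -> np.ndarray:
    """Choose n_s = L regression points from the tensor grid of quadrature roots.

    Candidates are the tensor combinations of the roots of the order (p + 1)
    univariate orthogonal polynomial, processed in shells of decreasing joint
    probability density (distance from the origin in standardized
    coordinates); within a shell, points are picked greedily D-optimally
    (largest determinant gain of the regression Gram matrix, lexicographic
    tie-break).  For even orders the nominal point is itself a quadrature
    root and heads the design, and for three parameters the order-2 design
    contains the full sigma-point set; for odd orders the design is a
    balanced fraction symmetric about the nominal point, which keeps the
    regressed moments centrally accurate.  Falls back to a 2L-point
    least-squares design if the square design is singular.
    """
    if np.allclose(spec.cov, 0.0):
        raise ValueError("degenerate (zero) covariance: sampling points coincide")
    _, _, roots_of = _poly_1d(basis.family)
    roots = np.sort(roots_of(basis.order + 1))
    cands = [np.array(c) for c in itertools.product(roots, repeat=basis.n_theta)]
    cands.sort(key=lambda c: (round(float(c @ c), 12), tuple(c)))
    origin = np.zeros(basis.n_theta)
    L = basis.L
    shells: list[list[np.ndarray]] = []
    last_r2 = None
    for c in cands:
        r2 = round(float(c @ c), 12)
        if r2 != last_r2:
            shells.append([])
            last_r2 = r2
        shells[-1].append(c)
    chosen: list[np.ndarray] = []
    Q: list[np.ndarray] = []  # orthonormal basis of the chosen design columns

    def residual(phi: np.ndarray) -> np.ndarray:
        for q in Q:
            phi = phi - (q @ phi) * q
        return phi

    for shell in shells:
        remaining = list(shell)
        while remaining and len(chosen) < L:
            best_i, best_res, best_norm = None, None, 1e-9
            for i, c in enumerate(remaining):
                res = residual(basis.eval_basis(c[None, :])[:, 0])
                nrm = float(np.linalg.norm(res))
                if nrm > best_norm + 1e-12:
                    best_i, best_res, best_norm = i, res, nrm
            if best_i is None:
                break  # shell adds no new rank
            chosen.append(remaining.pop(best_i))
            Q.append(best_res / best_norm)
        if len(chosen) == L:
            break
    if len(chosen) < L:  # least-squares fallback
        extra = [c for c in cands if not np.allclose(c, origin)][: 2 * L - 1]
        chosen = [origin] + extra
    pts = np.vstack(chosen)
    basis.points_xi = pts
    basis.Lambda = basis.eval_basis(pts)
    if np.linalg.matrix_rank(basis.Lambda @ basis.Lambda.T, tol=1e-9) < L:
        raise ValueError(
            f"singular PCE regression design (cond={basis.condition_number:.3g})")
    return basis.points_theta


def pce_moments(values, basis: PCEBasis) -> tuple[float, float, np.ndarray]:
    """Regress R onto the basis; return (mean, variance, coefficients)."""
    v = np.asarray(values, dtype=float)
    if len(v) != basis.n_s:
        raise ValueError(f"expected {basis.n_s} values, got {len(v)}")
    Lam = basis.Lambda
    a = np.linalg.solve(Lam @ Lam.T, Lam @ v)
    mean = float(a[0])
    var = float(np.sum(a[1:] ** 2 * basis.norms[1:]))
    return mean, max(var, 0.0), a


# --------------------------------------------------------------------------
# result container + fixed-control propagation driver


@dataclass
class PropagationResult:
    """Per-quantity (mean, variance) estimates for one propagation technique."""

    technique: str
    quantities: dict[str, tuple[float, float]]
    raw_values: dict[str, np.ndarray] = field(default_factory=dict)
    n_states: int = 0

    def mean(self, name: str) -> float:
        return self.quantities[name][0]

    def var(self, name: str) -> float:
        return self.quantities[name][1]

    def std(self, name: str) -> float:
        return math.sqrt(max(self.quantities[name][1], 0.0))

    def to_frame(self):
        import pandas as pd

        rows = [{"quantity": q, "technique": self.technique, "E": m, "Var": v,
                 "n_states": self.n_states}
                for q, (m, v) in self.quantities.items()]
        return pd.DataFrame(rows)


def augmented_state_count(technique: str, n_x: int, n_theta: int) -> int:
    """Dynamic state count of the augmented system for each technique."""
    if technique == "nominal":
        return n_x
    if technique == "linearization":
        return (n_theta + 1) * n_x
    if technique == "sigma_points":
        return (2 * n_theta + 1) * n_x
    if technique in ("pce1", "pce2"):
        p = int(technique[-1])
        return pce_term_count(n_theta, p) * n_x
    raise ValueError(f"unknown technique {technique!r}")


def propagate(model: NetworkModel, controls: ControlProfile, spec: UncertaintySpec,
              technique: str, quantities: Sequence[str] | None = None,
              rtol: float = 1e-8) -> PropagationResult:
    """Propagate parametric uncertainty to terminal states at fixed controls.

    ``quantities`` are terminal state names (default: the states appearing in
    the model's terminal constraints and terminal objectives).
    """
    if technique not in TECHNIQUES:
        raise ValueError(f"unknown technique {technique!r}; one of {TECHNIQUES}")
    if quantities is None:
        quantities = [c.expr for c in model.terminal_constraints
                      if c.expr in model.state_names]
        quantities += [o.expr for o in model.objectives
                       if o.kind == "terminal" and o.expr in model.state_names]
    result = PropagationResult(technique, {},
                               n_states=augmented_state_count(technique, model.n_x,
                                                              spec.n_theta))
    if technique == "nominal":
        traj = simulate(model, controls, spec.theta_nom, rtol=rtol)
        for q in quantities:
            result.quantities[q] = (traj.terminal(q), 0.0)
        return result
    if technique == "linearization":
        if spec.family != "normal":
            raise ValueError("the linearization technique assumes normal uncertainty")
        system = build_sensitivity_system(model, spec.theta_nom)
        traj = simulate(system, controls, spec.theta_nom, rtol=rtol)
        xT = traj.states[-1]
        for q in quantities:
            result.quantities[q] = linearized_moments(xT, system, spec.cov, state=q)
        return result
    if technique == "sigma_points":
        sps = generate_sigma_points(spec)
        terms = [simulate(model, controls, th, rtol=rtol).states[-1]
                 for th in sps.points]
        for q in quantities:
            j = model.state_names.index(q)
            vals = np.array([t[j] for t in terms])
            result.raw_values[q] = vals
            result.quantities[q] = sigma_point_moments(vals, sps.kappa)
        return result
    # PCE
    p = int(technique[-1])
    basis = build_pce_basis(spec, p)
    terms = [simulate(model, controls, th, rtol=rtol).states[-1]
             for th in basis.points_theta]
    for q in quantities:
        j = model.state_names.index(q)
        vals = np.array([t[j] for t in terms])
        result.raw_values[q] = vals
        mean, var, _ = pce_moments(vals, basis)
        result.quantities[q] = (mean, var)
    return result
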