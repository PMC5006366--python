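"""Kinetic network ODE models and their simulation.

A :class:`NetworkModel` is a declarative description of a metabolic reaction
network: a stoichiometric matrix ``N`` (one row per integrated metabolite, one
column per flux), a rate law per flux (mass-action or Michaelis-Menten), a set
of controls (either enzyme concentrations manipulated directly, or enzyme
expression rates feeding enzyme balance ODEs), auxiliary integrator states for
integral objectives, and the constraints/objectives of the associated optimal
control problem.  The right-hand side ``dx/dt = N v(x, u, theta)`` (stacked
with the auxiliary integrands) is assembled symbolically with sympy, so exact
Jacobians with respect to states, controls and parameters are available to the
uncertainty-propagation and transcription layers.

Two case-study fixtures ship with the package:

* :func:`case1_model` -- a three-step linear pathway with mass-action kinetics
  turning a buffered substrate S1 into a product S4, where the accumulation of
  the intermediates S2 + S3 is minimized subject to a minimum terminal product
  concentration.
* :func:`case2_model` -- a glycolysis-inspired branched network with
  Michaelis-Menten kinetics, dynamic enzyme balances de/dt = r - lambda*e
  driven by expression-rate controls, and a trade-off between time-to-target
  and enzymatic cost (the time integral of total enzyme concentration).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sympy as sp
import yaml
from scipy.integrate import solve_ivp


class ModelStructureError(ValueError):
    """Inconsistent model declaration (dimensions, unknown labels, ...)."""


class SimulationError(RuntimeError):
    """Forward integration failed."""


# --------------------------------------------------------------------------
# declarative pieces


@dataclass
class RateLaw:
    """Kinetics of one reaction flux.

    ``kind`` is ``"mass_action"`` (v = k * S * e) or ``"michaelis_menten"``
    (v = kcat * S / (K_M + S) * e).  ``enzyme`` may name a control or a state.
    """

    kind: str
    substrate: str
    enzyme: str
    rate_constant: str
    km: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mass_action", "michaelis_menten"):
            raise ModelStructureError(f"unknown rate law kind {self.kind!r}")
        if self.kind == "michaelis_menten" and self.km is None:
            raise ModelStructureError("michaelis_menten rate law needs a km parameter")


@dataclass
class ExtraState:
    """Auxiliary integrator state with dx/dt = integrand(x, u)."""

    name: str
    integrand: str
    x0: float = 0.0


@dataclass
class PathConstraint:
    """Inequality expr(x, u) <= bound (direction 'le') or >= bound ('ge')."""

    expr: str
    bound: float
    direction: str = "le"


@dataclass
class TerminalConstraint:
    """Terminal inequality on expr(x(t_f)); chance constraints get a backoff."""

    expr: str
    bound: float
    direction: str = "ge"
    chance: bool = True


@dataclass
class Objective:
    """Objective, either a terminal expression or the final time itself."""

    name: str
    kind: str = "terminal"  # "terminal" | "final_time"
    expr: str | None = None
    robustify: bool = False


@dataclass
class ControlProfile:
    """Piecewise-constant control parameterization on an element grid."""

    grid: np.ndarray  # element boundaries, length n_el + 1, strictly increasing
    values: np.ndarray  # (n_el, n_u)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.grid) <= 0):
            raise ModelStructureError("control grid must be strictly increasing")
        if self.values.shape[0] != len(self.grid) - 1:
            raise ModelStructureError("one control vector per element is required")

    @property
    def t_f(self) -> float:
        return float(self.grid[-1])

    @property
    def n_elements(self) -> int:
        return len(self.grid) - 1

    def value_at(self, t: float) -> np.ndarray:
        idx = int(np.clip(np.searchsorted(self.grid, t, side="right") - 1, 0,
                          self.n_elements - 1))
        return self.values[idx]

    @classmethod
    def constant(cls, u: Sequence[float], t_f: float, n_elements: int = 1) -> "ControlProfile":
        grid = np.linspace(0.0, t_f, n_elements + 1)
        values = np.tile(np.asarray(u, dtype=float), (n_elements, 1))
        return cls(grid, values)


@dataclass
class Trajectory:
    """Simulated state (and control) history on an output time grid."""

    times: np.ndarray
    states: np.ndarray  # (n_t, n_x)
    state_names: list[str]
    controls: np.ndarray | None = None  # (n_t, n_u)
    control_names: list[str] | None = None

    def state(self, name: str) -> np.ndarray:
        try:
            j = self.state_names.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r}") from None
        return self.states[:, j]

    def terminal(self, name: str) -> float:
        return float(self.state(name)[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, state, value) table."""
        frames = [
            pd.DataFrame({"time": self.times, "state": name, "value": self.states[:, j]})
            for j, name in enumerate(self.state_names)
        ]
        return pd.concat(frames, ignore_index=True)

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.state_names)
        df.insert(0, "time", self.times)
        if self.controls is not None and self.control_names:
            for j, name in enumerate(self.control_names):
                df[name] = self.controls[:, j]
        return df

    def write_csv(self, path, wide: bool = True) -> None:
        (self.to_wide_frame() if wide else self.to_frame()).to_csv(path, index=False)


# --------------------------------------------------------------------------
# the model


@dataclass
class NetworkModel:
    """Kinetic network ODE model with controls, constraints and objectives."""

    name: str
    species: list[str]  # integrated metabolites, in stoichiometry row order
    stoichiometry: np.ndarray  # (n_species, n_reactions)
    rate_laws: list[RateLaw]
    control_names: list[str]
    param_names: list[str]
    theta_nominal: np.ndarray
    x0: np.ndarray  # initial values of species + extra states
    control_kind: str = "direct_concentration"  # or "expression_rate"
    extra_states: list[ExtraState] = field(default_factory=list)
    buffered_species: list[str] = field(default_factory=list)
    constants: dict[str, float] = field(default_factory=dict)  # non-integrated species
    control_lb: np.ndarray | None = None
    control_ub: np.ndarray | None = None
    fixed_initial_controls: np.ndarray | None = None  # pin first-element controls
    path_constraints: list[PathConstraint] = field(default_factory=list)
    terminal_constraints: list[TerminalConstraint] = field(default_factory=list)
    objectives: list[Objective] = field(default_factory=list)
    t_f: float = 1.0
    t_f_free: bool = False
    t_f_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.theta_nominal = np.asarray(self.theta_nominal, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        n_sp, n_rx = self.stoichiometry.shape
        if n_sp != len(self.species):
            raise ModelStructureError("stoichiometry needs one row per integrated species")
        if n_rx != len(self.rate_laws):
            raise ModelStructureError("stoichiometry needs one column per reaction flux")
        if len(self.theta_nominal) != len(self.param_names):
            raise ModelStructureError("theta_nominal length must match param_names")
        if len(self.x0) != self.n_x:
            raise ModelStructureError("x0 length must match number of integrated states")
        for s in self.buffered_species:
            if s in self.species:
                row = self.stoichiometry[self.species.index(s)]
                if np.any(row != 0.0):
                    raise ModelStructureError(
                        f"buffered species {s!r} must have a zero stoichiometry row")
            elif s not in self.constants:
                raise ModelStructureError(
                    f"buffered species {s!r} is neither integrated nor a declared constant")
        if self.control_lb is None:
            self.control_lb = np.zeros(self.n_u)
        if self.control_ub is None:
            self.control_ub = np.full(self.n_u, np.inf)
        self.control_lb = np.asarray(self.control_lb, dtype=float)
        self.control_ub = np.asarray(self.control_ub, dtype=float)
        self._cache: dict[str, object] = {}

    # -- bookkeeping ------------------------------------------------------

    @property
    def state_names(self) -> list[str]:
        return list(self.species) + [e.name for e in self.extra_states]

    @property
    def n_x(self) -> int:
        return len(self.species) + len(self.extra_states)

    @property
    def n_u(self) -> int:
        return len(self.control_names)

    @property
    def n_theta(self) -> int:
        return len(self.param_names)

    # -- symbolic assembly ------------------------------------------------

    def symbols(self):
        x = sp.symbols(self.state_names)
        u = sp.symbols(self.control_names)
        th = sp.symbols(self.param_names)
        # sp.symbols returns a bare Symbol for a single name
        as_list = lambda s: list(s) if isinstance(s, (tuple, list)) else [s]
        return as_list(x), as_list(u), as_list(th)

    def _symbol_map(self):
        x, u, th = self.symbols()
        smap: dict[str, sp.Expr] = {}
        for name, s in zip(self.state_names, x):
            smap[name] = s
        for name, s in zip(self.control_names, u):
            smap[name] = s
        for name, s in zip(self.param_names, th):
            smap[name] = s
        for name, val in self.constants.items():
            smap[name] = sp.Float(val)
        return x, u, th, smap

    def rhs_exprs(self) -> list[sp.Expr]:
        """Symbolic state derivatives: N v stacked with extra-state integrands."""
        if "rhs" in self._cache:
            return self._cache["rhs"]  # type: ignore[return-value]
        x, u, th, smap = self._symbol_map()
        fluxes = []
        for law in self.rate_laws:
            if law.substrate not in smap:
                raise ModelStructureError(f"unknown substrate {law.substrate!r}")
            if law.enzyme not in smap:
                raise ModelStructureError(f"unknown enzyme binding {law.enzyme!r}")
            S = smap[law.substrate]
            e = smap[law.enzyme]
            k = smap[law.rate_constant]
            if law.kind == "mass_action":
                fluxes.append(k * S * e)
            else:
                km = smap[law.km]
                fluxes.append(k * S / (km + S) * e)
        exprs = []
        for i, name in enumerate(self.species):
            d = sp.Integer(0)
            for j, v in enumerate(fluxes):
                coef = self.stoichiometry[i, j]
                if coef != 0.0:
                    d = d + sp.Float(coef) * v
            exprs.append(sp.simplify(d) if d != 0 else sp.Float(0))
        for ext in self.extra_states:
            exprs.append(sp.sympify(ext.integrand, locals=smap))
        self._cache["rhs"] = exprs
        return exprs

    def expression(self, text: str) -> sp.Expr:
        """Sympify an expression in state/control/parameter names."""
        _, _, _, smap = self._symbol_map()
        return sp.sympify(text, locals=smap)

    def _lambdify(self, key: str, exprs) -> Callable:
        if key not in self._cache:
            x, u, th = self.symbols()
            self._cache[key] = sp.lambdify((x, u, th, sp.Symbol("t")), exprs,
                                           modules="numpy")
        return self._cache[key]  # type: ignore[return-value]

    @property
    def f(self) -> Callable[[np.ndarray, np.ndarray, np.ndarray, float], np.ndarray]:
        fun = self._lambdify("f", self.rhs_exprs())

        def rhs(x, u, th, t=0.0):
            out = fun(x, u, th, t)
            return np.array([float(v) for v in out])

        return rhs

    @property
    def f_batch(self) -> Callable:
        """Vectorized right-hand side: x (n_x, N), theta (n_theta, N) -> (n_x, N)."""
        fun = self._lambdify("f", self.rhs_exprs())

        def rhs(x, u, th, t=0.0):
            out = fun(list(x), list(u), list(th), t)
            n = x.shape[1] if x.ndim > 1 else 1
            return np.vstack([np.broadcast_to(np.asarray(v, dtype=float), (n,))
                              for v in out])

        return rhs

    def _jacobian(self, wrt: str) -> Callable:
        key = f"jac_{wrt}"
        if key not in self._cache:
            x, u, th = self.symbols()
            cols = {"x": x, "u": u, "theta": th}[wrt]
            J = sp.Matrix(self.rhs_exprs()).jacobian(cols)
            fun = sp.lambdify((x, u, th, sp.Symbol("t")), J, modules="numpy")
            self._cache[key] = fun
        fun = self._cache[key]

        def jac(x, u, th, t=0.0):
            return np.asarray(fun(x, u, th, t), dtype=float)

        return jac

    @property
    def jac_x(self) -> Callable:
        return self._jacobian("x")

    @property
    def jac_u(self) -> Callable:
        return self._jacobian("u")

    @property
    def jac_theta(self) -> Callable:
        return self._jacobian("theta")


def evaluate_rhs(model: NetworkModel, x, u, theta, t: float = 0.0) -> np.ndarray:
    """Evaluate dx/dt = N v(x, u, theta) stacked with extra-state integrands."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if x.shape != (model.n_x,):
        raise ModelStructureError(
            f"state vector has length {x.size}, model has {model.n_x} states")
    if u.shape != (model.n_u,):
        raise ModelStructureError(
            f"control vector has length {u.size}, model has {model.n_u} controls")
    if theta.shape != (model.n_theta,):
        raise ModelStructureError(
            f"parameter vector has length {theta.size}, model has {model.n_theta}")
    return model.f(x, u, theta, t)


# --------------------------------------------------------------------------
# simulation


def simulate(model, controls: ControlProfile, theta, output_times=None,
             rtol: float = 1e-8, atol: float = 1e-10, method: str = "LSODA") -> Trajectory:
    """Integrate the model under a piecewise-constant control profile.

    Integration proceeds element by element so control discontinuities fall on
    integrator restarts.  ``model`` may be any object exposing ``f``,
    ``state_names``, ``x0`` and ``n_u`` (a :class:`NetworkModel` or an
    augmented system from the uncertainty layer).
    """
    theta = np.asarray(theta, dtype=float)
    t_f = controls.t_f
    if output_times is None:
        output_times = np.linspace(0.0, t_f, 201)
    output_times = np.asarray(output_times, dtype=float)
    if output_times[0] < -1e-12 or output_times[-1] > t_f + 1e-9:
        raise SimulationError("output_times must lie within [0, t_f]")

    f = model.f
    times: list[float] = []
    states: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    x = np.array(model.x0, dtype=float)
    eps = 1e-12
    for e in range(controls.n_elements):
        t0, t1 = controls.grid[e], controls.grid[e + 1]
        u = controls.values[e]
        mask = (output_times >= t0 - eps) & (output_times <= t1 + eps)
        if e > 0:  # element boundaries belong to the left element's output
            mask &= output_times > t0 + eps
        t_req = np.clip(output_times[mask], t0, t1)
        sol = solve_ivp(lambda t, y: f(y, u, theta, t), (t0, t1), x,
                        method=method, rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            raise SimulationError(f"integrator failed on element {e}: {sol.message}")
        x = sol.y[:, -1]
        if len(t_req):
            times.extend(t_req.tolist())
            states.extend(sol.sol(t_req).T)
            ctrls.extend([u] * len(t_req))
    return Trajectory(np.array(times), np.array(states), list(model.state_names),
                      np.array(ctrls), list(getattr(model, "control_names", []) or []))


def simulate_batch(model: NetworkModel, controls: ControlProfile, thetas,
                   substeps_per_element: int = 40) -> np.ndarray:
    """Vectorized fixed-step RK4 terminal-state simulation for many parameter sets.

    Intended for large Monte-Carlo ensembles where per-sample adaptive
    integration is wasteful; returns terminal states, shape (N, n_x).  The
    systems at hand are smooth and non-stiff, so classical RK4 with ~40
    substeps per control element resolves them to well below the Monte-Carlo
    noise floor (verified against the adaptive integrator in the tests).
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    n = thetas.shape[0]
    th = thetas.T  # (n_theta, N)
    f = model.f_batch
    x = np.repeat(np.asarray(model.x0, dtype=float)[:, None], n, axis=1)
    for e in range(controls.n_elements):
        t0, t1 = controls.grid[e], controls.grid[e + 1]
        u = controls.values[e]
        h = (t1 - t0) / substeps_per_element
        t = t0
        for _ in range(substeps_per_element):
            k1 = f(x, u, th, t)
            k2 = f(x + 0.5 * h * k1, u, th, t + 0.5 * h)
            k3 = f(x + 0.5 * h * k2, u, th, t + 0.5 * h)
            k4 = f(x + h * k3, u, th, t + h)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
    return x.T


def threshold_time(traj: Trajectory, species: str, threshold: float) -> float | None:
    """First time a state crosses ``threshold`` from below (linear interpolation).

    Returns ``None`` if the threshold is never reached.
    """
    y = traj.state(species)
    t = traj.times
    if y[0] >= threshold:
        return float(t[0])
    above = np.nonzero(y >= threshold)[0]
    if len(above) == 0:
        return None
    i = above[0]
    frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


# --------------------------------------------------------------------------
# fixtures


def case1_model(E_T: float = 1.0, t_f: float = 10.0, s4_min: float = 0.90,
                x0: Sequence[float] | None = None) -> NetworkModel:
    """Three-step linear pathway with mass-action kinetics.

    States: S1 (buffered substrate, trivially integrated with zero
    stoichiometry row), intermediates S2, S3, product S4, and the intermediate
    accumulation integrator x_extra.  Controls: the three enzyme
    concentrations e1..e3 in [0, E_T] with sum(e) <= E_T.  Uncertain
    parameters: rate constants k1..k3, nominal 1 (mM s)^-1.  Objective:
    minimize x_extra(t_f) = integral of S2 + S3; terminal chance constraint
    S4(t_f) >= 0.90 mM.
    """
    N = np.array([
        [0, 0, 0],
        [1, -1, 0],
        [0, 1, -1],
        [0, 0, 1],
    ], dtype=float)
    if x0 is None:
        x0 = [1.0, 0.0, 0.0, 0.0, 0.0]  # S1, S2, S3, S4, x_extra
    return NetworkModel(
        name="case1",
        species=["S1", "S2", "S3", "S4"],
        stoichiometry=N,
        rate_laws=[
            RateLaw("mass_action", "S1", "e1", "k1"),
            RateLaw("mass_action", "S2", "e2", "k2"),
            RateLaw("mass_action", "S3", "e3", "k3"),
        ],
        control_names=["e1", "e2", "e3"],
        param_names=["k1", "k2", "k3"],
        theta_nominal=np.ones(3),
        x0=np.asarray(x0, dtype=float),
        control_kind="direct_concentration",
        extra_states=[ExtraState("x_extra", "S2 + S3")],
        buffered_species=["S1"],
        control_lb=np.zeros(3),
        control_ub=np.full(3, E_T),
        path_constraints=[PathConstraint("e1 + e2 + e3", E_T, "le")],
        terminal_constraints=[TerminalConstraint("S4", s4_min, "ge", chance=True)],
        objectives=[Objective("intermediate_accumulation", "terminal", "x_extra",
                              robustify=False)],
        t_f=t_f,
    )


def case2_model(E_T: float = 1.0, t_f: float = 30.0, s5_min: float = 0.675,
                r_total: float = 0.5, t_f_free: bool = False) -> NetworkModel:
    """Glycolysis-inspired branched network with Michaelis-Menten kinetics.

    The substrate S1 is buffered at 1 mM and not integrated; intracellular
    metabolites S2..S4 and product S5 are integrated together with the four
    enzyme balances de_i/dt = r_i - lambda e_i and the enzymatic-cost
    integrator x_extra (integral of sum(e)).  Controls are the expression
    rates r1..r4 with sum(r) <= 0.5 and the pinned start r(t0) = (0.5, 0, 0,
    0).  Uncertain parameters: k_cat = 1 1/s, K_M = 1 mM, lambda = 0.5 1/s.
    Objectives: final time (for the bi-objective trade-off) and the enzymatic
    cost x_extra(t_f); terminal chance constraint S5(t_f) >= 0.675 mM.
    """
    # rows S2..S5, columns v1..v4 (v2 branches S2 into S3 and S4)
    N = np.array([
        [1, -1, 0, 0],
        [0, 1, -1, 0],
        [0, 1, 1, -1],
        [0, 0, 0, 1],
    ], dtype=float)
    extra = [ExtraState(f"e{i}", f"r{i} - lam*e{i}") for i in range(1, 5)]
    extra.append(ExtraState("x_extra", "e1 + e2 + e3 + e4"))
    return NetworkModel(
        name="case2",
        species=["S2", "S3", "S4", "S5"],
        stoichiometry=N,
        rate_laws=[
            RateLaw("michaelis_menten", "S1", "e1", "kcat", km="KM"),
            RateLaw("michaelis_menten", "S2", "e2", "kcat", km="KM"),
            RateLaw("michaelis_menten", "S3", "e3", "kcat", km="KM"),
            RateLaw("michaelis_menten", "S4", "e4", "kcat", km="KM"),
        ],
        control_names=["r1", "r2", "r3", "r4"],
        param_names=["kcat", "KM", "lam"],
        theta_nominal=np.array([1.0, 1.0, 0.5]),
        x0=np.zeros(9),
        control_kind="expression_rate",
        extra_states=extra,
        buffered_species=["S1"],
        constants={"S1": 1.0},
        control_lb=np.zeros(4),
        control_ub=np.full(4, r_total),
        fixed_initial_controls=np.array([0.5, 0.0, 0.0, 0.0]),
        path_constraints=[
            PathConstraint("e1 + e2 + e3 + e4", E_T, "le"),
            PathConstraint("r1 + r2 + r3 + r4", r_total, "le"),
        ],
        terminal_constraints=[TerminalConstraint("S5", s5_min, "ge", chance=True)],
        objectives=[
            Objective("final_time", "final_time", robustify=False),
            Objective("enzymatic_cost", "terminal", "x_extra", robustify=True),
        ],
        t_f=t_f,
        t_f_free=t_f_free,
        t_f_bounds=(1.0, t_f),
    )


MODEL_REGISTRY: dict[str, Callable[..., NetworkModel]] = {
    "case1": case1_model,
    "case2": case2_model,
}


def get_model(model_id: str, **kwargs) -> NetworkModel:
    try:
        factory = MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; "
                       f"registered: {sorted(MODEL_REGISTRY)}") from None
    return factory(**kwargs)


# --------------------------------------------------------------------------
# declarative round trip


def model_to_dict(model: NetworkModel) -> dict:
    d = {
        "name": model.name,
        "species": list(model.species),
        "stoichiometry": model.stoichiometry.tolist(),
        "rate_laws": [asdict(r) for r in model.rate_laws],
        "control_names": list(model.control_names),
        "param_names": list(model.param_names),
        "theta_nominal": model.theta_nominal.tolist(),
        "x0": model.x0.tolist(),
        "control_kind": model.control_kind,
        "extra_states": [asdict(e) for e in model.extra_states],
        "buffered_species": list(model.buffered_species),
        "constants": dict(model.constants),
        "control_lb": model.control_lb.tolist(),
        "control_ub": model.control_ub.tolist(),
        "fixed_initial_controls": (None if model.fixed_initial_controls is None
                                   else np.asarray(model.fixed_initial_controls).tolist()),
        "path_constraints": [asdict(c) for c in model.path_constraints],
        "terminal_constraints": [asdict(c) for c in model.terminal_constraints],
        "objectives": [asdict(o) for o in model.objectives],
        "t_f": float(model.t_f),
        "t_f_free": bool(model.t_f_free),
        "t_f_bounds": list(model.t_f_bounds) if model.t_f_bounds else None,
    }
    return d


def model_from_dict(d: dict) -> NetworkModel:
    return NetworkModel(
        name=d["name"],
        species=list(d["species"]),
        stoichiometry=np.asarray(d["stoichiometry"], dtype=float),
        rate_laws=[RateLaw(**r) for r in d["rate_laws"]],
        control_names=list(d["control_names"]),
        param_names=list(d["param_names"]),
        theta_nominal=np.asarray(d["theta_nominal"], dtype=float),
        x0=np.asarray(d["x0"], dtype=float),
        control_kind=d.get("control_kind", "direct_concentration"),
        extra_states=[ExtraState(**e) for e in d.get("extra_states", [])],
        buffered_species=list(d.get("buffered_species", [])),
        constants=dict(d.get("constants", {})),
        control_lb=np.asarray(d["control_lb"], dtype=float),
        control_ub=np.asarray(d["control_ub"], dtype=float),
        fixed_initial_controls=(None if d.get("fixed_initial_controls") is None
                                else np.asarray(d["fixed_initial_controls"], dtype=float)),
        path_constraints=[PathConstraint(**c) for c in d.get("path_constraints", [])],
        terminal_constraints=[TerminalConstraint(**c)
                              for c in d.get("terminal_constraints", [])],
        objectives=[Objective(**o) for o in d.get("objectives", [])],
        t_f=float(d["t_f"]),
        t_f_free=bool(d.get("t_f_free", False)),
        t_f_bounds=tuple(d["t_f_bounds"]) if d.get("t_f_bounds") else None,
    )


def save_model(model: NetworkModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> NetworkModel:
    if isinstance(path, io.IOBase):
        return model_from_dict(yaml.safe_load(path))
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
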