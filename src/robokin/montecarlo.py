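"""Monte-Carlo validation of (robustified) control profiles.

Robustified controls are fixed and the closed model is re-simulated for N
parameter sets drawn from the uncertainty distribution; the report collects
the per-realization terminal-constraint and objective values, the violation
count against the printed bound, and empirical means/standard deviations.
Violations are counted with a strict inequality (ties have measure zero for
continuous distributions).  Reports are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ControlProfile, NetworkModel, SimulationError, simulate
from .uncertainty import UncertaintySpec, psd_sqrt_columns

SQRT3 = math.sqrt(3.0)


def sample_parameters(spec: UncertaintySpec, N: int, seed: int | np.random.Generator = 0,
                      truncate_nonnegative: bool = False) -> np.ndarray:
    """Draw N parameter sets from the uncertainty distribution, shape (N, n_theta).

    Normal draws are not truncated by default (at 20 % relative standard
    deviation the probability of a negative rate constant is ~3e-7 per draw);
    ``truncate_nonnegative`` resamples negative rows if requested.
    """
    if N < 1:
        raise ValueError("need at least one realization")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.family == "normal":
        L = psd_sqrt_columns(spec.cov)
        draws = spec.theta_nom + rng.standard_normal((N, spec.n_theta)) @ L.T
        if truncate_nonnegative:
            for _ in range(100):
                bad = np.any(draws < 0, axis=1)
                if not bad.any():
                    break
                draws[bad] = (spec.theta_nom
                              + rng.standard_normal((bad.sum(), spec.n_theta)) @ L.T)
        return draws
    # uniform: independent marginals, mean theta_nom, std from the diagonal
    half = SQRT3 * spec.std
    return spec.theta_nom + rng.uniform(-1.0, 1.0, (N, spec.n_theta)) * half


@dataclass
class MCReport:
    """Violation counts and empirical moments over N Monte-Carlo realizations."""

    N: int
    seed: int | None
    constraint_expr: str
    bound: float
    direction: str
    constraint_values: np.ndarray
    objective_values: np.ndarray
    n_failures: int = 0

    @property
    def violations(self) -> int:
        ok = np.isfinite(self.constraint_values)
        v = self.constraint_values[ok]
        return int(np.sum(v < self.bound) if self.direction == "ge"
                   else np.sum(v > self.bound))

    @property
    def violation_percentage(self) -> float:
        return 100.0 * self.violations / self.N

    @property
    def objective_mean(self) -> float:
        return float(np.nanmean(self.objective_values))

    @property
    def objective_std(self) -> float:
        return float(np.nanstd(self.objective_values, ddof=1))

    @property
    def constraint_mean(self) -> float:
        return float(np.nanmean(self.constraint_values))

    @property
    def constraint_std(self) -> float:
        return float(np.nanstd(self.constraint_values, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quantity": ["J_mean", "J_std", "c_t_mean", "c_t_std",
                          "violations", "violation_pct", "failures"],
             "value": [self.objective_mean, self.objective_std,
                       self.constraint_mean, self.constraint_std,
                       self.violations, self.violation_percentage,
                       self.n_failures]})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def validate_controls(model: NetworkModel, controls: ControlProfile, samples,
                      constraint=None, objective: str | None = None,
                      seed: int | None = None, rtol: float = 1e-8) -> MCReport:
    """Simulate each parameter realization under fixed controls and count violations.

    ``samples`` is either an (N, n_theta) array or an integer N combined with
    the model-attached defaults.  Integration failures are counted separately
    (as NaN rows), never silently dropped.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if constraint is None:
        if not model.terminal_constraints:
            raise ValueError("model declares no terminal constraint to validate")
        constraint = model.terminal_constraints[0]
    if objective is None:
        objective = next(o.expr for o in model.objectives if o.kind == "terminal")
    if np.any(controls.values < model.control_lb - 1e-9) or \
       np.any(controls.values > model.control_ub + 1e-9):
        raise ValueError("control profile violates the declared control bounds")
    idx_c = model.state_names.index(constraint.expr)
    idx_j = model.state_names.index(objective)
    cvals = np.full(len(samples), np.nan)
    jvals = np.full(len(samples), np.nan)
    failures = 0
    t_end = np.array([controls.t_f])
    for i, theta in enumerate(samples):
        try:
            traj = simulate(model, controls, theta, output_times=t_end, rtol=rtol)
        except SimulationError:
            failures += 1
            continue
        cvals[i] = traj.states[-1, idx_c]
        jvals[i] = traj.states[-1, idx_j]
    return MCReport(N=len(samples), seed=seed, constraint_expr=constraint.expr,
                    bound=constraint.bound, direction=constraint.direction,
                    constraint_values=cvals, objective_values=jvals,
                    n_failures=failures)


def monte_carlo_summary_table(reports: dict[str, MCReport]) -> pd.DataFrame:
    """Technique-by-column table mirroring the usual validation report layout."""
    rows = ["J_mean", "J_std", "c_t_mean", "c_t_std", "violations", "violation_pct"]
    data = {}
    for name, rep in reports.items():
        data[name] = [rep.objective_mean, rep.objective_std, rep.constraint_mean,
                      rep.constraint_std, rep.violations, rep.violation_percentage]
    return pd.DataFrame(data, index=rows)
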