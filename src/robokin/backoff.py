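"""Chance-constraint backoff: quantile and Cantelli-Chebyshev policies.

A single chance constraint  Pr[c(x(t_f)) >= c_min] >= beta  is approximated
deterministically by backing the expected value off from the bound:

    c_min <= E[c] - alpha * sqrt(Var[c])

For a normally distributed constraint function, alpha is the one-sided
standard-normal quantile of beta.  Without distributional assumptions the
Cantelli-Chebyshev inequality gives the conservative alpha =
sqrt(beta / (1 - beta)) (4.36 at beta = 0.95 versus 1.96 for a normal at
beta = 0.975).  Objectives are robustified analogously by adding
alpha * sqrt(Var[J]) (or alpha * Var[J]) to the expected value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

#: Conventional two-decimal one-sided normal quantiles for the backoff levels
#: commonly tabulated (confidence -> alpha).
QUANTILE_TABLE = {0.80: 0.84, 0.90: 1.28, 0.95: 1.65, 0.975: 1.96}


def backoff_from_confidence(beta: float, method: str = "normal_quantile") -> float:
    """Backoff parameter alpha for a target confidence level beta in (0, 1)."""
    if not 0.0 < beta < 1.0:
        raise ValueError("confidence level must lie strictly between 0 and 1")
    if method == "normal_quantile":
        for level, alpha in QUANTILE_TABLE.items():
            if abs(beta - level) < 1e-12:
                return alpha
        return float(norm.ppf(beta))
    if method == "cantelli":
        return math.sqrt(beta / (1.0 - beta))
    raise ValueError(f"unknown backoff method {method!r}")


def robustify_constraint(E: float, Var: float, alpha: float, bound: float,
                         direction: str = "ge") -> float:
    """Feasibility margin of a backed-off constraint (feasible iff >= 0).

    For a lower bound (direction 'ge', bound <= c): E - alpha sqrt(Var) - bound.
    For an upper bound (direction 'le'): bound - E - alpha sqrt(Var).
    """
    if Var < 0:
        raise ValueError("variance must be non-negative")
    backoff = alpha * math.sqrt(Var)
    if direction == "ge":
        return E - backoff - bound
    if direction == "le":
        return bound - E - backoff
    raise ValueError(f"unknown constraint direction {direction!r}")


def robustify_objective(E: float, Var: float, alpha: float,
                        form: str = "sqrt_variance") -> float:
    """Robustified objective E + alpha * sqrt(Var) (or E + alpha * Var)."""
    if Var < 0:
        raise ValueError("variance must be non-negative")
    if form == "sqrt_variance":
        return E + alpha * math.sqrt(Var)
    if form == "variance":
        return E + alpha * Var
    raise ValueError(f"unknown objective penalty form {form!r}")


@dataclass
class BackoffPolicy:
    """Backoff configuration for the robustified optimal control problem.

    Either ``alpha`` is given directly or derived from ``confidence`` via
    ``method``.  ``objective_form`` selects the penalty added to robustified
    objectives: ``"sqrt_variance"`` (alpha * std) or ``"variance"``
    (alpha * Var).  One alpha is applied to every chance constraint and every
    robustified objective, matching the common practice of a single backoff
    level per solve; per-quantity policies can be expressed by assembling
    separate problems.
    """

    alpha: float | None = None
    confidence: float | None = None
    method: str = "normal_quantile"
    objective_form: str = "sqrt_variance"

    def __post_init__(self) -> None:
        if self.alpha is None:
            if self.confidence is None:
                raise ValueError("give either alpha or confidence")
            self.alpha = backoff_from_confidence(self.confidence, self.method)
        if self.alpha < 0:
            raise ValueError("backoff parameter must be non-negative")
        if self.objective_form not in ("sqrt_variance", "variance"):
            raise ValueError(f"unknown objective penalty form {self.objective_form!r}")
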