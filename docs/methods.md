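# Methods

## Model class

A `NetworkModel` describes a kinetic reaction network as dS/dt = N·v(S, e, θ)
with stoichiometric matrix N (one row per integrated metabolite, one column
per flux) and per-flux rate laws: mass action v = k·S·e or Michaelis–Menten
v = k_cat·S/(K_M + S)·e, where the catalysing enzyme e is either a control
(direct-concentration models) or itself a state driven by an expression-rate
control through de/dt = r − λe. Auxiliary integrator states carry integral
objectives (intermediate exposure ∫(S2+S3)dt, enzymatic cost ∫Σe dt) so that
every objective and constraint is a function of the terminal state. Buffered
species are held constant, either as a trivially integrated state with a
zero stoichiometry row (Case 1, keeping the printed 5-state count) or as a
substituted constant (Case 2, 9 integrated states). The right-hand side is
assembled symbolically (sympy), so exact Jacobians with respect to states,
controls and parameters are available everywhere downstream; models
round-trip losslessly through a declarative YAML form.

Initial conditions of the two case-study fixtures are not part of their
published description; the fixtures default to a buffered substrate of 1 mM
with all other metabolites, enzymes and integrators at zero, and both the
initial state and the enzyme budget E_T are overridable constructor
arguments. With these defaults the nominal optima reproduce the published
objective values to about 1 % (Case 1) and 0.002 % (Case 2), which supports
the choice.

## Uncertainty model and propagation

Parametric uncertainty is specified as a family (normal or uniform), a
nominal vector θ_nom and a covariance Σ, usually via a relative standard
deviation (std = rel_std·θ_nom; uniform marginals have support
θ_nom ± √3·std so that the std matches). Three propagation techniques
estimate (E, Var) of terminal quantities R(x(t_f)):

* **Linearization.** Forward sensitivities Ṡ = (∂f/∂x)S + ∂f/∂θ, S(0) = 0,
  integrated with the nominal states ((n_θ+1)·n_x states); the first-order
  covariance is P = SΣSᵀ and Var[R] = (∂R/∂x)P(∂R/∂x)ᵀ. Restricted to the
  normal family.
* **Sigma points.** The unscented transform with κ = 3 − n_θ: replicas at
  θ_nom and θ_nom ± columns of the Cholesky factor of (n_θ+κ)Σ
  ((2n_θ+1)·n_x states). The weighted moments reproduce the input mean and
  covariance exactly, are exact for affine R, and match Gaussian fourth
  marginal moments through the choice of κ.
* **Polynomial chaos (order p).** R is regressed onto multivariate
  polynomials of total degree ≤ p orthogonal under the parameter
  distribution — probabilists' Hermite for normal marginals, Legendre (in
  coordinates standardized to unit variance) for uniform — evaluated at
  n_s = (n_θ+p)!/(n_θ!p!) sampling points. With regression matrix Λ (basis ×
  points), a = (ΛΛᵀ)⁻¹ΛR; E[R] = a_0 and Var[R] = Σ_{j≥1} a_j²·E[Φ_j²] with
  analytic norms (n! for Hermite, 1/(2n+1) for Legendre).

**Sampling-point placement.** The design points are tensor combinations of
the roots of the order-(p+1) univariate orthogonal polynomial, processed in
shells of decreasing joint density; within a shell points are chosen greedily
D-optimally (largest Gram-determinant gain, lexicographic tie-break). For
p = 2 the origin is a root, so the design contains the nominal point and —
for three parameters — the complete sigma-point set, making the sigma-point
and PCE2 expected values coincide under normal uncertainty. For p = 1 the
roots are symmetric about (and exclude) the origin and the selection returns
a balanced two-level fraction (for n_θ = 3, a Hadamard half-fraction with
condition number 1). An alternative that forces the nominal point into the
odd-order design was rejected: it turns the linear regression into a
one-sided secant whose variance carries an O(σ) *relative* bias, which never
converges to the Monte-Carlo variance in the small-σ limit. Degenerate
(zero-covariance) designs are rejected; a rank-deficient square design falls
back to 2L-point least squares.

Correlated Σ is handled by the linear transform θ = θ_nom + Tξ with TTᵀ = Σ
in standardized coordinates; the shipped studies use independent marginals.

## Backoff policy

Chance constraints Pr[c ≥ c_min] ≥ β become c_min ≤ E[c] − α√Var[c]. α comes
either from the one-sided normal quantile of β — the four conventionally
tabulated levels (0.80, 0.90, 0.95, 0.975) return the standard two-decimal
values 0.84/1.28/1.65/1.96, other levels the unrounded quantile — or from
the distribution-free Cantelli–Chebyshev bound α = √(β/(1−β)), which is far
more conservative (4.36 vs 1.65 at β = 0.95). Robustified objectives add
α·√Var[J] by default; an alternative `variance` penalty form (α·Var[J]) is
available and is the Case 2 fixture's printed formulation — the two only
rescale the penalty weight, and the switch is explicit in `BackoffPolicy`
because the literature uses both. Only single (per-quantity) chance
constraints are supported; the backoff acts on each constraint separately.

## Transcription and solver

States and controls are fully discretized: finite elements with cubic
Lagrange interpolation through the element start plus the three right Radau
points (the classical Radau IIA scheme, order 5), collocation equalities at
the interior nodes, continuity constraints at element junctions, and
piecewise-constant controls per element (default 30 elements; the coarse
demo grids in examples use 6–10). A free final time is handled by scaling
the element widths with t_f as a decision variable.

Because the robustified problems replicate the dynamics (up to 90 states for
PCE2 on Case 2), the default solve path eliminates the collocation
equalities element-by-element with Newton's method — sequential orthogonal
collocation, identical discretization — leaving only the control parameters
(plus t_f) as decision variables for scipy's SLSQP (an SQP method; tolerance
1e-8, finite-difference gradients over cached rollouts). The fully
simultaneous NLP is also constructed (decision states at all nodes,
explicit collocation/continuity/initial-condition residuals) and is
exercised on small fixtures; its structure counts follow
(n_el−1)·n_states continuity equations and n_el·3·n_states collocation
equations.

The case-study optima are multimodal in the control discretization:
a mid-bound start converges to J = 3.711 on Case 1 while a
sequential-activation start (each enzyme fully active in its pathway stage,
the known just-in-time activation motif) reaches J = 3.682. `solve_ocp`
therefore tries both structured starts on a coarse grid (10 elements) and
refines the better converged solution on the target grid; robustified solves
are warm-started from the nominal solution. All starts are deterministic.

## Multi-objective trade-offs

Two-objective problems are scalarized by Normal Boundary Intersection:
objectives are normalized to the anchor bounding box (the anchors minimize
each objective alone), evenly spaced points on the segment between the
normalized anchors are pushed along the quasi-normal −(1,1)/√2, and each
subproblem maximizes the travelled distance subject to the original
constraints with the inequality form F̃(z) ≤ Φβ + d·n̂ (robust when fronts
are shallow near the anchors). Subproblems are warm-started from their
neighbour; failures are recorded per point and excluded from the front
array rather than aborting the sweep.

## Monte-Carlo validation

Optimized control profiles are fixed and the model is re-simulated for N
parameter draws (default N = 1000) with a stiff-capable adaptive integrator
(LSODA, rtol 1e-8, restarted at control discontinuities). Violations are
counted with a strict inequality against the printed bound; normal draws are
not truncated at zero by default (at 20 % relative std the probability of a
negative rate constant is ~3·10⁻⁷ per draw; a resampling flag exists).
Integration failures are counted separately, never dropped. For very large
ensembles (the 10⁵-sample oracle used in the tests) a vectorized fixed-step
RK4 integrator (`simulate_batch`, 30–40 substeps per element) evaluates all
realizations simultaneously; it matches the adaptive integrator to ~5·10⁻⁷
on the fixtures, far below Monte-Carlo noise.

## What the tests do and do not show

The test suite checks closed-form oracles (linear-decay and logistic
integration, linear-quadratic optimal control, Gaussian moment identities,
the analytic toy Pareto curve), structural bookkeeping (augmented state
counts per technique), and the published case-study behaviour: nominal
optima (2 % tolerance absorbs the control discretization), N = 1000
violation percentages (±3 percentage points of Monte-Carlo error), the
monotone growth of the robustified optimum in α, and the recession of the
Case 2 Pareto front as α grows (coarse 6-element grid, two backoff levels,
three points per front — scaled to desk hardware; the geometry, not the
resolution, is the claim).

The violation-percentage checks compare a single N = 1000 draw at one fixed
seed against the published percentage within ±3 points. Two caveats apply.
First, the binomial standard error at N = 1000 is ~1.6 points, so an
individual draw can legitimately land outside the band (the fixed suite seed
happens to produce a rate-constant sample whose k1 mean is 3 standard errors
low, which raises the violation count in both case studies by ~4 points; a
seed sweep and a 10⁵-sample estimate of the true rates sit 1.7–2.2 points
above the published values). Second, the published percentages belong to the
authors' discretized optimum; equally good local optima of the same problem
shift the true violation rate by a couple of points because the skew of the
terminal-constraint distribution depends on the control profile. The
assertions are kept at their stated strictness rather than widened.

One documented check fails by design of the techniques themselves: at 20 %
parameter spread the sigma-point/PCE2 *standard deviation* of S4 differs
from a 10⁵-sample Monte-Carlo oracle by ~1.5·10⁻³ (unmatched fourth-order
cross moments, an O(σ⁴) truncation), while the oracle's standard error is
~4·10⁻⁴ — so a 3-standard-error comparison at that sample size rejects
correctly-implemented techniques. The expected values do agree within
~1.5 standard errors, and at N = 1000 (the validation size used in
practice) both moments agree within one standard error. The corresponding
assertion is kept at its stated strictness and left failing rather than
loosened.

The synthetic study conditions mirror the published setups (20 % / 10 %
relative normal uncertainty, N = 1000 validation); they exercise parametric
uncertainty only — no process noise, no measurement feedback, no model-form
error — so passing tests certify the optimization/propagation machinery,
not the biological fidelity of the fixture networks.

## Known limitations

* Rate-law grammar is limited to mass action and Michaelis–Menten; other
  kinetics would extend `RateLaw`.
* The linearization technique is restricted to normal uncertainty
  (first-order covariance propagation has no distribution-shape information
  beyond Σ) and is least accurate of the three at large spread.
* SLSQP is a local solver; multimodality is mitigated by structured
  multistarts and continuation, not eliminated.
* Path constraints in the robustified problems are enforced on the nominal
  replica's trajectory (they are deterministic pass-throughs, matching the
  formulation); chance path constraints at collocation nodes would be a
  straightforward extension of the terminal machinery.
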