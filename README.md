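# robokin

Robust dynamic optimization of kinetic biological networks under parametric
uncertainty.

Metabolic engineering and systems-biology studies often ask for time-varying
enzyme schedules that steer a kinetic network model — for example, activate a
pathway so that a product concentration reaches a quality floor at the final
time while keeping toxic intermediates or the protein-synthesis burden low.
The kinetic parameters of such models (rate constants, Michaelis constants,
degradation rates) are never known exactly, and a schedule optimized at the
nominal parameters typically sits *on* its constraints, so roughly half of
all parameter perturbations violate them. `robokin` turns such chance
constraints

&nbsp;&nbsp;&nbsp;&nbsp;Pr[ c(x(t_f)) ≥ c_min ] ≥ β

into deterministic *backed-off* constraints

&nbsp;&nbsp;&nbsp;&nbsp;c_min ≤ E[c(x(t_f))] − α·√(Var[c(x(t_f))]),

where the backoff parameter α is the one-sided normal quantile of β (0.84 /
1.28 / 1.65 / 1.96 for confidence 0.80 / 0.90 / 0.95 / 0.975) or the
distribution-free Cantelli–Chebyshev bound √(β/(1−β)) (4.36 at β = 0.95).
Objectives are robustified the same way, E[J] + α·g(Var[J]).

The moments E and Var are propagated through the nonlinear ODE model by one
of three techniques, each embedded as augmented dynamics inside the
optimization problem:

| technique       | idea                                            | dynamic states |
|-----------------|-------------------------------------------------|----------------|
| linearization   | forward sensitivities Ṡ = (∂f/∂x)S + ∂f/∂θ, P = SΣSᵀ | (n_θ+1)·n_x |
| sigma points    | unscented transform, 2n_θ+1 replicas at θ_nom ± √((n_θ+κ)Σ), κ = 3−n_θ | (2n_θ+1)·n_x |
| PCE (order p)   | regression onto distribution-matched orthogonal polynomials (Hermite/Legendre) at (n_θ+p)!/(n_θ!p!) sampling points | (n_θ+p)!/(n_θ!p!)·n_x |

The optimal control problems are transcribed by orthogonal collocation on
finite elements (cubic Lagrange interpolation through the right Radau
points, piecewise-constant controls) and solved with an SQP solver;
two-objective trade-offs are traced by Normal Boundary Intersection; and
every optimized schedule can be validated by Monte-Carlo simulation over the
parameter distribution.

Two classic case-study networks ship as fixtures:

* **case1** — a three-step linear pathway (mass-action kinetics, buffered
  substrate) whose intermediate accumulation ∫(S2+S3)dt is minimized subject
  to S4(10 s) ≥ 0.90 mM and a shared enzyme budget Σe ≤ 1 mM.
* **case2** — a glycolysis-inspired branched network (Michaelis–Menten
  kinetics, enzyme balances de/dt = r − λe driven by expression rates) with
  the bi-objective trade-off between time-to-target (S5 ≥ 0.675 mM) and
  enzymatic cost ∫Σe dt.

## Worked example

```python
from robokin import (BackoffPolicy, UncertaintySpec, case1_model,
                     sample_parameters, validate_controls)
from robokin.collocation import solve_ocp
from robokin.robust import assemble_robust_ocp, solve_robust

model = case1_model()
spec = UncertaintySpec("normal", model.theta_nominal, rel_std=0.2)

nominal = solve_ocp(assemble_robust_ocp(model, "nominal", spec,
                                        BackoffPolicy(alpha=0.0)),
                    n_elements=30, refine_from=10)
robust, prop = solve_robust(model, "linearization", spec,
                            BackoffPolicy(alpha=1.96), n_elements=30,
                            warm_start=nominal)
samples = sample_parameters(spec, 1000, seed=0)
for name, sol in [("nominal", nominal), ("robust", robust)]:
    rep = validate_controls(model, sol.controls, samples)
    print(f"{name}: J = {sol.objective:.3f}, "
          f"violations = {rep.violation_percentage:.1f} %")
print(f"E[S4] = {prop.mean('S4'):.3f}, std[S4] = {prop.std('S4'):.3f}")
```

prints

```
nominal: J = 3.682, violations = 56.8 %
robust: J = 6.518, violations = 3.6 %
E[S4] = 1.502, std[S4] = 0.307
```

Read: the nominal schedule accumulates only 3.68 mM·s of intermediates but
leaves the product floor active, so about half of the 20 %-perturbed
parameter draws miss it (the exact percentage moves a couple of points with
the seed); the backed-off schedule over-produces (E[S4] ≈ 1.50 mM, with
E − 1.96·std pinned at 0.90 mM) and cuts violations to ~3–4 % at the price
of an ~80 % higher intermediate burden.

The `examples/` directory holds one short narrative script per capability
(simulation, uncertainty propagation, robustified solves, Monte-Carlo
validation, Pareto fronts), and the same workflow is scriptable from the
shell:

```bash
robokin robust --model case1 --technique sigma_points --alpha 1.65 \
        --family normal --rel-std 0.20 --elements 30 --out out/
```

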