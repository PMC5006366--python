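"""Time-versus-cost trade-off for the glycolysis network by NBI (coarse demo).

The Case 2 network trades the time needed to reach 0.675 mM of product
against the enzymatic cost (the time integral of total enzyme).  This demo
traces a small robustified Pareto front (linearization technique, backoff
0.84) on a coarse grid; expect a few minutes of runtime.
"""

from robokin import BackoffPolicy, UncertaintySpec, case2_model
from robokin.pareto import OCPBiobjective, nbi_front
from robokin.robust import assemble_robust_ocp

model = case2_model(t_f_free=True)
spec = UncertaintySpec("normal", model.theta_nominal, rel_std=0.1)
ocp = assemble_robust_ocp(model, "linearization", spec, BackoffPolicy(alpha=0.84),
                          objective="enzymatic_cost", t_f_free=True)
front = nbi_front(OCPBiobjective(ocp, n_elements=6), n_points=3)

print("beta_NBI   t_f [s]   robust cost [mM s]")
for p in front.points:
    flag = "" if p.success else "  (subproblem failed)"
    print(f"  {p.beta:4.2f}   {p.objectives[0]:7.3f}   {p.objectives[1]:10.3f}{flag}")
print("Left end: fastest schedule that still clears the backed-off product")
print("floor; right end: cheapest schedule. Larger backoffs push the whole")
print("front up and to the right (the price of robustness).")
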