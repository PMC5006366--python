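"""Propagate 20 % rate-constant uncertainty to the Case 1 product concentration.

Compares the three propagation techniques (forward-sensitivity linearization,
sigma points, polynomial chaos of order 1 and 2) at a fixed enzyme schedule:
each returns the expected terminal product concentration E[S4(10 s)] and its
standard deviation, together with the size of the augmented ODE system the
technique integrates.
"""

from robokin import ControlProfile, UncertaintySpec, case1_model, propagate

model = case1_model()
spec = UncertaintySpec("normal", model.theta_nominal, rel_std=0.2)
controls = ControlProfile.constant([0.5, 0.25, 0.25], t_f=10.0, n_elements=1)

print(f"{'technique':15s} {'E[S4]':>8s} {'std[S4]':>8s} {'states':>7s}")
for technique in ("linearization", "sigma_points", "pce1", "pce2"):
    res = propagate(model, controls, spec, technique, quantities=["S4"])
    print(f"{technique:15s} {res.mean('S4'):8.4f} {res.std('S4'):8.4f} "
          f"{res.n_states:7d}")
print("All techniques agree closely here; the augmented state count is the")
print("price each pays inside the optimizer (5 states in the nominal model).")
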