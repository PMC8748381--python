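"""Search gradient programs for the best separation of a fitted mixture.

With per-component LSS parameters in hand, any candidate elution program can
be simulated in milliseconds, so the program space (initial/final modifier
fraction and gradient time here) is searched by differential evolution with
Pareto bookkeeping: maximize the critical resolution, minimize the analysis
time, and keep every non-dominated trade-off.
"""

from chromforge.optimize import SearchSpace, optimize_separation
from chromforge.synthgen import example_six_component_spec

spec = example_six_component_spec(seed=0)
components = {c.name: c.lss for c in spec.components}

space = SearchSpace(
    (
        ("phi_initial", 0.02, 0.30),
        ("phi_final", 0.30, 1.00),
        ("t_G", 3.0, 20.0),
    )
)
front = optimize_separation(components, space, mode="pareto", seed=0, pop=40, gens=60)

print(f"Pareto front: {len(front.members)} non-dominated programs "
      f"({front.evaluations} simulations)")
print("\n  phi_0   phi_f    t_G    critical Rs   runtime (min)")
for m in sorted(front.members, key=lambda m: m.objectives[1])[::  max(1, len(front.members) // 10)]:
    print(f"  {m.vector[0]:.3f}   {m.vector[1]:.3f}  {m.vector[2]:5.1f}      "
          f"{m.objectives[0]:6.2f}        {m.objectives[1]:6.2f}")

best = front.best_by_Rs()
print(f"\nbest-resolution program: {best.program.nodes}  "
      f"critical Rs {best.objectives[0]:.2f} in {best.objectives[1]:.1f} min")
# Rs >= 1.5 means baseline separation; the front shows how much analysis
# time each extra increment of resolution costs.
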