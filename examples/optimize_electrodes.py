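"""GA search for the electrode geometry maximizing elongation, plus shape ranking.

A real-coded genetic algorithm (20 individuals, 10 generations) searches
electrode width [5, 50] um and gap [20, 70] um for the rectangular-
rectangular scenario, minimizing 1/L*.  The six tip-shape pairings are
then ranked at the small-gap/large-width corner.
"""

from depstretch import GAConfig, Resolution, SIX_SCENARIOS, ga_optimize, rank_scenarios
from depstretch.electrode_optimizer import default_base_config

base = default_base_config(Resolution(nodes_per_radius=8, stations=120))

result = ga_optimize(("rectangular", "rectangular"), GAConfig(seed=1), base)
print(f"best geometry: w = {result.best_w_um:.1f} um, d = {result.best_d_um:.1f} um")
print(f"best elongation L* = {result.best_lstar:.4f}")
print(f"objective change after generation 9: {100 * result.convergence_after(9):.4f}%")
print(f"unique simulations: {result.n_evaluations}")

print("\nshape ranking at (w=50, d=20) um:")
ranking = rank_scenarios(SIX_SCENARIOS, base_config=base)
print(ranking[["rank", "left", "right", "Lstar"]].to_string(index=False))
# The gap dominates: d = 20 um maximizes the stretch for every shape,
# and flat (rectangular) facing edges beat protruding tips.
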