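"""Map climate anomaly with the environmental similarity surface (MESS).

The reference sample is the environmental values at the occurrence cells of
the current scene; the query is a future scenario.  Negative similarity
marks extrapolation beyond the reference range (a climate anomaly); the
most-dissimilar variable (MoD) names the axis responsible.
"""

import numpy as np

import herbniche as hn
from herbniche.grid import cell_areas

SEED = 4

cfg = hn.default_scene(seed=SEED)
stack = hn.synth_climate_stack(cfg)
truth = hn.synth_truth_suitability(stack, cfg.truth)
occ = hn.sample_presences(truth, cfg.n_presences, seed=SEED)

reference = stack.values_at(occ.lons, occ.lats)
future = hn.scenario_stack(stack, temp_delta=3.0, precip_factor=0.97)
areas = cell_areas(stack.spec)

now = hn.mess_surface(reference, stack)
fut = hn.mess_surface(reference, future)
mean_now, neg_now = hn.mess_summary(now, areas)
mean_fut, neg_fut = hn.mess_summary(fut, areas)
print("area-weighted mean similarity (100 = reference climate, "
      "negative = novel):")
print(f"  current landscape: {mean_now:7.2f}  "
      f"({100 * neg_now:.1f}% of area novel)")
print(f"  future scenario:   {mean_fut:7.2f}  "
      f"({100 * neg_fut:.1f}% of area novel)")
print("the reference is the occupied niche, so much of the landscape is "
      "novel even today; the scenario lowers similarity further")

mod = fut.mod.valid_values().astype(int)
counts = np.bincount(mod, minlength=len(fut.var_names))
top = np.argsort(counts)[::-1][:3]
print("most-dissimilar variable under the scenario, share of cells:")
for k in top:
    print(f"  {fut.var_names[k]}: {100 * counts[k] / mod.size:.1f}%")
print("the MoD map names the climate axis that pushes each cell furthest "
      "outside the occupied range")
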