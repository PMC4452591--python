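"""Optimize the minimum light intensity I_min by ROC distance.

Predicted and observed 1° presence are compared per candidate I_min;
raising I_min shrinks the predicted habitat, trading false positives for
false negatives.  The sweep runs 50..500 by 50, refines by 10 around the
coarse optimum, and picks the operating point nearest the perfect-
classification corner (FPR, TPR) = (0, 1).
"""

import reefhab as rh

world = rh.generate_world(rh.WorldConfig(seed=11))
obs = rh.rasterize_reefs(world.reefs, world.env.fine_spec, world.env.coarse_spec)
observed = rh.presence_matrix(obs.coarse_fraction)
sweep = rh.sweep_imin(world.env, world.truth.limits, observed)

print(f"{'I_min':>6} {'FP':>4} {'FN':>4} {'TPR':>7} {'FPR':>7} {'distance':>9} {'area 10^3 km^2':>15}")
for p in sweep.points:
    mark = "  <- best" if p.i_min == sweep.best_i_min else ""
    print(f"{p.i_min:6.0f} {p.counts.FP:4d} {p.counts.FN:4d} {p.TPR:7.3f} "
          f"{p.FPR:7.3f} {p.distance:9.4f} {p.area_km2 / 1e3:15.1f}{mark}")
print()
print(f"best I_min = {sweep.best_i_min:.0f} umol photons m^-2 s^-1 "
      f"(planted: {world.truth.i_min:.0f})")
print("FP fall and FN rise monotonically with I_min; the jump in FN just above")
print("the optimum comes from reef cells whose shelves sit near Z_max.")
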