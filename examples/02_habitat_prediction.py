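"""Predict potential reef habitat on a synthetic world.

A 30" cell is suitable when its 1° environment passes the tolerance
envelope and its depth lies within the light-limited maximum reef-growth
depth Z_max = ln(PAR/I_min)/K490 of its 5' cell.  The result is reported
as a 1° habitat-percentage map and a total spherical area.
"""

import numpy as np

import reefhab as rh

world = rh.generate_world(rh.WorldConfig(seed=11))
result = rh.predict_habitat(world.env, rh.DEFAULT_LIMITS)

frac = result.coarse_fraction.values
print(f"domain: {world.env.coarse_spec.shape[0]} x {world.env.coarse_spec.shape[1]} cells at 1 degree")
print(f"suitable 30\" cells:        {int(result.fine_mask.values.sum())}")
print(f"1-degree cells with habitat: {(frac > 0).sum()} (fractions up to {frac.max():.2f})")
print(f"total potential habitat:    {result.total_area_km2 / 1e3:.1f} x 10^3 km^2")
print(f"envelope rejections per variable (1-degree cells): {result.rejection_counts}")
print()
print("Z_max worked example: PAR=1800, K490=0.05 m^-1, I_min=450 ->",
      f"{rh.max_reef_depth(1800.0, 0.05, 450.0):.3f} m")
print("(reefs can grow where the sea floor is shallower than this)")
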