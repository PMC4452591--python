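"""Solve the surface seawater CO2 system for the aragonite saturation state.

Given total alkalinity and dissolved inorganic carbon at surface
temperature and salinity, the solver returns total-scale pH, carbonate
ion, and the saturation states of both CaCO3 polymorphs.  Ω_ara > 1 means
seawater is supersaturated with respect to aragonite, the mineral corals
precipitate; reef growth is associated with comfortably supersaturated
water (the default envelope uses Ω_ara ≥ 2.82).
"""

import reefhab as rh

state = rh.solve_carbonate_system(rh.CarbonateInput(TA=2300.0, DIC=2000.0, T=25.0, S=35.0))
print("TA=2300, DIC=2000 umol/kg at 25 degC, S=35:")
print(f"  pH (total scale)   = {state.pH_total:.4f}")
print(f"  [CO3--]            = {state.CO3:.1f} umol/kg")
print(f"  omega_aragonite    = {state.omega_ara:.3f}")
print(f"  omega_calcite      = {state.omega_cal:.3f}")
print()
print("Omega_ara rises with alkalinity at fixed DIC (CO2 uptake reverses this):")
for ta in (2100.0, 2300.0, 2500.0):
    s = rh.solve_carbonate_system(rh.CarbonateInput(ta, 2000.0, 25.0, 35.0))
    print(f"  TA = {ta:6.0f} umol/kg  ->  omega_ara = {s.omega_ara:.3f}")
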