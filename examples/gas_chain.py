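"""Headspace TCD reading -> CO2-carbon mass, step by step.

Converts one gas-chromatograph reading (1000 ppm CO2 in the Exetainer gas
mixture) into the carbon mass of the bottle headspace, showing every link
of the chain: ideal-gas moles, He-dilution concentration factor, molar-mass
conversion, and the per-litre concentration.
"""

from lakesip import gas

constants = gas.GasConstants()  # 12 ml tube, 5 ml sample, V_m = 22.414 L/mol

# the bottle sat at 2 degC (winter) but the GC lab is at 21 degC:
v_std = gas.standardize_volume(constants.v_sample, 275.15, constants.t_measurement_k)
print(f"Charles's-law standardized sample volume: {v_std * 1000:.4f} ml")

cc = gas.headspace_carbon(1000.0, constants, v_sample=v_std)
print(f"n(gas)  = {cc.n_gas:.3e} mol   (tube + sample over molar volume)")
print(f"CF      = {cc.cf:.3f}          (undoes the He dilution)")
print(f"n(CO2)  = {cc.n_co2:.3e} mol")
print(f"m(C)    = {cc.m_c_g * 1e6:.2f} ug C in the 5 ml sample")
print(f"c(C)    = {cc.c_c_mg_per_l:.3f} mg C per litre of headspace")

headspace_l = 0.240 - 0.150  # bottle minus water
mass = gas.bottle_pool_mass(cc.c_c_mg_per_l, headspace_l)
print(f"headspace CO2-carbon pool: {mass:.3f} mg C")
print("-> this mass, with the pool's delta13C, feeds the tracer mass balance")
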