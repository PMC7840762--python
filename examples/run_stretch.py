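"""Simulate one dielectrophoretic stretch and print the elongation.

An 8 um cell (relative permittivity 120) sits centred between two
rectangular electrodes (width 30 um, gap 45 um) in an aqueous medium
(permittivity 80) driven at 10 V peak-to-peak.  The Maxwell-stress
traction on the cell boundary is computed from the solved field and fed
into the linear-elastic disk model (E = 0.1 kPa).
"""

from depstretch import ElectrodePair, Resolution, StretchConfig, simulate_stretch

config = StretchConfig(
    pair=ElectrodePair(width_um=30.0, gap_um=45.0),
    cell_radius_um=4.0,
    eps_m=80.0,
    eps_c=120.0,
    voltage=10.0,
    resolution=Resolution(nodes_per_radius=20),
)

result = simulate_stretch(config)
print(f"tip displacement u_tip = {result.u_tip_um:.4f} um")
print(f"deformed semi-axis  L  = {result.deformed_semi_axis_um:.4f} um")
print(f"normalized elongation L* = (L-R)/R = {result.lstar:.4f}")
print(f"peak surface traction   = {result.log['max_traction_pa']:.2f} N/m^2")
# L* is the fraction of the undeformed radius the cell tip moves outward:
# ~0.04 here means a 4% stretch along the electrode axis at 10 V.
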