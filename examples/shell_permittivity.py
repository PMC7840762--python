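"""Single-shell cell dielectrics and the Clausius-Mossotti spectrum.

A membrane-bounded cell (thin, poorly conducting membrane around a
conductive cytoplasm) is reduced to an effective homogeneous sphere;
the real part of the Clausius-Mossotti factor against the suspending
medium sets the sign of the dielectrophoretic response per frequency.
"""

import numpy as np

from depstretch import (
    DielectricMaterial,
    ShellCell,
    clausius_mossotti,
    complex_permittivity,
    shell_effective_permittivity,
)

cell = ShellCell(
    radius_um=4.0,
    membrane_thickness_um=0.008,
    membrane=DielectricMaterial(eps_r=6.0, sigma=1e-7),
    cytoplasm=DielectricMaterial(eps_r=60.0, sigma=0.5),
)
medium = DielectricMaterial(eps_r=80.0, sigma=0.01)  # low-conductivity DEP buffer

print(f"{'f [Hz]':>10} {'Re eps_cell*':>12} {'Re K':>8}")
for f in (1e4, 1e5, 1e6, 3e6, 1e7, 1e8):
    omega = 2 * np.pi * f
    eps_c = shell_effective_permittivity(cell, omega, relative=True)
    k = clausius_mossotti(
        shell_effective_permittivity(cell, omega),
        complex_permittivity(medium, omega),
    )
    print(f"{f:10.0e} {eps_c.real:12.1f} {k.real:8.3f}")
# Re K > 0 (positive DEP, cell pulled to field maxima and stretched)
# appears once the membrane is capacitively shorted in the MHz range.
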