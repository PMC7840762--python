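# Methods

## Physical model

The chip is modelled in the electrode plane (2-D top view, unit
out-of-plane depth): two facing electrode fingers of width `w` at
potentials ±V/2 across a gap `d`, and the cell as a circular disk of
radius `R` centred in the gap. The quasi-electrostatic potential solves
∇·(ε∇Φ) = 0 with relative permittivity ε_c inside the disk and ε_m
outside, Dirichlet values on the electrodes and insulating (homogeneous
Neumann) outer boundaries. Only the ε ratio enters Φ.

The electrical load on the cell is the jump of the Maxwell stress
tensor σ_ij = ε(E_iE_j − ½δ_ij|E|²) across the interface, evaluated
from one-sided field samples (traction formula in the README). By
default the traction is the peak-of-cycle value built from field
amplitudes and real permittivities at the drive frequency; an option
applies the ½ AC time-average factor. Either convention is absorbed
into the lumped parameter S, so the factorized law is unaffected. The
printed interface formula multiplies permittivities by real field
vectors; using complex permittivities there would not produce a real
traction, so the real parts at the drive frequency are used — the
frequency dependence enters through the single-shell effective cell
permittivity when one is supplied.

The cell responds as an isotropic linear-elastic disk (one-way
coupling: the field is not re-solved on the deformed shape). Defaults:
Young's modulus 100 Pa (0.1 kPa, the optimization-study value), Poisson
ratio ν = 0.49 (nearly incompressible cytoplasm), plane stress. The
readout is the tip displacement along the stretch axis, u_tip = mean of
the two tip displacements projected outward; L = R + u_tip and
L* = u_tip/R. Since field ∝ V, traction ∝ V², and elasticity is
linear, L* is exactly quadratic in V and exactly proportional to 1/E;
the tests assert both to 1e−10.

Cells wider than the gap rest on top of the (passivated) electrodes in
the real device. The geometry builder models this with
`on_overlap="allow"`: the electrode Dirichlet region excludes the cell
disk. The strict default rejects overlapping placements.

## Numerics

Discretization is a vertex-centred finite-volume scheme on a graded
tensor-product grid: spacing h = R/`nodes_per_radius` around the cell
(default 20; 8 for coarse/GA work), an intermediate spacing over the
gap and electrode tips, local h-bands around electrode edge corners
(their field singularities otherwise dominate the discretization
error), and geometric growth (ratio 1.3) to the far field. The domain
is 4(w+d) per side; a domain-doubling test bounds the truncation
effect on the interface field below 1%. Face permittivities are exact
sub-segment harmonic averages along each face through the circular
interface, which removes the O(h) staircase noise of node-sampled ε.
The sparse system is solved directly (SuperLU).

Interface fields are sampled at angular stations (default 360) from
the potential, not from differentiated nodal fields: per station a
quadratic is fitted through Φ at three one-sided radial offsets
(starting 1.5 fine cells from the interface, outside the one-cell
smeared zone of the interface coefficients); its derivative gives the
normal field on each side and its value the interface potential, whose
spectral θ-derivative (low-passed at harmonic 32 to stop spectral
amplification of staircase noise) gives the tangential field. The
scheme is validated against the classical dielectric cylinder in a
uniform field: interior field within 2% (typically <1%), and the
station-wise traction against an independent symbolic evaluation.

The disk elasticity uses the Michell solution: the traction is
Fourier-decomposed at the stations; per harmonic n ≥ 2 the two regular
Airy terms r^n, r^{n+2} are solved from a 2×2 system; n = 0 is the
Lamé mode, n = 1 (rigid content) must vanish after
`equilibrate_traction` removes net force and torque. The displacement
formulas are verified in the test suite by a sympy oracle (equilibrium
and boundary-condition residuals simplify to zero), which serves as
the independent second method for the solver.

Mesh independence: `mesh_independence` walks `nodes_per_radius` up by
1.5× until one refinement changes L* by less than a tolerance (default
1%); the reference chip settles within four refinements.

## The lumped law and its calibration

γ(R, d, w) is tabulated by running the simulator on a grid and
normalizing by the reference-point elongation — the table is exactly
independent of the (V, E) used to generate it. The shipped default
table (`data/gamma_default.csv`, regenerated by `depstretch
gamma-table`) covers R ∈ [3, 8] µm, d ∈ [20, 70] µm (log-spaced — γ
decays like a power of d, so log spacing keeps the trilinear
interpolation error under ~4%), w ∈ [10, 50] µm, with provenance in
its header. Queries outside the hull raise. Small-gap/large-R corners
of any table lie outside the small-strain regime and should be treated
as indicative only.

The contrast exponent α is fitted by scanning α over [0.5, 1.2] (step
0.01, then bounded refinement) and minimizing the worst-case
per-geometry relative spread (max−min)/mean of L*/Δε^α across contrast
levels, with Δε = |Re ε_m − Re ε_c| and the sign reported separately
(a fractional power needs a nonnegative base). Contrast levels for the
headline fit are cell permittivities {100, 120, 140, 160} against
medium 80 — a 0.5–2× bracket of the canonical 80/120 pair. Geometries
with d < 3R are excluded: a near-bridging cell is far outside the
small-strain regime and the factorized law's domain.

S is fitted by least squares through the origin of L* on V²γ
(S = Σxy/Σx², standard error from residuals), pooled per cell type by
default with per-cell fits alongside; D = S/Δε^α is reported when a
contrast is supplied.

### Known difference from a 3-D treatment

In this plane model the fitted exponent comes out at ≈1.05–1.1 with a
worst-case collapse deviation of ≈8–11%, rather than the sub-unity
exponent a 3-D spherical model yields. The reason is structural: the
tip displacement mixes an inflation mode proportional to the cylinder
contrast factor K₂ = Δε/(2ε_m + Δε) (log-slope < 1, saturating) with a
cos 2θ shape mode proportional to K₂² (log-slope ≈ 1.6–2); their
weight ratio is K₂ itself, pushing the consensus exponent above 1 for
any elastic constants. A sphere saturates more slowly
(K = Δε/(3ε_m + Δε)) and weights the modes differently. Users needing
the 3-D exponent should treat α as a calibration input rather than
taking the plane-model fit.

## Electrode optimization

Six tip-shape scenarios (unordered pairs of rectangular, triangular,
elliptical). Shape parameters not fixed by the geometry: triangular
apex half-angle 30°, elliptical protrusion axis ratio 0.5, both
configurable — only relative ranking is claimed. The GA is real-coded
over (w, d) with tournament selection (size 3), BLX-α crossover
(rate 0.9, α 0.5), Gaussian mutation (σ = 10% of range, rate 0.2),
clip-to-bounds, one elite, 20 individuals × 10 generations, the random
initial population counting as generation 1; objective 1/L* (failures
become large penalties), memoized per (w, d, scenario, resolution);
coarse solver resolution during the search with the winner worth
re-evaluating finer. The landscape is monotone in the gap (smaller d,
larger stretch) but in width it saturates: L* rises with w up to
w ≈ 15 µm at d = 20 µm and is then flat within ~1% (checked at three
resolutions), so repeated seeded runs agree on d = 20 while w lands
anywhere on the plateau. Rectangular–rectangular ranks first among the
six scenarios; protruding tips concentrate the field away from the
cell body and stretch it less.

## Synthetic measurement campaign

`synth_trajectories` emulates the experimental design: by default 3
cell types × 16 cells × 9 conditions (widths {10, 30, 50} µm × gaps
{20, 45, 70} µm at 8 V, 3 MHz), with planted per-type S values of
0.004/0.002/0.001 V⁻² ordered soft-to-stiff. Each trajectory is a
single-exponential rise (τ = 10 s, 60 s records — plateaus are reached
by ~40 s as in practice) to plateau L* = S_cell·V²·γ, with lognormal
cell-to-cell scatter of S (CV 5% by default), additive Gaussian
tracking noise (0.02 µm), and optional on/off cycles with a set
recovery fraction. Plateau detection uses a 10 s trailing window and a
2% slope tolerance; cycle summaries report per-cycle peaks, recovery
fraction per off interval, and the first-to-last peak drop. What
passing recovery tests show: the reduction+fit pipeline is unbiased
and tight (≈1% per-type error at 5% noise) under the model's own
kinetics and noise structure. What they do not show: robustness to
real-world tracking artefacts, drift, non-exponential viscoelastic
kinetics, or cell-size dispersion within a type — none of which the
generator emulates.

## Problem sizes and determinism

Default test and acceptance runs use coarse resolutions
(8–10 nodes per radius, 120–180 stations): the collapse fit simulates
84 configurations and the GA analysis five seeded runs of ≤200
evaluations each — a few tens of seconds in total; finer resolutions
change L* at the percent level and none of the reported ratios
qualitatively. All stochastic components (GA, synthetic data) are
seeded; simulations are deterministic for a fixed configuration.

## Limitations

2-D plane electrostatics and elasticity (no channel-height field
gradient, no out-of-plane attraction); small-strain linear elasticity
(a warning fires beyond |u|/R = 0.2, and near-bridging geometries
grossly violate it); one-way coupling; no Joule heating, electrode
polarization, AC electro-osmosis, or multi-shell (nucleated) cell
models; viability is reduced to trace summaries (peaks, recovery,
drop) with no biological interpretation.
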