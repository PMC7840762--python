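"""2-D electrostatics of a coplanar electrode pair with an embedded dielectric cell.

Top-view plane model (unit out-of-plane depth): two facing electrode
fingers held at +V/2 and -V/2 across a gap ``d``, with a circular cell of
radius ``R`` between them.  The potential solves the piecewise-dielectric
Laplace problem ``div(eps grad(phi)) = 0`` with ``eps = eps_c`` inside the
cell disk and ``eps_m`` outside, Dirichlet potentials on the electrodes
and homogeneous Neumann conditions on the outer box.

Discretization is a vertex-centred finite-volume scheme on a graded
tensor-product grid (fine around the cell, intermediate over the gap and
electrode tips, geometrically stretched towards the far field) with
harmonic-mean face permittivities across the cell interface.  Fields on
either side of the interface are sampled at fixed angular stations a
small offset away from the disk boundary, where the one-cell smearing of
the interface coefficient has decayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy import sparse
from scipy.interpolate import RegularGridInterpolator
from scipy.sparse.linalg import spsolve

Shape = Literal["rectangular", "triangular", "elliptical"]

_SHAPES: tuple[str, ...] = ("rectangular", "triangular", "elliptical")


class GeometryError(ValueError):
    """Invalid chip geometry (e.g. cell overlapping an electrode)."""


class SolverError(RuntimeError):
    """Linear solve failed or did not produce a finite potential."""


class RefinementError(RuntimeError):
    """Mesh-independence ladder failed to converge within the refinement cap."""


@dataclass(frozen=True)
class ElectrodePair:
    """Facing electrode fingers: width ``w`` (transverse), gap ``d`` (axial).

    Each finger spans the domain in its own half of the x axis and ends in
    a facing edge whose shape is rectangular (flat), triangular (tip with
    a given apex half-angle) or elliptical (semi-elliptical bulge with a
    given axis ratio).  The gap ``d`` is measured tip-to-tip along x.
    """

    width_um: float
    gap_um: float
    left_shape: Shape = "rectangular"
    right_shape: Shape = "rectangular"
    apex_half_angle_deg: float = 30.0
    ellipse_axis_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not self.width_um > 0:
            raise GeometryError("electrode width must be > 0")
        if not self.gap_um > 0:
            raise GeometryError("electrode gap must be > 0")
        for s in (self.left_shape, self.right_shape):
            if s not in _SHAPES:
                raise GeometryError(f"unknown electrode shape {s!r}")
        if not 0 < self.apex_half_angle_deg < 90:
            raise GeometryError("apex half-angle must be in (0, 90) degrees")
        if not 0 < self.ellipse_axis_ratio <= 2:
            raise GeometryError("ellipse axis ratio must be in (0, 2]")

    def protrusion_um(self, side: Literal["left", "right"]) -> float:
        """Axial extent of the shaped tip in front of the full-width finger."""
        shape = self.left_shape if side == "left" else self.right_shape
        if shape == "rectangular":
            return 0.0
        if shape == "triangular":
            return (self.width_um / 2.0) / np.tan(
                np.deg2rad(self.apex_half_angle_deg)
            )
        return self.ellipse_axis_ratio * self.width_um / 2.0


@dataclass(frozen=True)
class ChipGeometry:
    """Electrode pair + cell disk + rectangular simulation domain (all um).

    The domain is the box ``[-Lx/2, Lx/2] x [-Ly/2, Ly/2]``; the gap is
    centred on the origin and the cell disk sits at ``cell_center_um``.
    """

    pair: ElectrodePair
    cell_radius_um: float
    cell_center_um: tuple[float, float] = (0.0, 0.0)
    domain_um: tuple[float, float] = (0.0, 0.0)
    on_overlap: Literal["error", "allow"] = "error"

    def electrode_mask(
        self, side: Literal["left", "right"]
    ) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
        """Membership test (x, y in um) for one electrode region."""
        p = self.pair
        w2 = p.width_um / 2.0
        tip = p.gap_um / 2.0  # |x| of the tip plane
        prot = p.protrusion_um(side)
        shape = p.left_shape if side == "left" else p.right_shape
        sgn = -1.0 if side == "left" else 1.0

        def mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
            # axial distance behind the tip, measured away from the gap
            u = sgn * x - tip
            body = (u >= prot) & (np.abs(y) <= w2)
            if shape == "rectangular":
                return body | ((u >= 0) & (u < prot) & (np.abs(y) <= w2))
            if shape == "triangular":
                half = u * np.tan(np.deg2rad(p.apex_half_angle_deg))
                return body | ((u >= 0) & (u < prot) & (np.abs(y) <= half))
            # elliptical: semi-ellipse with semi-axes (prot, w2), apex at u=0
            half = w2 * np.sqrt(np.clip(1.0 - ((prot - u) / prot) ** 2, 0.0, 1.0))
            return body | ((u >= 0) & (u < prot) & (np.abs(y) <= half))

        return mask

    def cell_overlaps_electrodes(self) -> bool:
        cx, cy = self.cell_center_um
        th = np.linspace(0.0, 2.0 * np.pi, 1441)
        x = cx + self.cell_radius_um * np.cos(th)
        y = cy + self.cell_radius_um * np.sin(th)
        for side in ("left", "right"):
            m = self.electrode_mask(side)
            if m(x, y).any() or m(np.array([cx]), np.array([cy]))[0]:
                return True
        return False


def build_geometry(
    pair: ElectrodePair,
    cell_radius_um: float,
    *,
    cell_center_um: tuple[float, float] = (0.0, 0.0),
    domain_factor: float = 4.0,
    domain_um: tuple[float, float] | None = None,
    on_overlap: Literal["error", "allow"] = "error",
) -> ChipGeometry:
    """Assemble a :class:`ChipGeometry` with a validated domain and cell placement.

    The domain defaults to ``domain_factor * (w + d)`` in each direction,
    large enough that the homogeneous-Neumann truncation perturbs the gap
    field by well under a percent (checked by a domain-doubling test).

    Cells wider than the gap physically rest on top of the passivated
    electrodes; ``on_overlap="allow"`` models this by excluding the cell
    disk from the electrode Dirichlet region, while the default
    ``"error"`` rejects overlapping placements.
    """
    if not cell_radius_um > 0:
        raise GeometryError("cell radius must be > 0")
    if domain_um is None:
        extent = domain_factor * (pair.width_um + pair.gap_um)
        domain_um = (extent, extent)
    geom = ChipGeometry(
        pair=pair,
        cell_radius_um=cell_radius_um,
        cell_center_um=cell_center_um,
        domain_um=domain_um,
        on_overlap=on_overlap,
    )
    cx, cy = cell_center_um
    lx, ly = domain_um
    if abs(cx) + cell_radius_um > lx / 2 or abs(cy) + cell_radius_um > ly / 2:
        raise GeometryError("cell disk does not fit inside the domain")
    if on_overlap == "error" and geom.cell_overlaps_electrodes():
        raise GeometryError(
            f"cell (R={cell_radius_um} um at {cell_center_um}) overlaps an "
            f"electrode (gap {pair.gap_um} um); pass on_overlap='allow' to "
            "model a cell resting on the passivated electrodes"
        )
    return geom


@dataclass(frozen=True)
class Resolution:
    """Grid-resolution knobs.

    ``nodes_per_radius`` sets the fine spacing ``h = R / nodes_per_radius``
    around the cell; the gap/tip region is meshed at ``mid_factor * h``
    (capped at 5 um) and the far field grows geometrically by ``growth``
    per cell.  ``sample_offset_cells`` is the interface-sampling offset in
    units of ``h``.
    """

    nodes_per_radius: int = 20
    mid_factor: float = 4.0
    growth: float = 1.3
    stations: int = 360
    sample_offset_cells: float = 1.5
    max_harmonic: int = 32

    def __post_init__(self) -> None:
        if self.nodes_per_radius < 2:
            raise ValueError("nodes_per_radius must be >= 2")


COARSE = Resolution(nodes_per_radius=8, stations=180)


@dataclass
class FieldSolution:
    """Potential and field on the tensor grid plus cell-interface samples.

    ``phi`` is indexed ``[i, j]`` over ``(x[i], y[j])``; fields are in V/m
    (grid coordinates in um).  ``e_out``/``e_in`` are sampled just outside
    and inside the cell boundary at angles ``theta`` with outward normals
    ``normals``.
    """

    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    theta: np.ndarray
    e_out: np.ndarray
    e_in: np.ndarray
    normals: np.ndarray
    eps_m: float
    eps_c: float
    geom: ChipGeometry | None = None
    h_cell_um: float = 0.0
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        """Node table (x_um, y_um, phi_V, Ex_Vm, Ey_Vm) as a DataFrame."""
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        return pd.DataFrame(
            {
                "x_um": xx.ravel(),
                "y_um": yy.ravel(),
                "phi_V": self.phi.ravel(),
                "Ex_Vm": self.ex.ravel(),
                "Ey_Vm": self.ey.ravel(),
            }
        )


def _graded_axis(
    fine_half: float,
    mid_half: float,
    half_extent: float,
    h_fine: float,
    h_mid: float,
    growth: float,
    features: tuple[tuple[float, float], ...] = (),
) -> np.ndarray:
    """Symmetric 1-D grid from a spacing budget.

    Fine spacing ``h_fine`` to ``fine_half``, ``h_mid`` to ``mid_half``,
    geometric growth beyond.  ``features`` are (position, local spacing)
    pairs — electrode edges whose corner singularities need local
    resolution; spacing relaxes away from them at a fixed 0.4 grade.
    The node nearest each feature is snapped onto it so Dirichlet
    boundaries land on grid planes.
    """

    def budget(x: float) -> float:
        if x < fine_half:
            base = h_fine
        elif x < mid_half:
            base = h_mid
        else:
            base = np.inf  # growth-capped only
        for pos, hf in features:
            if pos <= half_extent:
                base = min(base, hf + 0.4 * abs(x - pos))
        return base

    pts = [0.0]
    h = min(budget(0.0), h_fine)
    while pts[-1] < half_extent - 1e-12:
        h = min(budget(pts[-1]), h * growth)
        pts.append(min(pts[-1] + h, half_extent))
    # avoid a sliver at the boundary
    if len(pts) > 2 and pts[-1] - pts[-2] < 0.25 * (pts[-2] - pts[-3]):
        pts.pop(-2)
    arr = np.asarray(pts)
    for pos, _ in features:
        if 0.0 < pos < half_extent:
            i = int(np.argmin(np.abs(arr - pos)))
            if 0 < i < len(arr) - 1:
                arr[i] = pos
    return np.concatenate([-arr[:0:-1], arr])


def _build_grid(geom: ChipGeometry, res: Resolution) -> tuple[np.ndarray, np.ndarray, float]:
    pair = geom.pair
    r = geom.cell_radius_um
    cx, cy = geom.cell_center_um
    lx, ly = geom.domain_um
    h = r / res.nodes_per_radius
    h_mid = min(res.mid_factor * h, 5.0)
    prot_l = pair.protrusion_um("left")
    prot_r = pair.protrusion_um("right")
    prot = max(prot_l, prot_r)
    fine_half = max(abs(cx), abs(cy)) + r + 2.0 * h
    mid_half_x = max(pair.gap_um / 2.0 + prot + 5.0, fine_half)
    mid_half_y = max(pair.width_um / 2.0 + 5.0, fine_half)
    tip = pair.gap_um / 2.0
    feats_x = tuple(
        {(tip, h), (tip + prot_l, h), (tip + prot_r, h)}
    )
    feats_y = ((pair.width_um / 2.0, h),)
    x = _graded_axis(fine_half, mid_half_x, lx / 2.0, h, h_mid, res.growth, feats_x)
    y = _graded_axis(fine_half, mid_half_y, ly / 2.0, h, h_mid, res.growth, feats_y)
    return x, y, h


def solve_potential(
    geom: ChipGeometry,
    eps_m: float,
    eps_c: float,
    voltage: float,
    resolution: Resolution | None = None,
) -> FieldSolution:
    """Solve ``div(eps grad phi) = 0`` for the chip and sample the cell interface.

    ``eps_m``/``eps_c`` are the (relative) permittivities of medium and
    cell; only their ratio enters the potential.  Electrodes are held at
    ``+voltage/2`` (left) and ``-voltage/2`` (right); the outer box is
    insulating.  Fields are returned in V/m.
    """
    res = resolution or Resolution()
    if eps_m <= 0 or eps_c <= 0:
        raise ValueError("permittivities must be > 0")
    x, y, h = _build_grid(geom, res)
    nx, ny = len(x), len(y)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    cx, cy = geom.cell_center_um
    r = geom.cell_radius_um
    in_cell = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2

    left = geom.electrode_mask("left")(xx, yy)
    right = geom.electrode_mask("right")(xx, yy)
    if geom.on_overlap == "allow":
        left &= ~in_cell
        right &= ~in_cell
    dirichlet = left | right
    phi_d = np.zeros((nx, ny))
    phi_d[left] = +voltage / 2.0
    phi_d[right] = -voltage / 2.0

    eps_fx, eps_fy = _face_permittivities(x, y, eps_m, eps_c, cx, cy, r)
    phi = _solve_piecewise_laplace(x, y, eps_fx, eps_fy, dirichlet, phi_d)

    ex, ey = _gradient_field(x, y, phi)
    sol = FieldSolution(
        x=x,
        y=y,
        phi=phi,
        ex=ex,
        ey=ey,
        theta=np.empty(0),
        e_out=np.empty((0, 2)),
        e_in=np.empty((0, 2)),
        normals=np.empty((0, 2)),
        eps_m=eps_m,
        eps_c=eps_c,
        geom=geom,
        h_cell_um=h,
        meta={"nx": nx, "ny": ny, "voltage": voltage},
    )
    _attach_interface_samples(sol, res)
    return sol


def _segment_fraction_in_disk(
    a: np.ndarray, b: np.ndarray, centre: float, half_chord_sq: np.ndarray
) -> np.ndarray:
    """Fraction of the 1-D segments [a, b] lying inside a chord of the disk."""
    s = np.sqrt(np.clip(half_chord_sq, 0.0, None))
    lo = np.maximum(a, centre - s)
    hi = np.minimum(b, centre + s)
    return np.clip(hi - lo, 0.0, None) / (b - a)


def _face_permittivities(
    x: np.ndarray,
    y: np.ndarray,
    eps_m: float,
    eps_c: float,
    cx: float,
    cy: float,
    r: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic sub-segment averages of eps along each grid face.

    Integrating 1/eps exactly along the face segment through the circular
    interface keeps the flux coefficients smooth as the interface cuts
    the grid, avoiding the O(h) staircase noise of node-sampled eps.
    """
    # x-faces: segments [x_i, x_{i+1}] at height y_j
    chord_x = r**2 - (y[None, :] - cy) ** 2  # (1, ny)
    frac_x = _segment_fraction_in_disk(
        x[:-1, None], x[1:, None], cx, np.broadcast_to(chord_x, (len(x) - 1, len(y)))
    )
    eps_fx = 1.0 / (frac_x / eps_c + (1.0 - frac_x) / eps_m)
    # y-faces: segments [y_j, y_{j+1}] at abscissa x_i
    chord_y = r**2 - (x[:, None] - cx) ** 2
    frac_y = _segment_fraction_in_disk(
        y[None, :-1], y[None, 1:], cy, np.broadcast_to(chord_y, (len(x), len(y) - 1))
    )
    eps_fy = 1.0 / (frac_y / eps_c + (1.0 - frac_y) / eps_m)
    return eps_fx, eps_fy


def _solve_piecewise_laplace(
    x: np.ndarray,
    y: np.ndarray,
    eps_fx: np.ndarray,
    eps_fy: np.ndarray,
    dirichlet: np.ndarray,
    phi_d: np.ndarray,
) -> np.ndarray:
    """Vertex-centred FV solve of div(eps grad phi)=0 on a tensor grid.

    ``eps_fx``/``eps_fy`` are permittivities on the x- and y-faces
    (shapes ``(nx-1, ny)`` and ``(nx, ny-1)``).
    """
    nx, ny = len(x), len(y)
    dx = np.diff(x)
    dy = np.diff(y)
    # control-volume widths
    wx = np.empty(nx)
    wx[1:-1] = 0.5 * (x[2:] - x[:-2])
    wx[0] = dx[0] / 2.0
    wx[-1] = dx[-1] / 2.0
    wy = np.empty(ny)
    wy[1:-1] = 0.5 * (y[2:] - y[:-2])
    wy[0] = dy[0] / 2.0
    wy[-1] = dy[-1] / 2.0

    # face conductances between (i,j)-(i+1,j) and (i,j)-(i,j+1)
    gx = eps_fx * wy[None, :] / dx[:, None]  # (nx-1, ny)
    gy = eps_fy * wx[:, None] / dy[None, :]  # (nx, ny-1)

    idx = np.arange(nx * ny).reshape(nx, ny)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros((nx, ny))

    def add_coupling(g: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> None:
        gf = g.ravel()
        rows.extend([ia.ravel(), ib.ravel()])
        cols.extend([ib.ravel(), ia.ravel()])
        vals.extend([-gf, -gf])

    add_coupling(gx, idx[:-1, :], idx[1:, :])
    add_coupling(gy, idx[:, :-1], idx[:, 1:])
    diag[:-1, :] += gx
    diag[1:, :] += gx
    diag[:, :-1] += gy
    diag[:, 1:] += gy

    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())

    a = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    )
    b = np.zeros(nx * ny)

    # impose Dirichlet rows
    d = dirichlet.ravel()
    vd = phi_d.ravel()
    # move known values to RHS for non-Dirichlet rows
    b -= a[:, d] @ vd[d]
    # zero Dirichlet columns/rows, set identity
    keep = sparse.diags((~d).astype(float))
    a = keep @ a @ keep + sparse.diags(d.astype(float))
    b[d] = vd[d]
    b[~d] -= 0.0

    phi = spsolve(a.tocsc(), b)
    if not np.all(np.isfinite(phi)):
        raise SolverError("linear solve produced non-finite potential")
    resid = np.linalg.norm(a @ phi - b) / max(np.linalg.norm(b), 1e-300)
    if resid > 1e-8:
        raise SolverError(f"linear solve residual too large: {resid:.3e}")
    return phi.reshape(nx, ny)


def _gradient_field(
    x: np.ndarray, y: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """E = -grad(phi); um coordinates -> V/m (factor 1e6)."""
    dpx = np.gradient(phi, x, axis=0)
    dpy = np.gradient(phi, y, axis=1)
    return -dpx * 1e6, -dpy * 1e6


def _attach_interface_samples(sol: FieldSolution, res: Resolution) -> None:
    """Sample E on both sides of the cell boundary from the potential.

    Per angular station a quadratic is fitted through the potential at
    three one-sided radial offsets (starting ``sample_offset_cells`` fine
    cells away from the interface, where the interface smearing of the
    discrete scheme has decayed); its derivative at r = R gives the
    normal field on that side and its value the interface potential.
    The tangential field is the spectral theta-derivative of the
    extrapolated interface potential, low-passed at ``max_harmonic`` to
    suppress staircase noise that spectral differentiation would amplify.
    """
    geom = sol.geom
    assert geom is not None
    r = geom.cell_radius_um
    cx, cy = geom.cell_center_um
    h = sol.h_cell_um
    k = res.stations
    theta = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    normals = np.column_stack([np.cos(theta), np.sin(theta)])
    tangents = np.column_stack([-np.sin(theta), np.cos(theta)])
    interp_phi = RegularGridInterpolator((sol.x, sol.y), sol.phi)

    base = res.sample_offset_cells
    offsets = np.array([base, base + 1.0, base + 2.0]) * h
    # keep the innermost sampling ring inside the disk
    if offsets[-1] > 0.8 * r:
        offsets = offsets * (0.8 * r / offsets[-1])

    def fit_side(sign: float) -> tuple[np.ndarray, np.ndarray]:
        radii = r + sign * offsets
        vals = np.array(
            [
                interp_phi(
                    np.column_stack(
                        [cx + ri * np.cos(theta), cy + ri * np.sin(theta)]
                    )
                )
                for ri in radii
            ]
        )
        design = np.vander(sign * offsets * 1e-6, 3)  # columns (s^2, s, 1)
        coef = np.linalg.lstsq(design, vals, rcond=None)[0]
        return coef[2], -coef[1]  # phi(R), E_normal(R) on this side

    phi_out, en_out = fit_side(+1.0)
    phi_in, en_in = fit_side(-1.0)

    freqs = np.fft.rfftfreq(k, d=1.0 / k)
    cut = min(res.max_harmonic, k // 3)

    def lowpass(f: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(f)
        spec[freqs > cut] = 0.0
        return np.real(np.fft.irfft(spec, k))

    phi_interface = 0.5 * (phi_out + phi_in)
    spec = np.fft.rfft(phi_interface)
    spec[freqs > cut] = 0.0
    e_tan = -np.real(np.fft.irfft(1j * freqs * spec, k)) / (r * 1e-6)
    en_out = lowpass(en_out)
    en_in = lowpass(en_in)

    sol.theta = theta
    sol.normals = normals
    sol.e_out = en_out[:, None] * normals + e_tan[:, None] * tangents
    sol.e_in = en_in[:, None] * normals + e_tan[:, None] * tangents


def solve_uniform_field_disk(
    cell_radius_um: float,
    eps_m: float,
    eps_c: float,
    e0_vm: float,
    *,
    domain_um: float | None = None,
    resolution: Resolution | None = None,
) -> FieldSolution:
    """Auxiliary harness: dielectric disk in an imposed uniform field E0 x-hat.

    Dirichlet strips on the left/right walls impose ``phi = -E0 * x``;
    top/bottom are insulating.  Used to validate the solver against the
    classical transmission solution for a dielectric cylinder, for which
    the interior field is uniform with magnitude ``2 eps_m/(eps_m+eps_c) E0``.
    """
    res = resolution or Resolution()
    r = cell_radius_um
    lx = domain_um if domain_um is not None else 16.0 * r
    # reuse the chip grid machinery with a dummy pair far outside the domain
    pair = ElectrodePair(width_um=lx, gap_um=4.0 * lx)
    geom = ChipGeometry(
        pair=pair, cell_radius_um=r, domain_um=(lx, lx), on_overlap="allow"
    )
    x, y, h = _build_grid(geom, res)
    nx, ny = len(x), len(y)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    dirichlet = np.zeros((nx, ny), dtype=bool)
    dirichlet[0, :] = True
    dirichlet[-1, :] = True
    phi_d = np.where(dirichlet, -e0_vm * 1e-6 * xx, 0.0)
    eps_fx, eps_fy = _face_permittivities(x, y, eps_m, eps_c, 0.0, 0.0, r)
    phi = _solve_piecewise_laplace(x, y, eps_fx, eps_fy, dirichlet, phi_d)
    ex, ey = _gradient_field(x, y, phi)
    sol = FieldSolution(
        x=x,
        y=y,
        phi=phi,
        ex=ex,
        ey=ey,
        theta=np.empty(0),
        e_out=np.empty((0, 2)),
        e_in=np.empty((0, 2)),
        normals=np.empty((0, 2)),
        eps_m=eps_m,
        eps_c=eps_c,
        geom=geom,
        h_cell_um=h,
        meta={"harness": "uniform_field", "e0_vm": e0_vm},
    )
    _attach_interface_samples(sol, res)
    return sol


def refine(res: Resolution, factor: float = 1.5) -> Resolution:
    """One refinement step: more nodes per radius, same grading policy."""
    return replace(
        res, nodes_per_radius=max(int(np.ceil(res.nodes_per_radius * factor)), res.nodes_per_radius + 1)
    )
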