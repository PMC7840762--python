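"""Disk elasticity: equilibration, Michell-series solution, and elongation readout."""

import numpy as np
import pytest

from depstretch import (
    DiskDisplacement,
    ElasticProperties,
    SurfaceTraction,
    deform_disk,
    elongation,
    equilibrate_traction,
)
from depstretch.elastic_response import (
    UnequilibratedTractionError,
    traction_resultants,
)


def _traction(f, theta=None):
    k = len(f)
    if theta is None:
        theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    n = np.column_stack([np.cos(theta), np.sin(theta)])
    return SurfaceTraction(theta=theta, f=np.asarray(f, dtype=float), normals=n)


def _radial_traction(fr, ft=None):
    k = len(fr)
    theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
    n = np.column_stack([np.cos(theta), np.sin(theta)])
    t = np.column_stack([-np.sin(theta), np.cos(theta)])
    f = fr[:, None] * n
    if ft is not None:
        f = f + ft[:, None] * t
    return SurfaceTraction(theta=theta, f=f, normals=n)


class TestEquilibrate:
    def test_self_equilibrated_input_unchanged(self):
        th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        tr = _radial_traction(np.cos(2 * th))
        out = equilibrate_traction(tr)
        assert np.allclose(out.f, tr.f, atol=1e-12)

    def test_uniform_translation_traction_removed(self):
        tr = _traction(np.tile([3.0, -1.5], (128, 1)))
        out = equilibrate_traction(tr)
        assert np.allclose(out.f, 0.0, atol=1e-12)

    def test_random_traction_balanced_to_quadrature_tolerance(self, rng):
        tr = _traction(rng.normal(0, 10.0, (180, 2)))
        out = equilibrate_traction(tr)
        force, torque = traction_resultants(out, 4.0)
        scale = np.abs(out.f).max() * 2 * np.pi * 4e-6
        assert np.linalg.norm(force) / scale < 1e-10
        assert abs(torque) / (scale * 4e-6) < 1e-10


class TestDeformDisk:
    def test_zero_traction_zero_displacement(self):
        tr = _traction(np.zeros((64, 2)))
        disp = deform_disk(tr, 4.0)
        u = disp.displacement_cartesian(np.ones(8), np.linspace(0, 6, 8))
        assert np.allclose(u, 0.0)

    @pytest.mark.parametrize("nu", [0.0, 0.3, 0.49])
    def test_lame_uniform_pressure_closed_form(self, nu):
        """Outward pressure p on a plane-stress disk: u_r(R) = p R (1-nu)/E."""
        p, r_um, e_pa = 5.0, 4.0, 100.0
        th = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        tr = _radial_traction(np.full(90, p))
        disp = deform_disk(
            tr, r_um, ElasticProperties(e_pa, nu), equilibrium_rtol=1e-6
        )
        u_r, u_t = disp.displacement_polar(np.ones_like(th), th)
        expected = p * (r_um) * (1 - nu) / e_pa  # um
        assert np.allclose(u_r, expected, rtol=5e-3)
        assert np.allclose(u_t, 0.0, atol=1e-12)

    def test_unequilibrated_traction_rejected(self):
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        tr = _radial_traction(np.cos(th))  # net force along x
        with pytest.raises(UnequilibratedTractionError):
            deform_disk(tr, 4.0)

    def test_cos2_mode_gives_elliptical_deformation(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        tr = _radial_traction(2.0 * np.cos(2 * th))
        disp = deform_disk(tr, 4.0, ElasticProperties(100.0, 0.3))
        u_r, _ = disp.displacement_polar(np.ones_like(th), th)
        # stretch along x, equal compression along y, zero at 45 degrees
        assert u_r[0] > 0
        assert u_r[90] == pytest.approx(-u_r[0], rel=1e-9)
        assert u_r[45] == pytest.approx(0.0, abs=1e-12 + 1e-9 * u_r[0])

    @pytest.mark.parametrize("regime", ["plane_stress", "plane_strain"])
    @pytest.mark.parametrize("n", [2, 3])
    def test_michell_solution_verified_symbolically(self, n, regime):
        """Independent sympy oracle: the closed-form displacement satisfies the
        Navier equations and reproduces the imposed boundary traction."""
        import sympy as sp

        nu_val = sp.Rational(3, 10)
        e_val = sp.Integer(100)
        mu = e_val / (2 * (1 + nu_val))
        if regime == "plane_strain":
            kappa = 3 - 4 * nu_val
            lam = e_val * nu_val / ((1 + nu_val) * (1 - 2 * nu_val))
        else:
            kappa = (3 - nu_val) / (1 + nu_val)
            lam = e_val * nu_val / (1 - nu_val**2)  # effective plane-stress lambda

        r, th = sp.symbols("r theta", positive=True)
        fn, gn = sp.Rational(7, 3), sp.Rational(-2, 5)  # cos/sin boundary amplitudes
        r_disk = sp.Integer(1)

        # solve the 2x2 Michell system as the implementation does
        m = sp.Matrix(
            [
                [n * (1 - n), n + 2 - n**2],
                [n * (n - 1), n * (n + 1)],
            ]
        )
        a_hat, b_hat = m.LUsolve(sp.Matrix([fn, gn]))
        u_r = (a_hat * (-n) * r ** (n - 1) + b_hat * (kappa - n - 1) * r ** (n + 1)) / (
            2 * mu
        ) * sp.cos(n * th)
        u_t = (a_hat * n * r ** (n - 1) + b_hat * (kappa + n + 1) * r ** (n + 1)) / (
            2 * mu
        ) * sp.sin(n * th)

        err = sp.symbols("err")  # noqa: F841 - readability only
        e_rr = sp.diff(u_r, r)
        e_tt = u_r / r + sp.diff(u_t, th) / r
        e_rt = (sp.diff(u_r, th) / r + sp.diff(u_t, r) - u_t / r) / 2
        tr_eps = e_rr + e_tt
        s_rr = lam * tr_eps + 2 * mu * e_rr
        s_tt = lam * tr_eps + 2 * mu * e_tt
        s_rt = 2 * mu * e_rt

        eq_r = sp.diff(s_rr, r) + sp.diff(s_rt, th) / r + (s_rr - s_tt) / r
        eq_t = sp.diff(s_rt, r) + sp.diff(s_tt, th) / r + 2 * s_rt / r
        assert sp.simplify(eq_r) == 0
        assert sp.simplify(eq_t) == 0
        assert sp.simplify(s_rr.subs(r, r_disk) - fn * sp.cos(n * th)) == 0
        assert sp.simplify(s_rt.subs(r, r_disk) - gn * sp.sin(n * th)) == 0

    def test_numeric_solver_matches_symbolic_coefficients(self):
        """deform_disk reproduces the per-harmonic closed form for a mixed load."""
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        fr = 1.5 * np.cos(2 * th) + 0.7 * np.sin(3 * th)
        ft = -0.4 * np.sin(2 * th) + 0.2 * np.cos(3 * th)
        tr = equilibrate_traction(_radial_traction(fr, ft))
        props = ElasticProperties(100.0, 0.3)
        disp = deform_disk(tr, 4.0, props)
        # reconstruct boundary traction from the stored Airy coefficients
        mu = props.shear_modulus_pa
        u_r, u_t = disp.displacement_polar(1.0, th)
        # independent check: cos2 radial response amplitude from the 2x2 system
        import numpy.linalg as la

        for n, (f_amp, g_amp) in ((2, (1.5, -0.4)), (3, (0.7, -0.2))):
            m = np.array(
                [[n * (1 - n), n + 2 - n**2], [n * (n - 1), n * (n + 1)]]
            )
            a_hat, b_hat = la.solve(m, [f_amp, g_amp])
            kappa = props.kolosov_kappa
            amp = (-n * a_hat + (kappa - n - 1) * b_hat) / (2 * mu) * 4e-6 * 1e6
            grid = np.cos(n * th) if n == 2 else np.sin(n * th)
            proj = 2 * np.mean(u_r * grid)
            assert proj == pytest.approx(amp, rel=1e-9)


class TestElongation:
    def test_zero_displacement_zero_elongation(self):
        tr = _traction(np.zeros((64, 2)))
        res = elongation(deform_disk(tr, 4.0), 4.0)
        assert res.lstar == 0.0
        assert res.deformed_semi_axis_um == 4.0

    def test_tip_displacement_arithmetic(self):
        # manufacture a displacement object with known boundary motion
        disp = DiskDisplacement(
            cell_radius_um=4.0,
            props=ElasticProperties(100.0, 0.3),
            n=np.array([0]),
            a_hat=np.array([0.0 + 0j]),
            b_hat=np.array([0.0 + 0j]),
        )
        # uniform pressure giving u_r = 0.8 um at R: invert the Lame factor
        props = disp.props
        f0 = 0.8 / (4.0 * (1 - 0.3) / 100.0)
        disp.a_hat = np.array([complex(f0)])
        res = elongation(disp, 4.0)
        assert res.u_tip_um == pytest.approx(0.8, rel=1e-9)
        assert res.lstar == pytest.approx(0.2, rel=1e-9)

    def test_elongation_along_arbitrary_axis(self):
        th = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        tr = _radial_traction(2.0 * np.cos(2 * th))
        disp = deform_disk(tr, 4.0, ElasticProperties(100.0, 0.3))
        along = elongation(disp, 4.0, axis=(1.0, 0.0))
        across = elongation(disp, 4.0, axis=(0.0, 1.0))
        assert along.lstar > 0 > across.lstar
        assert across.lstar == pytest.approx(-along.lstar, rel=1e-9)
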