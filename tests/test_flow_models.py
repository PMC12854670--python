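"""Stokes flow fields: boundary conditions, far fields, force balance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ciliaflow.flow_models import (
    DomainError,
    EnvelopeField,
    ModelSpec,
    ParameterError,
    SingularityError,
    SinkingField,
    StokesletSphereField,
    calibrate_swimming_speed,
    envelope_velocity,
    field_to_frame,
    legendre_deriv_table,
    legendre_table,
    make_field,
)


# ---------------------------------------------------------------------------
# envelope (squirmer / tethered pump)
# ---------------------------------------------------------------------------

class TestEnvelope:
    def test_motile_slip_boundary_condition(self):
        f = EnvelopeField("motile")
        u_r, u_t = f.velocity(1.0, math.pi / 2)
        assert u_r == pytest.approx(0.0, abs=1e-14)
        assert u_t == pytest.approx(1.0, abs=1e-14)  # (3/2) U = slip scale

    def test_motile_far_field_is_swimming_speed(self):
        f = EnvelopeField("motile")
        u_r, u_t = f.velocity(1e4, 0.7)
        speed = math.hypot(u_r, u_t)
        assert speed == pytest.approx(2.0 / 3.0, rel=1e-10)

    def test_sessile_matches_generic_ansatz_oracle(self):
        # independent solve: psi = sin^2(theta) (A/r + B r), impose
        # u_r(1) = 0 and u_theta(1) = slip scale, evaluate at r = 2
        mat = np.array([[1.0, 1.0], [1.0, -1.0]])  # A+B=0 ; A-B=1
        A, B = np.linalg.solve(mat, [0.0, 1.0])
        r, th = 2.0, math.pi / 2
        u_t_oracle = math.sin(th) * (A / r**3 - B / r)
        u_r_oracle = 2 * math.cos(th) * (A / r**3 + B / r)
        f = EnvelopeField("sessile")
        u_r, u_t = f.velocity(r, th)
        assert u_t == pytest.approx(u_t_oracle, rel=1e-12)
        assert u_t == pytest.approx(0.3125, rel=1e-12)
        assert u_r == pytest.approx(u_r_oracle, abs=1e-12)

    @given(st.floats(1.0, 50.0), st.floats(0.01, math.pi - 0.01))
    @settings(max_examples=50, deadline=None)
    def test_slip_and_frame_consistency(self, r, theta):
        """Body-frame field plus +U z equals the lab-frame source doublet."""
        f = EnvelopeField("motile")
        u_r, u_t = f.velocity(r, theta)
        U = f.U
        lab_r = u_r + U * math.cos(theta)
        lab_t = u_t - U * math.sin(theta)
        assert lab_r == pytest.approx(U * math.cos(theta) / r**3, abs=1e-12)
        assert lab_t == pytest.approx(U * math.sin(theta) / (2 * r**3), abs=1e-12)

    def test_rejects_interior_and_sinking(self):
        with pytest.raises(DomainError):
            EnvelopeField("motile").velocity(0.5, 1.0)
        with pytest.raises(ParameterError):
            EnvelopeField("sinking")
        with pytest.raises(ParameterError):
            envelope_velocity(ModelSpec("sinking", "sinking", U_sink=1.0), 2.0, 1.0)


# ---------------------------------------------------------------------------
# sinking sphere
# ---------------------------------------------------------------------------

class TestSinking:
    def test_no_slip_and_far_field(self):
        f = SinkingField(1.0)
        u = f.velocity(1.0, np.linspace(0, math.pi, 11))
        assert np.max(np.abs(u)) < 1e-14
        u_r, _ = f.velocity(1e5, 0.0)
        assert u_r == pytest.approx(-1.0, rel=1e-4)  # 1 - 3a/(2r) at r = 1e5

    def test_classical_formula_and_streamfunction(self):
        f = SinkingField(2.0)
        _, u_t = f.velocity(2.0, math.pi / 2)
        assert u_t == pytest.approx(2.0 * 0.59375, rel=1e-12)
        # u must be derivable from psi (stream-function consistency)
        r, th, h = 3.0, 1.1, 1e-5
        dpsi_dth = (f.psi(r, th + h) - f.psi(r, th - h)) / (2 * h)
        dpsi_dr = (f.psi(r + h, th) - f.psi(r - h, th)) / (2 * h)
        u_r, u_t = f.velocity(r, th)
        assert u_r == pytest.approx(dpsi_dth / (r**2 * math.sin(th)), rel=1e-7)
        assert u_t == pytest.approx(-dpsi_dr / (r * math.sin(th)), rel=1e-7)


# ---------------------------------------------------------------------------
# stokeslet + sphere
# ---------------------------------------------------------------------------

class TestStokesletSphere:
    def test_no_slip_on_sphere(self, stokeslet_sessile_L2, theta_grid):
        u_r, u_t = stokeslet_sessile_L2.velocity(np.ones_like(theta_grid), theta_grid)
        assert np.max(np.abs(u_r)) < 1e-8
        assert np.max(np.abs(u_t)) < 1e-8

    def test_no_slip_motile_body_frame(self, stokeslet_motile_L2, theta_grid):
        u_r, u_t = stokeslet_motile_L2.velocity(np.ones_like(theta_grid), theta_grid)
        scale = abs(stokeslet_motile_L2.F)
        assert np.max(np.abs(u_r)) < 1e-8 * scale
        assert np.max(np.abs(u_t)) < 1e-8 * scale

    def test_biharmonic_streamfunction_residual(self, stokeslet_sessile_L2):
        """E^4 psi = 0 away from the singularity (nested centered FD with
        Richardson extrapolation; the raw FD residual converges at 2nd order
        to its own truncation floor)."""
        psi = stokeslet_sessile_L2.psi

        def e2(fn, h):
            def out(r, th):
                prr = (fn(r + h, th) - 2 * fn(r, th) + fn(r - h, th)) / h**2
                g = lambda t: (fn(r, t + h) - fn(r, t - h)) / (2 * h) / np.sin(t)
                return prr + np.sin(th) / r**2 * (g(th + h) - g(th - h)) / (2 * h)
            return out

        rng = np.random.default_rng(7)
        r = rng.uniform(6.0, 15.0, 100)
        th = rng.uniform(0.4, math.pi - 0.4, 100)
        coarse = e2(e2(psi, 0.1), 0.1)(r, th)
        fine = e2(e2(psi, 0.05), 0.05)(r, th)
        assert np.max(np.abs(fine)) < 0.35 * np.max(np.abs(coarse))  # ~O(h^2)
        assert np.max(np.abs((4 * fine - coarse) / 3)) < 2e-6

    def test_motile_field_is_force_free(self, stokeslet_motile_L2):
        """The 1/r (Stokeslet) moment of the far field vanishes: the traction
        transmitted to the sphere balances the cilia reaction."""
        from numpy.polynomial.legendre import leggauss
        mu, w = leggauss(64)
        th = np.arccos(mu)

        U = stokeslet_motile_L2.U

        def moment(r):  # 3/2 * int u_r P_1 dmu = (2 beta)/r + dipole/r^3
            u_r, _ = stokeslet_motile_L2.velocity(np.full_like(th, r), th)
            u_r = u_r + U * mu  # remove the uniform stream of the body frame
            return 1.5 * np.sum(w * u_r * mu)

        m1, m2 = moment(100.0), moment(200.0)
        # solve [1/r, 1/r^3] model for the 1/r amplitude
        a = np.linalg.solve([[1 / 100, 100**-3], [1 / 200, 200**-3]], [m1, m2])[0]
        net_force = abs(4 * math.pi * a)  # 8 pi beta = force, a = 2 beta
        assert net_force < 1e-6 * abs(stokeslet_motile_L2.F)

    def test_linearity_in_force(self):
        f1 = StokesletSphereField(1.5, 1.0, "sessile")
        f2 = StokesletSphereField(1.5, 2.0, "sessile")
        r = np.array([1.3, 2.0, 7.0])
        th = np.array([0.5, 1.5, 2.8])
        u1 = f1.velocity(r, th)
        u2 = f2.velocity(r, th)
        np.testing.assert_allclose(u2[0], 2 * u1[0], rtol=1e-13)
        np.testing.assert_allclose(u2[1], 2 * u1[1], rtol=1e-13)

    @pytest.mark.parametrize(
        "make,slope_max",
        [
            (lambda: EnvelopeField("sessile"), -0.9),
            (lambda: EnvelopeField("motile"), -2.7),
            (lambda: StokesletSphereField(2.0, 1.0, "sessile"), -0.9),
            (lambda: StokesletSphereField(2.0, None, "motile"), -1.8),
        ],
    )
    def test_far_field_decay_exponent(self, make, slope_max):
        """Sessile ~ 1/r (tethered, forced), motile envelope ~ 1/r^3,
        motile stokeslet-sphere ~ 1/r^2 or faster (force-free)."""
        field = make()
        r = np.geomspace(20.0, 200.0, 12)
        u_r, u_t = field.velocity(r, np.full_like(r, 1.0))
        if getattr(field, "U", 0.0):  # remove the uniform stream in body frame
            u_r = u_r + field.U * math.cos(1.0)
            u_t = u_t - field.U * math.sin(1.0)
        speed = np.hypot(u_r, u_t)
        slope = np.polyfit(np.log(r), np.log(speed), 1)[0]
        assert slope < slope_max
        if slope_max in (-0.9, -2.7):  # nominal exponents known exactly
            nominal = -1.0 if slope_max == -0.9 else -3.0
            assert abs(slope - nominal) < 0.1 * abs(nominal)

    def test_singularity_guard_and_parameter_errors(self):
        f = StokesletSphereField(2.0, 1.0, "sessile")
        with pytest.raises(SingularityError) as err:
            f.velocity(2.0, 0.0)
        assert err.value.point == (2.0, 0.0)
        with pytest.raises(ParameterError):
            StokesletSphereField(0.9, 1.0, "sessile")
        with pytest.raises(ParameterError):
            ModelSpec("stokeslet_sphere", "sessile", L=0.5)


# ---------------------------------------------------------------------------
# swimming-speed calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_envelope_exact(self):
        assert calibrate_swimming_speed("envelope", slip_amplitude=1.0).U == pytest.approx(2 / 3)
        assert calibrate_swimming_speed("envelope", slip_amplitude=3.0).U == pytest.approx(2.0)

    def test_zero_force_zero_speed(self):
        assert calibrate_swimming_speed("stokeslet_sphere", L=2.0, F=0.0).U == 0.0

    @pytest.mark.parametrize("L", [1.2, 2.0, 5.0, 100.0])
    def test_mobility_matches_faxen_oracle(self, L):
        """Faxen's law is exact for a sphere in an ambient Stokeslet flow:
        U = F (1 - 3a/(2L) + a^3/(2L^3)) / (6 pi eta a)."""
        cal = calibrate_swimming_speed("stokeslet_sphere", L=L, F=1.0)
        oracle = (1 - 1.5 / L + 0.5 / L**3) / (6 * math.pi)
        assert cal.U == pytest.approx(oracle, rel=1e-12)

    def test_mobility_limits_to_stokes_drag(self):
        cal = calibrate_swimming_speed("stokeslet_sphere", L=100.0, F=1.0)
        assert cal.alpha * 6 * math.pi == pytest.approx(1.0, abs=0.02)

    def test_force_for_requested_speed_roundtrip(self):
        cal = calibrate_swimming_speed("stokeslet_sphere", L=2.0, U_target=2 / 3)
        back = calibrate_swimming_speed("stokeslet_sphere", L=2.0, F=cal.F_cilia)
        assert back.U == pytest.approx(2 / 3, rel=1e-12)
        fld = StokesletSphereField(2.0, cal.F_cilia, "motile")
        assert fld.U == pytest.approx(2 / 3, rel=1e-10)


# ---------------------------------------------------------------------------
# plumbing
# ---------------------------------------------------------------------------

class TestPlumbing:
    def test_legendre_tables_match_scipy(self):
        from scipy.special import eval_legendre
        mu = np.linspace(-1, 1, 21)
        table = legendre_table(mu, 12)
        for n in (0, 1, 5, 12):
            np.testing.assert_allclose(table[n], eval_legendre(n, mu), atol=1e-12)
        dp = legendre_deriv_table(mu[1:-1], 8)
        h = 1e-6
        fd = (eval_legendre(8, mu[1:-1] + h) - eval_legendre(8, mu[1:-1] - h)) / (2 * h)
        np.testing.assert_allclose(dp[8], fd, rtol=1e-5, atol=1e-5)

    def test_model_spec_config_roundtrip(self):
        spec = ModelSpec("stokeslet_sphere", "motile", L=2.5, F_cilia=3.0)
        again = ModelSpec.from_config(spec.to_config())
        assert again.L == 2.5 and again.F_cilia == 3.0 and again.state == spec.state

    def test_make_field_dispatch_and_export(self):
        for cfg in (
            {"model": "envelope", "state": "motile"},
            {"model": "sinking", "state": "sinking", "U_sink": 1.0},
            {"model": "stokeslet_sphere", "state": "sessile", "L_over_a": 2.0, "F_cilia": 1.0},
        ):
            field = make_field(ModelSpec.from_config(cfg))
            frame = field_to_frame(field, [1.5, 2.0], np.linspace(0.1, 3.0, 5))
            assert list(frame.columns) == ["r", "theta", "u_r", "u_theta"]
            assert len(frame) == 10 and np.isfinite(frame.to_numpy()).all()
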