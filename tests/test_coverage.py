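"""Banded cilia coverage and partial absorption."""

import math

import numpy as np
import pytest

from ciliaflow.coverage import (
    ModeSpectrum,
    SurfaceBand,
    multimode_flow,
    project_slip,
    sh_partial,
)
from ciliaflow.flow_models import EnvelopeField, ParameterError, legendre_deriv_table
from ciliaflow.transport import Grid, solve_sherwood


class TestSurfaceBand:
    def test_named_placements_cover_half_the_sphere(self):
        for name in ("front", "middle", "back"):
            band = SurfaceBand.named("coverage", name)
            assert band.area_fraction == pytest.approx(0.5)
        assert SurfaceBand.named("coverage", "full").area_fraction == pytest.approx(1.0)

    def test_mask_orientation(self):
        theta = np.linspace(0, math.pi, 11)
        front = SurfaceBand.named("absorption", "front").mask(theta)
        assert front[0] and not front[-1]  # theta = 0 is the leading pole

    def test_invalid_bands(self):
        with pytest.raises(ParameterError):
            SurfaceBand("coverage", 0.5, 0.5)
        with pytest.raises(ParameterError):
            SurfaceBand.named("coverage", "sideways")


class TestProjection:
    def test_full_coverage_is_pure_b1(self):
        spec = project_slip(SurfaceBand.named("coverage", "full"), 1.0, 64)
        assert spec.B[1] == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(spec.B[2:])) < 1e-12

    def test_vanishing_band_projects_to_zero(self):
        spec = project_slip(SurfaceBand("coverage", 0.3, 0.3 + 1e-12), 1.0, 16)
        assert np.max(np.abs(spec.B)) < 1e-10

    def test_front_band_matches_least_squares_oracle(self):
        """Dense weighted least squares (piecewise Gauss nodes, sin(theta)
        inner product) must agree with the Galerkin projection."""
        from numpy.polynomial.legendre import leggauss
        N = 64
        spec = project_slip(SurfaceBand.named("coverage", "front"), 1.0, N)
        nodes, weights = leggauss(1000)
        mus, ws, target = [], [], []
        for lo, hi, absorbing in ((-1.0, 0.0, False), (0.0, 1.0, True)):
            mu = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
            w = 0.5 * (hi - lo) * weights
            mus.append(mu)
            ws.append(w)
            target.append(np.sqrt(1 - mu**2) if absorbing else np.zeros_like(mu))
        mu = np.concatenate(mus)
        w = np.concatenate(ws)
        target = np.concatenate(target)
        dp = legendre_deriv_table(mu, N)
        sin = np.sqrt(1 - mu**2)
        design = np.array([2.0 / (n * (n + 1)) * sin * dp[n] for n in range(1, N + 1)]).T
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], target * sw, rcond=None)
        np.testing.assert_allclose(coef, spec.B[1:], atol=1e-6)

    def test_projection_requires_enough_modes(self):
        with pytest.raises(ParameterError):
            project_slip(SurfaceBand.named("coverage", "front"), 1.0, 4)


class TestMultimodeFlow:
    def test_pure_b1_reduces_to_envelope(self):
        B = np.zeros(65)
        B[1] = 1.0
        flow = multimode_flow(ModeSpectrum(B=B), "motile")
        env = EnvelopeField("motile")
        rr, tt = np.meshgrid(np.linspace(1, 6, 8), np.linspace(0, math.pi, 9), indexing="ij")
        u1 = flow.velocity(rr, tt)
        u2 = env.velocity(rr, tt)
        assert np.max(np.abs(u1[0] - u2[0])) < 1e-10
        assert np.max(np.abs(u1[1] - u2[1])) < 1e-10
        assert flow.U == pytest.approx(2 / 3)

    def test_swimming_speed_set_by_b1_alone(self):
        rng = np.random.default_rng(3)
        B = np.zeros(33)
        B[1] = 0.4
        B[2:] = rng.normal(0, 0.2, 31)
        flow = multimode_flow(ModeSpectrum(B=B), "motile")
        assert flow.U == pytest.approx(2 * 0.4 / 3)
        # force-free: far field decays faster than the Stokeslet 1/r
        r = np.geomspace(30, 300, 8)
        u_r, u_t = flow.velocity(r, np.full_like(r, 1.0))
        u_r = u_r + flow.U * math.cos(1.0)
        u_t = u_t - flow.U * math.sin(1.0)
        slope = np.polyfit(np.log(r), np.log(np.hypot(u_r, u_t)), 1)[0]
        assert slope < -1.8

    def test_banded_sessile_sphere_is_impermeable(self, theta_grid):
        spec = project_slip(SurfaceBand.named("coverage", "front"), 1.0, 64)
        flow = multimode_flow(spec, "sessile")
        u_r, _ = flow.velocity(np.ones_like(theta_grid), theta_grid)
        assert np.max(np.abs(u_r)) < 1e-8

    def test_slip_reproduced_away_from_band_edges(self):
        spec = project_slip(SurfaceBand.named("coverage", "back"), 1.0, 64)
        flow = multimode_flow(spec, "motile")
        assert flow.bc_residual < 0.1  # Gibbs-limited but bounded
        assert not flow.flagged


class TestPartialAbsorption:
    def test_full_absorption_is_the_reference(self):
        sh, pct = sh_partial(EnvelopeField("sessile"), 0.0, SurfaceBand.named("absorption", "full"))
        assert pct == pytest.approx(100.0, abs=1e-9)

    def test_mode_truncation_stability(self):
        """Sh at Pe = 100 moves by < 1% between N = 64 and N = 128."""
        vals = []
        for n in (64, 128):
            spec = project_slip(SurfaceBand.named("coverage", "front"), 1.0, n)
            vals.append(solve_sherwood(multimode_flow(spec, "sessile"), 100.0).sh)
        assert abs(vals[1] - vals[0]) / vals[0] < 0.01
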