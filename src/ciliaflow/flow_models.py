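"""Axisymmetric Stokes flow around spherical model microorganisms.

Three configurations are covered, each in a sessile (tethered, lab frame)
and/or motile (force-free swimmer, body frame) state:

* ``envelope`` -- the ciliary envelope (squirmer) model: densely packed
  cilia replaced by a tangential slip velocity ``u_theta(a) = U_s sin(theta)``
  on the sphere surface.
* ``stokeslet_sphere`` -- the ciliary crown replaced by a point force
  ``F_cilia`` on the symmetry axis at distance ``L`` from the center,
  pointing toward the cell, with a no-slip sphere.
* ``sinking`` -- a rigid no-slip sphere settling at speed ``U_sink``.

Everything is nondimensional: sphere radius ``a = 1``, viscosity
``eta = 1``, and slip-velocity scale ``U_s = 1`` unless stated otherwise.
The symmetry axis is z; the point force sits at ``z = +L`` and points in
``-z``, so the feeding current runs front (theta = 0) to back (theta = pi).

Fields are exact solutions of the Stokes equations built from stream
functions separated in Gegenbauer functions ``G_m(mu) = (P_{m-2}(mu) -
P_m(mu)) / (2m - 1)``; the decaying radial solutions for mode ``m`` are
``r**(1-m)`` and ``r**(3-m)`` (the latter is the Stokeslet for ``m = 2``,
admissible only when a net tether force is present).
"""

from __future__ import annotations

import dataclasses
import enum
import io
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelKind",
    "State",
    "Frame",
    "ModelSpec",
    "VelocityField",
    "EnvelopeField",
    "SinkingField",
    "StokesletSphereField",
    "envelope_velocity",
    "stokeslet_sphere_velocity",
    "sinking_velocity",
    "calibrate_swimming_speed",
    "make_field",
    "field_to_frame",
    "legendre_table",
    "legendre_deriv_table",
    "DomainError",
    "ParameterError",
    "SingularityError",
    "TruncationError",
]

SINGULARITY_GUARD = 1e-6  # exclusion radius around the point force, units of a


class DomainError(ValueError):
    """Evaluation point outside the fluid domain (r < a)."""


class ParameterError(ValueError):
    """Physically invalid model parameter."""


class SingularityError(ValueError):
    """Evaluation within the guard radius of the point force."""

    def __init__(self, r: float, theta: float):
        self.point = (r, theta)
        super().__init__(
            f"evaluation point (r={r!r}, theta={theta!r}) lies within "
            f"{SINGULARITY_GUARD:g}a of the Stokeslet singularity"
        )


class TruncationError(RuntimeError):
    """Series truncation failed to meet the boundary-residual tolerance."""

    def __init__(self, residual: float, n_modes: int, tol: float):
        self.residual = residual
        self.n_modes = n_modes
        super().__init__(
            f"boundary residual {residual:.3e} exceeds tol {tol:.1e} "
            f"at maximum truncation N={n_modes}"
        )


class ModelKind(str, enum.Enum):
    STOKESLET_SPHERE = "stokeslet_sphere"
    ENVELOPE = "envelope"
    SINKING = "sinking"


class State(str, enum.Enum):
    SESSILE = "sessile"
    MOTILE = "motile"
    SINKING = "sinking"


class Frame(str, enum.Enum):
    LAB = "lab"
    BODY = "body"


# ---------------------------------------------------------------------------
# Legendre / Gegenbauer utilities
# ---------------------------------------------------------------------------

def legendre_table(mu: np.ndarray, nmax: int) -> np.ndarray:
    """Legendre polynomials P_n(mu) for n = 0..nmax via upward recurrence.

    Returns an array of shape ``(nmax + 1,) + mu.shape``.
    """
    mu = np.asarray(mu, dtype=float)
    out = np.empty((nmax + 1,) + mu.shape)
    out[0] = 1.0
    if nmax >= 1:
        out[1] = mu
    for n in range(1, nmax):
        out[n + 1] = ((2 * n + 1) * mu * out[n] - n * out[n - 1]) / (n + 1)
    return out


def legendre_deriv_table(mu: np.ndarray, nmax: int) -> np.ndarray:
    """Derivatives P'_n(mu), n = 0..nmax, via P'_{n+1} = P'_{n-1} + (2n+1) P_n."""
    mu = np.asarray(mu, dtype=float)
    p = legendre_table(mu, max(nmax - 1, 0))
    out = np.zeros((nmax + 1,) + mu.shape)
    if nmax >= 1:
        out[1] = 1.0
    for n in range(1, nmax):
        out[n + 1] = out[n - 1] + (2 * n + 1) * p[n]
    return out


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelSpec:
    """Which organism model, its state, and its physical parameters.

    All lengths are in units of the cell radius ``a`` and all speeds in
    units of the slip-velocity scale; ``eta = 1``.
    """

    kind: ModelKind
    state: State
    a: float = 1.0
    L: float | None = None            # point-force location (stokeslet_sphere)
    F_cilia: float | None = None      # point-force magnitude; None => calibrated
    slip_amplitude: float = 1.0       # envelope slip scale U_s
    U_sink: float | None = None       # settling speed (sinking only)
    eta: float = 1.0

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)
        self.state = State(self.state)
        if self.kind is ModelKind.STOKESLET_SPHERE:
            if self.L is None or self.L <= self.a:
                raise ParameterError("stokeslet_sphere requires L > a")
            if self.state is State.SINKING:
                raise ParameterError("stokeslet_sphere has no sinking state")
        elif self.kind is ModelKind.ENVELOPE:
            if self.state is State.SINKING:
                raise ParameterError("envelope model has no sinking state")
        elif self.kind is ModelKind.SINKING:
            if self.state is not State.SINKING:
                raise ParameterError("sinking model requires state='sinking'")
            if self.U_sink is None or self.U_sink < 0:
                raise ParameterError("sinking model requires U_sink >= 0")

    # -- flat config mapping -------------------------------------------------
    def to_config(self) -> dict:
        cfg = {"model": self.kind.value, "state": self.state.value}
        if self.kind is ModelKind.STOKESLET_SPHERE:
            cfg["L_over_a"] = self.L / self.a
            if self.F_cilia is not None:
                cfg["F_cilia"] = self.F_cilia
        if self.kind is ModelKind.ENVELOPE:
            cfg["slip_amplitude"] = self.slip_amplitude
        if self.kind is ModelKind.SINKING:
            cfg["U_sink"] = self.U_sink
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ModelSpec":
        kind = ModelKind(cfg["model"])
        state = State(cfg.get("state", "sinking" if kind is ModelKind.SINKING else "sessile"))
        return cls(
            kind=kind,
            state=state,
            L=cfg.get("L_over_a"),
            F_cilia=cfg.get("F_cilia"),
            slip_amplitude=cfg.get("slip_amplitude", 1.0),
            U_sink=cfg.get("U_sink"),
        )


# ---------------------------------------------------------------------------
# Velocity fields
# ---------------------------------------------------------------------------

class VelocityField:
    """Axisymmetric exterior Stokes solution, evaluable at (r, theta).

    ``velocity(r, theta)`` returns ``(u_r, u_theta)`` for ``r >= a``,
    ``theta`` in ``[0, pi]``; ``psi(r, theta)`` returns the Stokes stream
    function. ``frame`` records whether the far field is quiescent (lab)
    or a uniform stream ``-U z_hat`` (body).
    """

    frame: Frame = Frame.LAB
    spec: ModelSpec | None = None
    U: float = 0.0  # translation speed (motile / sinking), 0 for sessile

    def velocity(self, r, theta):
        raise NotImplementedError

    def psi(self, r, theta):
        raise NotImplementedError

    @staticmethod
    def _check_domain(r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        if np.any(r < 1.0 - 1e-12):
            raise DomainError("r < a: evaluation point inside the sphere")
        return r


def _as_angles(theta):
    theta = np.asarray(theta, dtype=float)
    return theta, np.cos(theta), np.sin(theta)


class EnvelopeField(VelocityField):
    """Ciliary-envelope (squirmer) flow, sessile tethered pump or B1 swimmer."""

    def __init__(self, state: State | str = State.MOTILE, slip_amplitude: float = 1.0):
        state = State(state)
        if state is State.SINKING:
            raise ParameterError("envelope model has no sinking state")
        self.state = state
        self.Us = float(slip_amplitude)
        self.U = 2.0 * self.Us / 3.0 if state is State.MOTILE else 0.0
        self.frame = Frame.BODY if state is State.MOTILE else Frame.LAB
        self.spec = ModelSpec(ModelKind.ENVELOPE, state, slip_amplitude=self.Us)

    def velocity(self, r, theta):
        r = self._check_domain(r)
        _, mu, sin = _as_angles(theta)
        if self.state is State.MOTILE:
            U = self.U
            u_r = U * mu * (r ** -3 - 1.0)
            u_t = U * sin * (1.0 + 0.5 * r ** -3)
        else:
            Us = self.Us
            u_r = Us * mu * (r ** -3 - r ** -1)
            u_t = Us * sin * (0.5 * r ** -3 + 0.5 * r ** -1)
        return u_r, u_t

    def psi(self, r, theta):
        r = self._check_domain(r)
        _, mu, sin = _as_angles(theta)
        g2 = 0.5 * sin ** 2
        if self.state is State.MOTILE:
            return self.U * (1.0 / r - r ** 2) * g2
        return self.Us * (1.0 / r - r) * g2


class SinkingField(VelocityField):
    """Stokes flow past a rigid no-slip sphere, body frame (far field -U z)."""

    def __init__(self, U_sink: float):
        if U_sink < 0:
            raise ParameterError("U_sink must be nonnegative")
        self.U = float(U_sink)
        self.frame = Frame.BODY
        self.state = State.SINKING
        self.spec = ModelSpec(ModelKind.SINKING, State.SINKING, U_sink=self.U)

    def velocity(self, r, theta):
        r = self._check_domain(r)
        _, mu, sin = _as_angles(theta)
        U = self.U
        u_r = -U * mu * (1.0 - 1.5 / r + 0.5 * r ** -3)
        u_t = U * sin * (1.0 - 0.75 / r - 0.25 * r ** -3)
        return u_r, u_t

    def psi(self, r, theta):
        r = self._check_domain(r)
        _, mu, sin = _as_angles(theta)
        return -self.U * sin ** 2 * (0.5 * r ** 2 - 0.75 * r + 0.25 / r)


class StokesletSphereField(VelocityField):
    """Point force at z = L (pointing -z) outside a no-slip unit sphere.

    The free-space Stokeslet stream function is cancelled on the sphere
    surface mode-by-mode: expanding ``psi_S`` about the origin in
    Gegenbauer functions gives surface coefficients

        s_m = beta m(m-1) [L^(1-m)/(2m-3) - L^(-1-m)/(2m+1)]
        t_m = beta m(m-1) [m L^(1-m)/(2m-3) - (m+2) L^(-1-m)/(2m+1)]

    (values of psi and of d(psi)/dr at r = 1, beta = -F/(8 pi)), and the
    image ``sum_m (a_m r^(1-m) + b_m r^(3-m)) G_m`` solves the 2x2 system
    that zeroes both. The coefficient ``b_2`` of the image Stokeslet term
    carries the force the sphere exerts on the fluid, ``4 pi b_2``, from
    which the force-balance swimming speed follows.

    Motile state: the sessile solution plus rigid-sphere flow past the
    sphere at the force-balance speed U (body frame).
    """

    MAX_MODES = 512

    def __init__(
        self,
        L: float,
        F: float | None = None,
        state: State | str = State.SESSILE,
        n_modes: int = 64,
        bc_tol: float = 1e-8,
    ):
        state = State(state)
        if state is State.SINKING:
            raise ParameterError("stokeslet_sphere has no sinking state")
        if L <= 1.0:
            raise ParameterError("point force must lie outside the sphere (L > a)")
        self.L = float(L)
        if F is None:
            # calibrate to the envelope model's swimming speed U = 2/3
            F = calibrate_swimming_speed("stokeslet_sphere", L=L, U_target=2.0 / 3.0).F_cilia
        self.F = float(F)
        self.state = state
        self.frame = Frame.BODY if state is State.MOTILE else Frame.LAB
        self.bc_tol = bc_tol
        self.spec = ModelSpec(ModelKind.STOKESLET_SPHERE, state, L=self.L, F_cilia=self.F)

        n = max(8, n_modes)
        while True:
            self._assemble(n)
            if self.boundary_residual <= bc_tol * max(1.0, abs(self.F)):
                break
            if n >= self.MAX_MODES:
                raise TruncationError(self.boundary_residual, n, bc_tol)
            n = min(2 * n, self.MAX_MODES)
        self.n_modes = n

        # force balance: fluid pushes the organism +z through the cilia (+F),
        # the sphere feels -4*pi*b2 from the image system; Stokes drag closes it.
        self.sphere_force = -4.0 * math.pi * self.b[2]
        self.U = (self.F + self.sphere_force) / (6.0 * math.pi) if state is State.MOTILE else 0.0
        self._carrier = SinkingField(self.U) if state is State.MOTILE else None

    # -- series assembly -----------------------------------------------------
    def _assemble(self, n_modes: int) -> None:
        beta = -self.F / (8.0 * math.pi)
        L = self.L
        m = np.arange(2, n_modes + 1, dtype=float)
        pref = beta * m * (m - 1.0)
        lo = L ** (1.0 - m) / (2.0 * m - 3.0)
        hi = L ** (-1.0 - m) / (2.0 * m + 1.0)
        s = pref * (lo - hi)
        t = pref * (m * lo - (m + 2.0) * hi)
        b = ((1.0 - m) * s - t) / 2.0
        a = -s - b
        # store with index == Gegenbauer order
        self.a = np.zeros(n_modes + 1)
        self.b = np.zeros(n_modes + 1)
        self.a[2:] = a
        self.b[2:] = b
        theta = np.linspace(0.0, math.pi, 361)
        u_r, u_t = self._eval_no_carrier(np.ones_like(theta), theta)
        self.boundary_residual = float(max(np.max(np.abs(u_r)), np.max(np.abs(u_t))))

    # -- evaluation ----------------------------------------------------------
    def _stokeslet_free(self, r, mu, sin):
        """Free-space Stokeslet at z = L, force -F z_hat, in (r, theta) about origin."""
        beta = -self.F / (8.0 * math.pi)
        R2 = r ** 2 + self.L ** 2 - 2.0 * self.L * r * mu
        R = np.sqrt(R2)
        u_r = -beta * (-2.0 * mu / R + (1.0 - mu ** 2) * self.L * r / R ** 3)
        dpsi_dr = beta * (1.0 - mu ** 2) * (2.0 * r / R - r ** 2 * (r - self.L * mu) / R ** 3)
        with np.errstate(divide="ignore", invalid="ignore"):
            u_t = np.where(sin > 0.0, -dpsi_dr / (r * np.where(sin > 0, sin, 1.0)), 0.0)
        return u_r, u_t

    def _image(self, r, mu, sin):
        nmax = len(self.a) - 1
        p = legendre_table(mu, nmax - 1)
        dp = legendre_deriv_table(mu, nmax - 1)
        u_r = np.zeros_like(r)
        u_t = np.zeros_like(r)
        for m in range(2, nmax + 1):
            am, bm = self.a[m], self.b[m]
            if am == 0.0 and bm == 0.0:
                continue
            psi_m = am * r ** (1 - m) + bm * r ** (3 - m)
            dpsi_m = am * (1 - m) * r ** (-m) + bm * (3 - m) * r ** (2 - m)
            n = m - 1
            u_r += psi_m / r ** 2 * p[n]
            # G_m(mu)/sin(theta) = sin(theta) P'_n(mu) / (n (n+1))
            u_t += -dpsi_m / r * sin * dp[n] / (n * (n + 1))
        return u_r, u_t

    def _eval_no_carrier(self, r, theta):
        _, mu, sin = _as_angles(theta)
        u1 = self._stokeslet_free(r, mu, sin)
        u2 = self._image(r, mu, sin)
        return u1[0] + u2[0], u1[1] + u2[1]

    def _guard(self, r, theta):
        r = np.asarray(r, float)
        theta = np.asarray(theta, float)
        d2 = r ** 2 + self.L ** 2 - 2.0 * self.L * r * np.cos(theta)
        bad = d2 < SINGULARITY_GUARD ** 2
        if np.any(bad):
            idx = np.unravel_index(np.argmax(bad), np.shape(bad)) if np.ndim(bad) else ()
            rb = float(np.asarray(r)[idx]) if np.ndim(r) else float(r)
            tb = float(np.asarray(theta)[idx]) if np.ndim(theta) else float(theta)
            raise SingularityError(rb, tb)

    def velocity(self, r, theta):
        r = self._check_domain(r)
        self._guard(r, theta)
        r, theta = np.broadcast_arrays(np.asarray(r, float), np.asarray(theta, float))
        u_r, u_t = self._eval_no_carrier(r, theta)
        if self._carrier is not None:
            c_r, c_t = self._carrier.velocity(r, theta)
            u_r = u_r + c_r
            u_t = u_t + c_t
        return u_r, u_t

    def psi(self, r, theta):
        r = self._check_domain(r)
        self._guard(r, theta)
        r, theta = np.broadcast_arrays(np.asarray(r, float), np.asarray(theta, float))
        _, mu, sin = _as_angles(theta)
        beta = -self.F / (8.0 * math.pi)
        R = np.sqrt(r ** 2 + self.L ** 2 - 2.0 * self.L * r * mu)
        out = beta * r ** 2 * (1.0 - mu ** 2) / R
        nmax = len(self.a) - 1
        p = legendre_table(mu, nmax)
        for m in range(2, nmax + 1):
            g_m = (p[m - 2] - p[m]) / (2 * m - 1)
            out += (self.a[m] * r ** (1 - m) + self.b[m] * r ** (3 - m)) * g_m
        if self._carrier is not None:
            out += self._carrier.psi(r, theta)
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def envelope_velocity(spec: ModelSpec, r, theta):
    """(u_r, u_theta) of the envelope model described by ``spec`` at (r, theta)."""
    if ModelKind(spec.kind) is not ModelKind.ENVELOPE:
        raise ParameterError("spec.kind must be 'envelope'")
    return EnvelopeField(spec.state, spec.slip_amplitude).velocity(r, theta)


def stokeslet_sphere_velocity(spec: ModelSpec, r, theta, **field_kwargs):
    """(u_r, u_theta) of the Stokeslet-sphere model described by ``spec``."""
    if ModelKind(spec.kind) is not ModelKind.STOKESLET_SPHERE:
        raise ParameterError("spec.kind must be 'stokeslet_sphere'")
    fld = StokesletSphereField(spec.L, spec.F_cilia, spec.state, **field_kwargs)
    return fld.velocity(r, theta)


def sinking_velocity(U_sink: float, r, theta):
    """(u_r, u_theta) of Stokes flow past a no-slip sphere sinking at U_sink."""
    return SinkingField(U_sink).velocity(r, theta)


@dataclasses.dataclass
class Calibration:
    U: float
    F_cilia: float | None = None
    alpha: float | None = None  # mobility U / F for the stokeslet model


def calibrate_swimming_speed(
    kind: ModelKind | str,
    *,
    slip_amplitude: float = 1.0,
    L: float | None = None,
    F: float | None = None,
    U_target: float | None = None,
) -> Calibration:
    """Force-balance swimming speed of the motile models.

    envelope: U = 2 U_s / 3 exactly (B1 squirmer).

    stokeslet_sphere: the sphere carries the cilia reaction +F z_hat and is
    advected by the ambient Stokeslet; the image-Stokeslet coefficient of the
    exact series gives the mobility

        alpha(L) = U / F = (1 - 3a/(2L) + a^3/(2L^3)) / (6 pi eta a),

    which tends to the bare Stokes mobility 1/(6 pi eta a) as L/a grows.
    Supply ``F`` to get U, or ``U_target`` to get the force achieving it.
    """
    kind = ModelKind(kind)
    if kind is ModelKind.ENVELOPE:
        return Calibration(U=2.0 * slip_amplitude / 3.0)
    if kind is ModelKind.SINKING:
        raise ParameterError("sinking speed is a free parameter, not calibrated")
    if L is None or L <= 1.0:
        raise ParameterError("stokeslet_sphere calibration requires L > a")
    # b2 of the image series at unit force (closed form of the mode-2 solve)
    beta = -1.0 / (8.0 * math.pi)
    s2 = beta * 2.0 * (1.0 / L - 1.0 / (5.0 * L ** 3))
    t2 = beta * 2.0 * (2.0 / L - 4.0 / (5.0 * L ** 3))
    b2 = (-s2 - t2) / 2.0
    alpha = (1.0 - 4.0 * math.pi * b2) / (6.0 * math.pi)
    if U_target is not None:
        return Calibration(U=U_target, F_cilia=U_target / alpha, alpha=alpha)
    if F is None:
        F = 1.0
    return Calibration(U=alpha * F, F_cilia=F, alpha=alpha)


def make_field(spec: ModelSpec, **kwargs) -> VelocityField:
    """Instantiate the velocity field for a model specification."""
    kind = ModelKind(spec.kind)
    if kind is ModelKind.ENVELOPE:
        return EnvelopeField(spec.state, spec.slip_amplitude)
    if kind is ModelKind.SINKING:
        return SinkingField(spec.U_sink)
    return StokesletSphereField(spec.L, spec.F_cilia, spec.state, **kwargs)


def field_to_frame(field: VelocityField, r: Sequence[float], theta: Sequence[float]) -> pd.DataFrame:
    """Evaluate a field on the tensor grid r x theta as a tidy DataFrame."""
    rr, tt = np.meshgrid(np.asarray(r, float), np.asarray(theta, float), indexing="ij")
    u_r, u_t = field.velocity(rr, tt)
    return pd.DataFrame(
        {
            "r": rr.ravel(),
            "theta": tt.ravel(),
            "u_r": np.asarray(u_r).ravel(),
            "u_theta": np.asarray(u_t).ravel(),
        }
    )
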