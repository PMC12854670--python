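"""Feeding metrics: annular clearance rate and sessile-vs-motile differences.

The clearance rate is the volumetric fluid flux through an annular
"encounter zone" in the equatorial plane, extending from the cell surface
out to radius R:

    Q = -2 pi * integral_a^R  u . e_z |_{z=0}  rho  d(rho),

normalized by the advective flux ``pi R^2 U`` with U the matched swimming
speed (2/3 in dimensionless units). Positive Q counts flux in the
feeding-current direction (front-to-back, -z); on the equatorial plane
``u . e_z = -u_theta``.

``delta_sweep`` produces the paired sessile/motile tables for either
metric (Q over a point-force-location sweep, Sh over a Pe sweep), with
identical grids for the paired states so the differences are clean.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .flow_models import (
    EnvelopeField,
    ModelKind,
    ParameterError,
    StokesletSphereField,
    VelocityField,
    calibrate_swimming_speed,
    make_field,
)
from . import transport

__all__ = ["ClearanceResult", "clearance_rate", "delta_sweep", "delta_sh_sign_change"]

#: matched swimming speed used to normalize Q for sessile and motile alike
U_MATCHED = 2.0 / 3.0


@dataclasses.dataclass
class ClearanceResult:
    Q_normalized: float
    Q: float
    R: float
    U_ref: float
    quadrature_error: float
    spec: object = None


def clearance_rate(
    field: VelocityField,
    R: float = 1.1,
    U_ref: float = U_MATCHED,
) -> ClearanceResult:
    """Clearance rate through the equatorial annulus rho in [a, R].

    Sessile fields are integrated in the lab frame and motile ones in the
    body frame (whatever frame the field carries); both are normalized by
    ``pi R^2 U_ref`` with the same matched speed, following the definition
    of the advective reference flux.
    """
    if R <= 1.0:
        raise ParameterError("encounter radius must exceed the cell radius")

    def integrand(rho: float) -> float:
        # u . e_z at theta = pi/2 is -u_theta; Q carries another minus sign
        _, u_t = field.velocity(rho, math.pi / 2.0)
        return float(u_t) * rho

    val, err = quad(integrand, 1.0, R, limit=200, epsabs=1e-12, epsrel=1e-10)
    if err > 1e-6 * max(abs(val), 1e-12):
        raise RuntimeError(f"clearance quadrature did not converge (err={err:.2e})")
    Q = 2.0 * math.pi * val
    return ClearanceResult(
        Q_normalized=Q / (math.pi * R**2 * U_ref),
        Q=Q,
        R=R,
        U_ref=U_ref,
        quadrature_error=err,
        spec=getattr(field, "spec", None),
    )


def _paired_fields(kind: ModelKind, L: float | None):
    """Sessile/motile field pair sharing one calibrated cilia force."""
    kind = ModelKind(kind)
    if kind is ModelKind.ENVELOPE:
        return EnvelopeField("sessile"), EnvelopeField("motile")
    cal = calibrate_swimming_speed(kind, L=L, U_target=U_MATCHED)
    return (
        StokesletSphereField(L, cal.F_cilia, "sessile"),
        StokesletSphereField(L, cal.F_cilia, "motile"),
    )


def delta_sweep(
    kind: ModelKind | str,
    variable: str,
    values: Sequence[float],
    R: float = 1.1,
    pe: float = 100.0,
    L: float | None = None,
) -> pd.DataFrame:
    """Paired sessile/motile metric sweep.

    ``variable='L_over_a'``: clearance rate Q (at encounter radius R) and,
    via ``pe``, Sherwood number, swept over point-force locations of the
    Stokeslet-sphere model. ``variable='Pe'``: Sherwood number swept over
    Peclet numbers for a fixed configuration (envelope, or Stokeslet at
    ``L``). Sessile and motile states share the calibrated force, the
    transport grid, and the series truncation at every sweep point.
    """
    values = list(values)
    if not values:
        raise ParameterError("sweep values must be nonempty")
    kind = ModelKind(kind)
    rows = []
    if variable == "L_over_a":
        if kind is not ModelKind.STOKESLET_SPHERE:
            raise ParameterError("L_over_a sweeps apply to the stokeslet_sphere model")
        for L_val in values:
            sess, mot = _paired_fields(kind, float(L_val))
            qs = clearance_rate(sess, R).Q_normalized
            qm = clearance_rate(mot, R).Q_normalized
            rows.append(
                {
                    "model": kind.value,
                    "variable": "L_over_a",
                    "value": float(L_val),
                    "Q_sessile": qs,
                    "Q_motile": qm,
                    "dQ": qm - qs,
                    "Sh_sessile": np.nan,
                    "Sh_motile": np.nan,
                    "dSh": np.nan,
                }
            )
    elif variable == "Pe":
        sess, mot = _paired_fields(kind, L)
        for pe_val in values:
            grid = transport.Grid.auto(float(pe_val))
            shs = transport.solve_sherwood(sess, float(pe_val), grid).sh
            shm = transport.solve_sherwood(mot, float(pe_val), grid).sh
            qs = clearance_rate(sess, R).Q_normalized
            qm = clearance_rate(mot, R).Q_normalized
            rows.append(
                {
                    "model": kind.value,
                    "variable": "Pe",
                    "value": float(pe_val),
                    "Q_sessile": qs,
                    "Q_motile": qm,
                    "dQ": qm - qs,
                    "Sh_sessile": shs,
                    "Sh_motile": shm,
                    "dSh": shm - shs,
                }
            )
    else:
        raise ParameterError("variable must be 'L_over_a' or 'Pe'")
    return pd.DataFrame.from_records(rows)


def delta_sh_sign_change(
    L_values: Sequence[float],
    pe: float = 100.0,
) -> tuple[float, pd.DataFrame]:
    """Locate the zero crossing of dSh(L) = Sh_motile - Sh_sessile.

    Returns ``((L*-a)/a, table)``; the location is NaN when dSh keeps one
    sign across the sweep.
    """
    rows = []
    for L_val in L_values:
        sess, mot = _paired_fields(ModelKind.STOKESLET_SPHERE, float(L_val))
        grid = transport.Grid.auto(pe)
        shs = transport.solve_sherwood(sess, pe, grid).sh
        shm = transport.solve_sherwood(mot, pe, grid).sh
        rows.append({"L_over_a": float(L_val), "Sh_sessile": shs, "Sh_motile": shm, "dSh": shm - shs})
    table = pd.DataFrame.from_records(rows).sort_values("L_over_a", ignore_index=True)
    d = table["dSh"].to_numpy()
    Lg = table["L_over_a"].to_numpy()
    sign_change = np.nonzero(np.diff(np.sign(d)) != 0)[0]
    if len(sign_change) == 0:
        return float("nan"), table
    i = sign_change[0]
    # linear interpolation of the crossing
    L_star = Lg[i] + (Lg[i + 1] - Lg[i]) * (0.0 - d[i]) / (d[i + 1] - d[i])
    return float(L_star - 1.0), table
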