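"""Asymptotic Sherwood expressions and scaling-exponent fits.

For the sessile envelope (tethered pump) the closed forms are

    Pe << 1:  Sh = 1 + (43/720) Pe^2
    Pe >> 1:  Sh = (2 / sqrt(3 pi)) Pe^(1/2)

The module also provides log-log least-squares fits of scaling exponents
from numerical Sh(Pe) data (slope of log(Sh - 1) vs log Pe at small Pe,
log Sh vs log Pe at large Pe), and Richardson-extrapolation helpers that
anchor the transport solver against the closed forms: the small-Pe
quadratic coefficient is recovered from solves at Pe in {0.5, 1} on
domains of 300a and 600a (the advective correction at small Pe is set by
an outer region of extent ~a/Pe, so the leading domain-truncation error
scales like 1/R and is removed by extrapolation over the two domains).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

from .flow_models import EnvelopeField, ParameterError, VelocityField
from .transport import Grid, shifted_sherwood, solve_sherwood

__all__ = [
    "LARGE_PE_PREFACTOR",
    "SMALL_PE_COEFF",
    "sh_sessile_asymptotic",
    "fit_scaling_exponent",
    "ScalingFit",
    "small_pe_quadratic_coefficient",
    "large_pe_prefactor",
]

SMALL_PE_COEFF = 43.0 / 720.0
LARGE_PE_PREFACTOR = 2.0 / math.sqrt(3.0 * math.pi)

#: default regime windows for exponent fits (caller-overridable)
SMALL_PE_WINDOW = (0.0, 1.0)
LARGE_PE_WINDOW = (300.0, math.inf)


def sh_sessile_asymptotic(pe: float, regime: str):
    """Closed-form sessile-envelope Sherwood number in the given regime.

    ``regime`` is 'small_Pe' or 'large_Pe'; no automatic switching.
    """
    pe = np.asarray(pe, dtype=float)
    if np.any(pe < 0):
        raise ParameterError("Pe must be nonnegative")
    if regime == "small_Pe":
        out = 1.0 + SMALL_PE_COEFF * pe**2
    elif regime == "large_Pe":
        out = LARGE_PE_PREFACTOR * np.sqrt(pe)
    else:
        raise ParameterError("regime must be 'small_Pe' or 'large_Pe'")
    return out if out.ndim else float(out)


@dataclasses.dataclass
class ScalingFit:
    exponent: float
    prefactor: float
    exponent_stderr: float
    prefactor_stderr: float
    n_points: int
    regime: str


def fit_scaling_exponent(
    pe_values: Sequence[float],
    sh_values: Sequence[float],
    regime: str,
) -> ScalingFit:
    """Least-squares power-law fit of numerical Sh(Pe) data.

    small_Pe: fits log(Sh - 1) = log A + p log Pe (points with Sh <= 1 are
    excluded with a warning); large_Pe: fits log Sh = log A + p log Pe.
    """
    pe = np.asarray(pe_values, dtype=float)
    sh = np.asarray(sh_values, dtype=float)
    if regime == "small_Pe":
        y = sh - 1.0
        keep = (y > 0) & (pe > 0)
        if np.any(~keep):
            warnings.warn(
                f"excluding {int(np.sum(~keep))} points with Sh <= 1 or Pe = 0 "
                "from the small-Pe fit",
                stacklevel=2,
            )
        pe, y = pe[keep], y[keep]
    elif regime == "large_Pe":
        y = sh
    else:
        raise ParameterError("regime must be 'small_Pe' or 'large_Pe'")
    if len(pe) < 3:
        raise ParameterError("need at least 3 usable points for a scaling fit")
    res = stats.linregress(np.log(pe), np.log(y))
    prefactor = math.exp(res.intercept)
    return ScalingFit(
        exponent=float(res.slope),
        prefactor=prefactor,
        exponent_stderr=float(res.stderr),
        prefactor_stderr=prefactor * float(res.intercept_stderr),
        n_points=len(pe),
        regime=regime,
    )


def small_pe_quadratic_coefficient(
    field: VelocityField | None = None,
    pe_values: tuple[float, float] = (0.5, 1.0),
    domains: tuple[float, float] = (300.0, 600.0),
) -> float:
    """Quadratic coefficient of (Sh - 1) in Pe from the transport solver.

    Runs the four solves (two Pe, two domains), removes the O(1/R) domain
    truncation by Richardson extrapolation over the two domains, then the
    O(Pe^2) correction to the coefficient by extrapolation over the two Pe
    values. The flow-induced shift Sh(Pe) - Sh(0) is computed on a shared
    grid per solve so discretization bias cancels.
    """
    if field is None:
        field = EnvelopeField("sessile")
    r1, r2 = domains
    if not (r2 > r1):
        raise ParameterError("domains must be increasing")
    shift = {}
    for pe in pe_values:
        for r_inf in domains:
            grid = Grid.auto(pe, r_inf=r_inf)
            shift[(pe, r_inf)] = shifted_sherwood(field, pe, grid)
    w = r1 / (r2 - r1)  # Richardson weight for error ~ 1/R
    coeff = []
    for pe in pe_values:
        extrap = (1.0 + w) * shift[(pe, r2)] - w * shift[(pe, r1)]
        coeff.append(extrap / pe**2)
    p1, p2 = pe_values
    # coefficient(Pe) = A + B Pe^2 + ...; eliminate the Pe^2 term
    ratio = (p2 / p1) ** 2
    return float((ratio * coeff[0] - coeff[1]) / (ratio - 1.0))


def large_pe_prefactor(
    field: VelocityField | None = None,
    pe_values: Sequence[float] = (500.0, 1000.0),
) -> float:
    """Fitted prefactor of Sh * Pe^(-1/2) at large Pe (exponent held at 1/2)."""
    if field is None:
        field = EnvelopeField("sessile")
    vals = [solve_sherwood(field, pe).sh / math.sqrt(pe) for pe in pe_values]
    return float(np.mean(vals))
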