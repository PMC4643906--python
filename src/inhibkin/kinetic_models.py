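"""Closed-form enzyme-kinetics and concentration-response equations.

These are the velocity laws every other stage of the package simulates from
or fits to: the Michaelis-Menten hyperbola, the linear mixed-inhibition model
(with its pure-competitive limit), the four-parameter logistic used for
pIC50/IC50 potency estimation, and the straight-line coefficients of the
Dixon plot (1/v against inhibitor concentration at fixed substrate).

Units
-----
All concentrations are in micromolar (uM). pIC50 is defined on the molar
scale, so the IC50 conversion is ``IC50_uM = 10**(6 - pIC50)``. Velocity
units are arbitrary but must be consistent; Vmax absorbs the scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMParameters",
    "InhibitionParameters",
    "PotencyParameters",
    "mm_velocity",
    "mixed_inhibition_velocity",
    "competitive_velocity",
    "four_pl_response",
    "pic50_to_ic50_uM",
    "ic50_uM_to_pic50",
    "dixon_line_coefficients",
    "two_inhibitor_velocity",
]


class InvalidParameterError(ValueError):
    """A kinetic or potency parameter is outside its physical domain."""


@dataclass(frozen=True)
class MMParameters:
    """Michaelis-Menten parameters.

    Parameters
    ----------
    Km : float
        Substrate concentration at half-maximal velocity (uM). Must be > 0.
    Vmax : float
        Maximal velocity, in arbitrary but consistent signal units per unit
        time. Must be > 0.
    """

    Km: float
    Vmax: float

    def __post_init__(self) -> None:
        if not (self.Km > 0):
            raise InvalidParameterError(f"Km must be > 0, got {self.Km}")
        if not (self.Vmax > 0):
            raise InvalidParameterError(f"Vmax must be > 0, got {self.Vmax}")


@dataclass(frozen=True)
class InhibitionParameters:
    """Reversible-inhibition parameters for the linear mixed model.

    Parameters
    ----------
    Ki : float
        Inhibition constant of the enzyme-inhibitor complex (uM). Must be > 0.
    alpha : float
        Cooperativity factor of the mixed model (dimensionless). ``alpha = 1``
        is pure noncompetitive, ``alpha -> inf`` pure competitive. Ignored
        (treated as infinite) when ``mode == "competitive"``.
    mode : {"mixed", "competitive"}
        Which velocity law applies.
    """

    Ki: float
    alpha: float = math.inf
    mode: str = "mixed"

    def __post_init__(self) -> None:
        if self.mode not in ("mixed", "competitive"):
            raise InvalidParameterError(f"unknown inhibition mode {self.mode!r}")
        if not (self.Ki > 0):
            raise InvalidParameterError(f"Ki must be > 0, got {self.Ki}")
        if self.mode == "mixed" and not (self.alpha > 0):
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class PotencyParameters:
    """Four-parameter logistic (4PL) concentration-response parameters.

    ``pIC50`` is -log10 of the molar IC50; ``hill_slope`` is the Hill
    coefficient n_H; ``top`` and ``bottom`` are the responses (% of control)
    at zero and saturating inhibitor.
    """

    pIC50: float
    hill_slope: float = 1.0
    top: float = 100.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if not (self.top > self.bottom):
            raise InvalidParameterError(
                f"top ({self.top}) must exceed bottom ({self.bottom})"
            )
        if not math.isfinite(self.hill_slope) or self.hill_slope == 0:
            raise InvalidParameterError(
                f"hill_slope must be finite and nonzero, got {self.hill_slope}"
            )

    @property
    def ic50_uM(self) -> float:
        return pic50_to_ic50_uM(self.pIC50)


def mm_velocity(S, p: MMParameters):
    """Michaelis-Menten velocity v = Vmax / (1 + Km/S).

    ``S = 0`` returns 0 (a blank well), not an error. Accepts scalars or
    arrays of substrate concentration (uM).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise InvalidParameterError("substrate concentration must be >= 0")
    with np.errstate(divide="ignore"):
        v = np.where(S > 0, p.Vmax / (1.0 + p.Km / np.where(S > 0, S, 1.0)), 0.0)
    return v if v.ndim else float(v)


def mixed_inhibition_velocity(S, I, p: MMParameters, q: InhibitionParameters):
    """Velocity under linear mixed inhibition.

    The observed velocity is the Michaelis-Menten form with apparent
    constants::

        v       = Vmax_app / (1 + Km_app / S)
        Vmax_app = Vmax / (1 + I / (alpha * Ki))
        Km_app   = Km * (1 + I / Ki) / (1 + I / (alpha * Ki))

    ``mode == "competitive"`` delegates to :func:`competitive_velocity`
    (the alpha -> infinity limit).
    """
    if q.mode == "competitive":
        return competitive_velocity(S, I, p, q.Ki)
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise InvalidParameterError("inhibitor concentration must be >= 0")
    denom_v = 1.0 + I / (q.alpha * q.Ki)
    vmax_app = p.Vmax / denom_v
    km_app = p.Km * (1.0 + I / q.Ki) / denom_v
    with np.errstate(divide="ignore"):
        v = np.where(S > 0, vmax_app / (1.0 + km_app / np.where(S > 0, S, 1.0)), 0.0)
    return v if v.ndim else float(v)


def competitive_velocity(S, I, p: MMParameters, Ki: float):
    """Velocity under pure competitive inhibition: v = Vmax / (1 + (Km/S)(1 + I/Ki))."""
    if not (Ki > 0):
        raise InvalidParameterError(f"Ki must be > 0, got {Ki}")
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise InvalidParameterError("inhibitor concentration must be >= 0")
    with np.errstate(divide="ignore"):
        v = np.where(
            S > 0,
            p.Vmax / (1.0 + (p.Km / np.where(S > 0, S, 1.0)) * (1.0 + I / Ki)),
            0.0,
        )
    return v if v.ndim else float(v)


def two_inhibitor_velocity(
    S, I1, I2, p: MMParameters, K1: float, K2: float, beta: float = math.inf
):
    """Velocity with two competitive inhibitors present simultaneously.

    v = Vmax / (1 + (Km/S) * (1 + I1/K1 + I2/K2 + I1*I2/(beta*K1*K2)))

    ``beta = inf`` removes the product term: the inhibitors are mutually
    exclusive and the Dixon lines of 1/v vs I1 are parallel across I2
    levels. Finite ``beta`` lets both bind at once (cooperatively for small
    beta), making the slope in I1 grow with I2 -- the "V" shape.
    """
    if not (K1 > 0 and K2 > 0):
        raise InvalidParameterError("K1 and K2 must be > 0")
    if not (beta > 0):
        raise InvalidParameterError(f"beta must be > 0, got {beta}")
    S = np.asarray(S, dtype=float)
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if np.any(I1 < 0) or np.any(I2 < 0):
        raise InvalidParameterError("inhibitor concentrations must be >= 0")
    cross = 0.0 if math.isinf(beta) else I1 * I2 / (beta * K1 * K2)
    occupancy = 1.0 + I1 / K1 + I2 / K2 + cross
    with np.errstate(divide="ignore"):
        v = np.where(
            S > 0,
            p.Vmax / (1.0 + (p.Km / np.where(S > 0, S, 1.0)) * occupancy),
            0.0,
        )
    return v if v.ndim else float(v)


def four_pl_response(log10_conc_M, p: PotencyParameters):
    """Four-parameter logistic response (% of control) at log10 molar concentration.

    response = bottom + (top - bottom) / (1 + 10**((x + pIC50) * n_H))

    This is the inhibition-curve convention: with a positive Hill slope the
    response falls from ``top`` (no inhibitor) to ``bottom`` (saturating
    inhibitor). At ``conc == IC50`` the response is the midpoint
    (top + bottom)/2; as ``conc -> 0`` it tends to ``top``.
    """
    x = np.asarray(log10_conc_M, dtype=float)
    r = p.bottom + (p.top - p.bottom) / (1.0 + 10.0 ** ((x + p.pIC50) * p.hill_slope))
    return r if r.ndim else float(r)


def pic50_to_ic50_uM(pIC50: float) -> float:
    """Convert pIC50 (molar scale) to IC50 in uM: 10**(6 - pIC50)."""
    return 10.0 ** (6.0 - pIC50)


def ic50_uM_to_pic50(ic50_uM: float) -> float:
    """Convert IC50 in uM to pIC50 (molar scale): 6 - log10(IC50_uM)."""
    if not (ic50_uM > 0):
        raise InvalidParameterError(f"IC50 must be > 0, got {ic50_uM}")
    return 6.0 - math.log10(ic50_uM)


def dixon_line_coefficients(
    S: float, p: MMParameters, q: InhibitionParameters
) -> tuple[float, float]:
    """Slope and intercept of the Dixon line 1/v vs [I] at fixed substrate S.

    For the linear mixed model 1/v is exactly linear in I::

        slope     = (Km/S + 1/alpha) / (Vmax * Ki)
        intercept = (1 + Km/S) / Vmax

    In the competitive limit the 1/alpha term vanishes. Lines for any two
    substrate concentrations intersect at ``I = -Ki``,
    ``1/v = (1 - 1/alpha) / Vmax`` (height ``1/Vmax`` for competitive).
    """
    if not (S > 0):
        raise InvalidParameterError(f"substrate concentration must be > 0, got {S}")
    inv_alpha = 0.0 if q.mode == "competitive" else 1.0 / q.alpha
    slope = (p.Km / S + inv_alpha) / (p.Vmax * q.Ki)
    intercept = (1.0 + p.Km / S) / p.Vmax
    return slope, intercept
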