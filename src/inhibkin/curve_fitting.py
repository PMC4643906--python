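"""Nonlinear least-squares estimation of potency and inhibition parameters.

Provides the four fitting entry points the analysis pipeline relies on:

* :func:`fit_potency` -- 4PL concentration-response fit (top fixed at 100,
  bottom fixed at zero or floating) returning pIC50/IC50 and the Hill slope;
* :func:`fit_inhibition_kinetics` -- global fit of a substrate x inhibitor
  velocity table to the linear mixed and pure competitive models;
* :func:`select_by_aic` -- Akaike-criterion model selection between candidate
  fits of the same data;
* :func:`robust_line` -- outlier-resistant straight-line fit (Tukey bisquare
  IRLS) for Dixon plots.

All positive kinetic parameters (Km, Vmax, Ki, alpha) are estimated on the
log scale so the optimizer stays in the physical region; standard errors are
back-transformed by the delta method. Nonlinear fits start from a small grid
of log-spaced initial values and polish the best starts with
Levenberg-Marquardt, which makes the estimates reproducible without relying
on a single lucky initialisation.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .kinetic_models import (
    InvalidParameterError,
    MMParameters,
    InhibitionParameters,
    PotencyParameters,
    competitive_velocity,
    four_pl_response,
    mixed_inhibition_velocity,
    pic50_to_ic50_uM,
)

__all__ = [
    "PotencyFit",
    "MixedInhibitionFit",
    "FitComparison",
    "LineFit",
    "FitFailureError",
    "DegenerateDataError",
    "DesignError",
    "fit_potency",
    "select_by_aic",
    "fit_inhibition_kinetics",
    "robust_line",
    "aic_from_rss",
]


class FitFailureError(RuntimeError):
    """The optimizer failed to converge from any starting point."""


class DegenerateDataError(ValueError):
    """The data carry no information about the parameters (e.g. flat responses)."""


class DesignError(ValueError):
    """The experimental design lacks a dimension the fit requires."""


def aic_from_rss(rss: float, n: int, k_free: int) -> float:
    """Gaussian-residual Akaike criterion: AIC = n*ln(RSS/n) + 2k.

    ``k = k_free + 1`` counts the residual variance as an estimated
    parameter alongside the ``k_free`` free model parameters.
    """
    if n <= 0 or rss < 0:
        raise ValueError("need n > 0 and RSS >= 0")
    rss = max(rss, 1e-300)  # exact fits: keep the log finite
    return n * math.log(rss / n) + 2 * (k_free + 1)


def _data_fingerprint(y: np.ndarray) -> str:
    return hashlib.sha1(np.round(np.asarray(y, float), 12).tobytes()).hexdigest()


@dataclass(frozen=True)
class PotencyFit:
    """Result of a 4PL concentration-response fit."""

    params: PotencyParameters
    se: dict[str, float]
    bottom_mode: str  # "fixed_zero" | "floating"
    aic: float
    rss: float
    n_obs: int
    data_id: str = ""

    @property
    def ic50_uM(self) -> float:
        return pic50_to_ic50_uM(self.params.pIC50)

    @property
    def n_free_params(self) -> int:
        return 2 if self.bottom_mode == "fixed_zero" else 3


@dataclass(frozen=True)
class MixedInhibitionFit:
    """Result of a global velocity-table fit to one inhibition model."""

    mm: MMParameters
    inhib: InhibitionParameters
    se: dict[str, float]
    aic: float
    rss: float
    n_obs: int
    model_label: str  # "mixed" | "competitive"
    data_id: str = ""

    @property
    def n_free_params(self) -> int:
        return 4 if self.model_label == "mixed" else 3


@dataclass(frozen=True)
class FitComparison:
    """Akaike comparison across candidate fits of the same data."""

    candidates: tuple
    selected: int
    delta_aic: tuple[float, ...]

    @property
    def best(self):
        return self.candidates[self.selected]


@dataclass(frozen=True)
class LineFit:
    """A straight-line fit y = slope*x + intercept."""

    slope: float
    intercept: float
    method: str  # "ols" | "robust"
    scale: float
    n_obs: int

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept

    def rss(self, x, y) -> float:
        r = np.asarray(y, float) - self.predict(x)
        return float(r @ r)


def select_by_aic(candidates) -> FitComparison:
    """Pick the candidate with the smallest AIC; ties go to fewer parameters.

    All candidates must be fits of the same observations (same ``n_obs`` and,
    when available, the same data fingerprint); otherwise their RSS-based
    AICs are not comparable and a ``ValueError`` is raised.
    """
    candidates = tuple(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate fits to compare")
    n0 = candidates[0].n_obs
    id0 = getattr(candidates[0], "data_id", "")
    for c in candidates[1:]:
        if c.n_obs != n0 or (id0 and getattr(c, "data_id", "") not in ("", id0)):
            raise ValueError("candidates were fit to different data")
    aics = np.array([c.aic for c in candidates])
    best_aic = aics.min()
    # ties (numerically identical AIC) resolve toward the simpler model
    tied = np.flatnonzero(aics - best_aic < 1e-9)
    selected = int(tied[np.argmin([candidates[i].n_free_params for i in tied])])
    return FitComparison(
        candidates=candidates,
        selected=selected,
        delta_aic=tuple(float(a - aics[selected]) for a in aics),
    )


# ---------------------------------------------------------------------------
# potency (4PL) fitting


def fit_potency(conc_uM, response, bottom_mode: str = "fixed_zero") -> PotencyFit:
    """Fit a 4PL inhibition curve with top fixed at 100% of control.

    Parameters
    ----------
    conc_uM, response : array-like
        Inhibitor concentrations (uM, zero rows allowed and ignored for the
        log axis only if zero) and responses in % of control.
    bottom_mode : {"fixed_zero", "floating"}
        Whether the bottom plateau is pinned to 0% or estimated.

    Returns
    -------
    PotencyFit with pIC50, hill_slope (and bottom when floating), standard
    errors from the local curvature of the objective, RSS and AIC.
    """
    if bottom_mode not in ("fixed_zero", "floating"):
        raise ValueError(f"unknown bottom_mode {bottom_mode!r}")
    conc = np.asarray(conc_uM, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("conc_uM and response must have the same shape")
    if np.any(conc < 0):
        raise InvalidParameterError("concentrations must be >= 0")
    n = y.size
    if n < 5:
        raise DesignError("need at least 5 concentration-response points")
    if np.ptp(y) < 1e-9 or np.std(y) < 1e-3 * max(1.0, abs(np.mean(y))):
        raise DegenerateDataError("responses are flat; no transition to fit")

    # zero-concentration wells sit at -inf on the log axis; clamp far left
    pos = conc > 0
    x = np.empty_like(conc)
    x[pos] = np.log10(conc[pos] * 1e-6)
    x[~pos] = (np.log10(conc[pos].min() * 1e-6) - 6.0) if pos.any() else -30.0

    nfree = 2 if bottom_mode == "fixed_zero" else 3

    def residuals(theta):
        pic50, hill = theta[0], theta[1]
        bottom = theta[2] if nfree == 3 else 0.0
        expo = np.clip((x + pic50) * hill, -300.0, 300.0)
        pred = bottom + (100.0 - bottom) / (1.0 + 10.0**expo)
        return pred - y

    # multi-start: pIC50 across the sampled range, a few Hill slopes
    if pos.any():
        pic50_grid = 6.0 - np.log10(
            np.geomspace(conc[pos].min(), conc[pos].max(), 4)
        )
    else:
        pic50_grid = np.array([6.0])
    starts = [
        np.array([p0, h0] + ([0.0] if nfree == 3 else []))
        for p0 in pic50_grid
        for h0 in (0.5, 1.0, 2.0)
    ]
    best = None
    for th0 in starts:
        try:
            res = least_squares(residuals, th0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and best.cost > 1e6:
        raise FitFailureError(
            f"4PL fit did not converge from {len(starts)} starts (n={n})"
        )

    theta = best.x
    bottom = float(theta[2]) if nfree == 3 else 0.0
    if bottom >= 100.0:
        raise FitFailureError("fitted bottom reached/exceeded the fixed top of 100%")
    rss = float(2 * best.cost)
    se = _se_from_jacobian(best.jac, rss, n, ("pIC50", "hill_slope", "bottom")[:nfree])
    params = PotencyParameters(
        pIC50=float(theta[0]), hill_slope=float(theta[1]), top=100.0, bottom=bottom
    )
    return PotencyFit(
        params=params,
        se=se,
        bottom_mode=bottom_mode,
        aic=aic_from_rss(rss, n, nfree),
        rss=rss,
        n_obs=n,
        data_id=_data_fingerprint(y),
    )


def _se_from_jacobian(jac, rss, n, names) -> dict[str, float]:
    """Asymptotic SEs from the Gauss-Newton curvature at the optimum."""
    k = jac.shape[1]
    dof = max(n - k, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
        diag = np.clip(np.diag(cov), 0, None)
        return {nm: float(np.sqrt(d)) for nm, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {nm: float("nan") for nm in names}


# ---------------------------------------------------------------------------
# inhibition-kinetics (velocity table) fitting


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DesignError(f"velocity table is missing column(s): {missing}")


def fit_inhibition_kinetics(
    table: pd.DataFrame,
    models: tuple[str, ...] = ("mixed", "competitive"),
    n_polish: int = 3,
) -> FitComparison:
    """Globally fit a velocity table to mixed and competitive inhibition models.

    The table needs columns ``substrate_uM``, ``inhibitor_uM`` and
    ``velocity`` with at least two distinct substrate and two distinct
    inhibitor levels (a zero-inhibitor control counts as a level). Both
    candidate models are fit to all points simultaneously; the returned
    :class:`FitComparison` selects between them by AIC, and each candidate
    carries Ki +/- SE (and alpha +/- SE for the mixed model).

    ``n_polish`` controls how many of the grid starting points are polished
    with Levenberg-Marquardt (the grid itself is 3x3x3 over log-spaced
    Ki, alpha and Km).
    """
    _require_columns(table, ("substrate_uM", "inhibitor_uM", "velocity"))
    S = table["substrate_uM"].to_numpy(float)
    I = table["inhibitor_uM"].to_numpy(float)
    v = table["velocity"].to_numpy(float)
    if np.unique(S).size < 2:
        raise DesignError("need >= 2 distinct substrate concentrations")
    if np.unique(I).size < 2:
        raise DesignError("need >= 2 distinct inhibitor concentrations")
    if not np.all(np.isfinite(v)):
        raise ValueError("velocities must be finite")

    fits = [_fit_one_kinetic_model(S, I, v, label, n_polish) for label in models]
    return select_by_aic(fits)


def _fit_one_kinetic_model(S, I, v, label: str, n_polish: int) -> MixedInhibitionFit:
    n = v.size
    is_mixed = label == "mixed"

    def predict(theta):
        km, vmax, ki = np.exp(theta[:3])
        if is_mixed:
            alpha = np.exp(theta[3])
            denom = 1.0 + I / (alpha * ki)
            return (vmax / denom) / (1.0 + (km * (1.0 + I / ki) / denom) / S)
        return vmax / (1.0 + (km / S) * (1.0 + I / ki))

    def residuals(theta):
        return predict(theta) - v

    # data-driven anchors: Km near the substrate range, Vmax near the top
    # velocity, Ki near the inhibitor range
    s_mid = math.sqrt(S.min() * S.max())
    vmax0 = max(v.max(), 1e-12) * 1.2
    i_pos = I[I > 0]
    ki_mid = math.sqrt(i_pos.min() * i_pos.max()) if i_pos.size else 1.0
    km_grid = np.log(s_mid * np.array([0.3, 1.0, 3.0]))
    ki_grid = np.log(ki_mid * np.array([0.2, 1.0, 5.0]))
    alpha_grid = np.log(np.array([0.5, 3.0, 30.0]))

    starts = []
    for km0 in km_grid:
        for ki0 in ki_grid:
            if is_mixed:
                for a0 in alpha_grid:
                    starts.append(np.array([km0, math.log(vmax0), ki0, a0]))
            else:
                starts.append(np.array([km0, math.log(vmax0), ki0]))

    # rank all grid starts by RSS, polish only the most promising few
    rss0 = [float(np.sum(residuals(th) ** 2)) for th in starts]
    order = np.argsort(rss0)[: max(1, n_polish)]
    best = None
    for idx in order:
        try:
            res = least_squares(residuals, starts[idx], method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError(f"{label} kinetic fit failed from all starts")

    theta = best.x
    rss = float(2 * best.cost)
    names_log = ("Km", "Vmax", "Ki") + (("alpha",) if is_mixed else ())
    se_log = _se_from_jacobian(best.jac, rss, n, names_log)
    vals = dict(zip(names_log, np.exp(theta)))
    # delta method: se(p) = p * se(log p)
    se = {nm: vals[nm] * se_log[nm] for nm in names_log}

    mm = MMParameters(Km=vals["Km"], Vmax=vals["Vmax"])
    if is_mixed:
        inhib = InhibitionParameters(Ki=vals["Ki"], alpha=vals["alpha"], mode="mixed")
        k_free = 4
    else:
        inhib = InhibitionParameters(Ki=vals["Ki"], mode="competitive")
        k_free = 3
    return MixedInhibitionFit(
        mm=mm,
        inhib=inhib,
        se=se,
        aic=aic_from_rss(rss, n, k_free),
        rss=rss,
        n_obs=n,
        model_label=label,
        data_id=_data_fingerprint(v),
    )


# ---------------------------------------------------------------------------
# robust straight lines for Dixon plots


def robust_line(x, y, method: str = "robust") -> LineFit:
    """Outlier-resistant straight-line fit for Dixon plots.

    Uses iteratively reweighted least squares with the Tukey bisquare loss
    (tuning constant 4.685, scale from the median absolute deviation).
    With fewer than 4 points the robust weights are meaningless, so the fit
    falls back to ordinary least squares; two points are interpolated
    exactly. Raises ``ValueError`` when all x coincide (vertical line).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical: vertical line has no finite slope")

    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    resid = y - ols.fittedvalues
    ols_scale = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
    # n < 4: robust weights are meaningless.  Near-perfectly collinear data:
    # MAD scale degenerates to 0 and IRLS weights blow up, but OLS is already
    # exact there.
    if n < 4 or method == "ols" or ols_scale <= 1e-10 * max(1.0, float(np.ptp(y))):
        return LineFit(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            method="ols",
            scale=ols_scale,
            n_obs=n,
        )
    # normalise the response before IRLS so the fit is exactly equivariant
    # under rescaling of the velocity units (the IRLS stopping rule is
    # otherwise sensitive to the absolute scale of y)
    c0 = float(np.median(np.abs(y))) or float(np.std(y)) or 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # scale_est="mad": median-absolute-deviation scale
        rlm = sm.RLM(y / c0, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(
            scale_est="mad", maxiter=200, tol=1e-10
        )
    return LineFit(
        slope=float(rlm.params[1]) * c0,
        intercept=float(rlm.params[0]) * c0,
        method="robust",
        scale=float(rlm.scale) * c0,
        n_obs=n,
    )
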