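"""Dixon-plot analysis: line families, intersections, median Ki, exclusivity.

A Dixon plot graphs reciprocal velocity against inhibitor concentration at
several fixed substrate concentrations. For a linear mixed-type (or
competitive) inhibitor every such line is exactly straight, and the lines
for any two substrate concentrations intersect at I = -Ki. With n substrate
levels there are C(n, 2) pairwise intersections; taking the *median* of
their x-coordinates (in the spirit of the direct linear plot of Eisenthal &
Cornish-Bowden) gives a Ki estimate that single wild intersections cannot
drag around.

The same 1/v-vs-[I] construction settles whether two inhibitors bind
mutually exclusively: plotting 1/v against inhibitor 1 at several fixed
levels of inhibitor 2 yields parallel lines when the two cannot occupy the
enzyme simultaneously, and a "V" opening toward the y-axis (slopes growing
with [I2]) when they bind cooperatively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .curve_fitting import DesignError, LineFit, aic_from_rss, robust_line

__all__ = [
    "DixonFamily",
    "IntersectionSet",
    "DixonKiEstimate",
    "ExclusivityResult",
    "build_dixon_family",
    "pairwise_intersections",
    "median_intersection_ki",
    "exclusivity_analysis",
    "NEAR_PARALLEL_TOL",
]

#: relative slope-difference tolerance below which a line pair is treated as
#: parallel and excluded from the intersection census
NEAR_PARALLEL_TOL = 1e-6


@dataclass(frozen=True)
class DixonFamily:
    """One robust line of 1/v vs [I] per substrate concentration (uM)."""

    lines: dict[float, LineFit]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.lines) < 2:
            raise DesignError("a Dixon family needs lines at >= 2 substrate levels")

    @property
    def substrate_levels(self) -> tuple[float, ...]:
        return tuple(sorted(self.lines))


@dataclass(frozen=True)
class IntersectionSet:
    """All pairwise line intersections of a Dixon family.

    ``pairs`` holds (S_a, S_b, x, y) tuples; near-parallel pairs are moved to
    ``excluded_pairs`` with a reason. Conservation:
    ``len(pairs) + len(excluded_pairs) == n_expected == C(n_lines, 2)``.
    """

    pairs: tuple
    excluded_pairs: tuple
    n_expected: int

    def __post_init__(self) -> None:
        if len(self.pairs) + len(self.excluded_pairs) != self.n_expected:
            raise ValueError("intersection census does not add up to C(n, 2)")

    @property
    def x_values(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])

    @property
    def y_values(self) -> np.ndarray:
        return np.array([p[3] for p in self.pairs])


@dataclass(frozen=True)
class DixonKiEstimate:
    """Median-intersection Ki: Ki = -median(x_intersect)."""

    ki: float
    median_x: float
    median_y: float
    n_used: int


@dataclass(frozen=True)
class ExclusivityResult:
    """Verdict of a two-inhibitor Dixon analysis at fixed substrate.

    ``family`` maps each level of the secondary inhibitor to the straight
    line of 1/v against the primary inhibitor. The shared-slope
    (parallel-lines) and free-slope models are compared by an
    extra-sum-of-squares F test and by AIC; the verdict is

    * ``mutually_exclusive`` -- parallel lines: the shared-slope model is
      not rejected and AIC does not favour free slopes;
    * ``cooperative`` -- slopes grow with the secondary inhibitor and the
      free-slope model is clearly preferred (p < 0.05 and dAIC >= 2);
    * ``inconclusive`` -- anything else.
    """

    family: dict[float, LineFit]
    common_slope: float
    rss_common: float
    rss_free: float
    f_statistic: float
    p_value: float
    delta_aic: float  # AIC(common) - AIC(free); negative favours parallel lines
    verdict: str
    n_obs: int

    def __post_init__(self) -> None:
        if self.rss_free > self.rss_common * (1 + 1e-9):
            raise ValueError("free-slope RSS cannot exceed common-slope RSS")


def build_dixon_family(
    table: pd.DataFrame,
    inhibitor_col: str = "inhibitor_uM",
    aggregate: str = "mean",
) -> DixonFamily:
    """Build one robust 1/v-vs-[I] line per substrate concentration.

    Non-positive velocities cannot be plotted on a reciprocal axis and are
    dropped with a warning; substrate levels retaining fewer than two
    distinct inhibitor levels are skipped with a warning. By default
    replicate velocities are averaged per (substrate, inhibitor) condition
    before taking reciprocals, mirroring how Dixon plots of mean data are
    drawn; pass ``aggregate="none"`` to fit every replicate point.
    """
    for col in ("substrate_uM", inhibitor_col, "velocity"):
        if col not in table.columns:
            raise DesignError(f"velocity table is missing column {col!r}")

    bad = table["velocity"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} non-positive velocity point(s) "
            "from the Dixon plot",
            stacklevel=2,
        )
        table = table.loc[~bad]

    if aggregate == "mean":
        table = (
            table.groupby(["substrate_uM", inhibitor_col], as_index=False)["velocity"]
            .mean()
        )
    elif aggregate != "none":
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    lines: dict[float, LineFit] = {}
    for s_level, grp in table.groupby("substrate_uM"):
        if grp[inhibitor_col].nunique() < 2:
            warnings.warn(
                f"substrate level {s_level} uM has < 2 inhibitor levels; skipped",
                stacklevel=2,
            )
            continue
        lines[float(s_level)] = robust_line(
            grp[inhibitor_col].to_numpy(float), 1.0 / grp["velocity"].to_numpy(float)
        )
    if len(lines) < 2:
        raise DesignError(
            "need >= 2 usable substrate levels to construct a Dixon family"
        )
    return DixonFamily(lines=lines)


def pairwise_intersections(
    family: DixonFamily, tol: float = NEAR_PARALLEL_TOL
) -> IntersectionSet:
    """Solve every unordered pair of Dixon lines for its intersection.

    For lines y = m1 x + b1 and y = m2 x + b2 the crossing is at
    x = (b2 - b1)/(m1 - m2). Pairs whose relative slope difference is below
    ``tol`` would produce numerically explosive x values and are excluded
    (recorded with a reason) instead.
    """
    levels = family.substrate_levels
    pairs = []
    excluded = []
    for s_a, s_b in combinations(levels, 2):
        la, lb = family.lines[s_a], family.lines[s_b]
        dm = la.slope - lb.slope
        if abs(dm) < tol * max(abs(la.slope), abs(lb.slope)):
            excluded.append((s_a, s_b, "near-parallel"))
            continue
        x = (lb.intercept - la.intercept) / dm
        y = la.slope * x + la.intercept
        pairs.append((s_a, s_b, float(x), float(y)))
    return IntersectionSet(
        pairs=tuple(pairs),
        excluded_pairs=tuple(excluded),
        n_expected=math.comb(len(levels), 2),
    )


def median_intersection_ki(intersections: IntersectionSet) -> DixonKiEstimate:
    """Ki from the median intersection: Ki = -median(x_intersect).

    Even counts use the midpoint of the two central x values (the ordinary
    sample median). The median y-coordinate is reported alongside; for a
    mixed inhibitor it projects to (1 - 1/alpha)/Vmax.
    """
    if not intersections.pairs:
        raise ValueError("no usable intersections: all line pairs were excluded")
    mx = float(np.median(intersections.x_values))
    my = float(np.median(intersections.y_values))
    return DixonKiEstimate(
        ki=-mx, median_x=mx, median_y=my, n_used=len(intersections.pairs)
    )


def exclusivity_analysis(
    table: pd.DataFrame,
    primary_axis: str = "inhibitor_uM",
    secondary_axis: str = "inhibitor2_uM",
    alpha_level: float = 0.05,
    delta_aic_threshold: float = 2.0,
) -> ExclusivityResult:
    """Decide whether two inhibitors act mutually exclusively or cooperatively.

    Expects a fixed-substrate table with both inhibitor columns. 1/v is
    regressed on the primary inhibitor separately at each level of the
    secondary inhibitor, twice: once with every line's slope free and once
    with a single shared slope (per-line intercepts stay free). Mutually
    exclusive inhibitors give parallel lines, so the shared-slope model
    should fit as well as the free one; cooperative binding makes the slope
    grow with the secondary inhibitor.
    """
    for col in (primary_axis, secondary_axis, "velocity"):
        if col not in table.columns:
            raise DesignError(f"two-inhibitor table is missing column {col!r}")
    if "substrate_uM" in table.columns and table["substrate_uM"].nunique() > 1:
        raise DesignError("exclusivity analysis expects a fixed substrate level")

    tbl = table.loc[table["velocity"] > 0]
    levels2 = np.sort(tbl[secondary_axis].unique())
    if levels2.size < 2:
        raise DesignError("need >= 2 levels of the secondary inhibitor")

    x_all, y_all, group_idx = [], [], []
    family: dict[float, LineFit] = {}
    for j, lev in enumerate(levels2):
        grp = tbl.loc[tbl[secondary_axis] == lev]
        if grp[primary_axis].nunique() < 3:
            raise DesignError(
                f"secondary level {lev} uM has < 3 primary-inhibitor levels"
            )
        x = grp[primary_axis].to_numpy(float)
        y = 1.0 / grp["velocity"].to_numpy(float)
        family[float(lev)] = robust_line(x, y, method="ols")
        x_all.append(x)
        y_all.append(y)
        group_idx.append(np.full(x.size, j))
    x_all = np.concatenate(x_all)
    y_all = np.concatenate(y_all)
    group_idx = np.concatenate(group_idx)
    n = y_all.size
    g = levels2.size

    # free-slope model: per-group intercept + per-group slope (2g params)
    X_free = np.zeros((n, 2 * g))
    X_free[np.arange(n), group_idx] = 1.0
    X_free[np.arange(n), g + group_idx] = x_all
    # common-slope model: per-group intercept + one slope (g + 1 params)
    X_common = np.zeros((n, g + 1))
    X_common[np.arange(n), group_idx] = 1.0
    X_common[:, g] = x_all

    # velocity noise has roughly constant CV, so on the reciprocal axis
    # sd(1/v) is proportional to 1/v itself; weight by 1/y^2 to keep the
    # extra-sum-of-squares F test calibrated across inhibition levels
    w = 1.0 / y_all
    beta_f, rss_f = _lstsq_rss(X_free * w[:, None], y_all * w)
    beta_c, rss_c = _lstsq_rss(X_common * w[:, None], y_all * w)
    rss_f = min(rss_f, rss_c)  # guard against lstsq round-off inverting the nesting

    df_num = g - 1
    df_den = n - 2 * g
    if df_den <= 0:
        raise DesignError("not enough points for the extra-sum-of-squares F test")
    y_scale = float((y_all * w) @ (y_all * w))
    if rss_c <= 1e-18 * y_scale:
        # both models fit to machine precision: exactly parallel, noiseless data
        f_stat, p_value = 0.0, 1.0
    elif rss_f <= 1e-18 * y_scale:
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = ((rss_c - rss_f) / df_num) / (rss_f / df_den)
        p_value = float(stats.f.sf(f_stat, df_num, df_den))
    if rss_c <= 1e-18 * y_scale:
        delta_aic = -2.0 * (g - 1)  # equal (perfect) fits: only the penalty differs
    else:
        delta_aic = aic_from_rss(rss_c, n, g + 1) - aic_from_rss(rss_f, n, 2 * g)

    slopes = beta_f[g:]
    tau = stats.kendalltau(levels2, slopes).statistic if g > 2 else (
        1.0 if slopes[1] > slopes[0] else -1.0
    )

    shared_ok = p_value >= alpha_level and delta_aic <= delta_aic_threshold
    free_preferred = p_value < alpha_level and delta_aic >= delta_aic_threshold
    if shared_ok:
        verdict = "mutually_exclusive"
    elif free_preferred and tau > 0:
        verdict = "cooperative"
    else:
        verdict = "inconclusive"

    return ExclusivityResult(
        family=family,
        common_slope=float(beta_c[g]),
        rss_common=float(rss_c),
        rss_free=float(rss_f),
        f_statistic=float(f_stat),
        p_value=p_value,
        delta_aic=float(delta_aic),
        verdict=verdict,
        n_obs=n,
    )


def _lstsq_rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return beta, float(r @ r)
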