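"""Synthetic radioenzymatic-assay data with the structure the fits assume.

The generators emulate [3H]AEA-hydrolysis assays in brain homogenate:
8 substrate concentrations evenly spanning 0.5-4 uM, a handful of inhibitor
levels including a zero-inhibitor control, 3 replicates per condition, and
multiplicative Gaussian noise (constant coefficient of variation, matching
the roughly proportional SEMs such assays show). An optional additive noise
floor covers low-velocity wells, and an optional albumin binding model
depletes the free inhibitor before it reaches the enzyme.

Every generator is driven by a single integer seed through numpy's
``default_rng``, so a fixed configuration reproduces its table bit for bit.
Tables are plain :class:`pandas.DataFrame` objects with the long-format
columns the rest of the package consumes (``substrate_uM``,
``inhibitor_uM``, optional ``inhibitor2_uM``, ``replicate``, ``velocity``);
the generating configuration is attached as ``df.attrs["provenance"]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .albumin_depletion import AlbuminBindingModel, free_concentration
from .kinetic_models import (
    MMParameters,
    InhibitionParameters,
    PotencyParameters,
    four_pl_response,
    mixed_inhibition_velocity,
    mm_velocity,
    two_inhibitor_velocity,
)

__all__ = [
    "TwoInhibitorParameters",
    "SimulationConfig",
    "simulate_velocity_table",
    "simulate_conc_response",
    "simulate_dilution_experiment",
    "DEFAULT_SUBSTRATE_GRID",
    "DEFAULT_INHIBITOR_GRID",
]

#: 8 substrate concentrations evenly spanning 0.5-4 uM of added substrate
DEFAULT_SUBSTRATE_GRID: tuple[float, ...] = tuple(np.linspace(0.5, 4.0, 8))
#: 4 inhibitor levels bracketing a sub-micromolar Ki, zero control included
DEFAULT_INHIBITOR_GRID: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class TwoInhibitorParameters:
    """Joint-occupancy parameters for a two-inhibitor experiment.

    ``beta = inf`` makes the inhibitors mutually exclusive; finite beta
    permits simultaneous (cooperative) binding via the I1*I2 cross term.
    """

    K1: float
    K2: float
    beta: float = math.inf

    def __post_init__(self) -> None:
        if not (self.K1 > 0 and self.K2 > 0 and self.beta > 0):
            raise ValueError("K1, K2 and beta must all be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate a synthetic assay table.

    ``mm`` is always required; supply ``inhib`` for single-inhibitor
    kinetics, ``two_inhibitor`` for joint-inhibition designs, neither for a
    plain substrate-saturation experiment. When ``albumin`` is set the
    *primary* inhibitor concentration is replaced by its free fraction
    before entering the velocity law.
    """

    seed: int = 0
    mm: MMParameters = field(default_factory=lambda: MMParameters(Km=1.5, Vmax=1.0))
    inhib: InhibitionParameters | None = None
    two_inhibitor: TwoInhibitorParameters | None = None
    substrate_grid: tuple[float, ...] = DEFAULT_SUBSTRATE_GRID
    inhibitor_grid: tuple[float, ...] = DEFAULT_INHIBITOR_GRID
    inhibitor2_grid: tuple[float, ...] = ()
    n_replicates: int = 3
    noise_cv: float = 0.05
    additive_sd: float = 0.0
    albumin: AlbuminBindingModel | None = None

    def __post_init__(self) -> None:
        if self.inhib is not None and self.two_inhibitor is not None:
            raise ValueError("configure either inhib or two_inhibitor, not both")
        if self.two_inhibitor is not None and not self.inhibitor2_grid:
            raise ValueError("two_inhibitor model needs a non-empty inhibitor2_grid")
        if self.noise_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if not self.substrate_grid or not self.inhibitor_grid:
            raise ValueError("substrate and inhibitor grids must be non-empty")

    def describe(self) -> dict:
        """JSON-serialisable echo of the configuration."""
        d = {
            "seed": self.seed,
            "mm": asdict(self.mm),
            "inhib": asdict(self.inhib) if self.inhib else None,
            "two_inhibitor": asdict(self.two_inhibitor) if self.two_inhibitor else None,
            "substrate_grid": list(self.substrate_grid),
            "inhibitor_grid": list(self.inhibitor_grid),
            "inhibitor2_grid": list(self.inhibitor2_grid),
            "n_replicates": self.n_replicates,
            "noise_cv": self.noise_cv,
            "additive_sd": self.additive_sd,
            "albumin": asdict(self.albumin) if self.albumin else None,
        }
        if d["inhib"] and math.isinf(d["inhib"]["alpha"]):
            d["inhib"]["alpha"] = None
        if d["two_inhibitor"] and math.isinf(d["two_inhibitor"]["beta"]):
            d["two_inhibitor"]["beta"] = None
        return d


def _model_velocity(config: SimulationConfig, S, I1, I2):
    i1 = I1
    if config.albumin is not None:
        i1 = free_concentration(I1, config.albumin)
    if config.two_inhibitor is not None:
        t = config.two_inhibitor
        return two_inhibitor_velocity(S, i1, I2, config.mm, t.K1, t.K2, t.beta)
    if config.inhib is not None:
        return mixed_inhibition_velocity(S, i1, config.mm, config.inhib)
    return mm_velocity(S, config.mm)


def _apply_noise(rng: np.random.Generator, v: np.ndarray, config: SimulationConfig):
    v_obs = v * (1.0 + rng.normal(0.0, config.noise_cv, size=v.shape))
    if config.additive_sd > 0:
        v_obs = v_obs + rng.normal(0.0, config.additive_sd, size=v.shape)
    n_trunc = int(np.sum(v_obs < 0))
    if n_trunc:
        warnings.warn(
            f"truncated {n_trunc} negative simulated velocity value(s) at 0",
            stacklevel=3,
        )
        v_obs = np.clip(v_obs, 0.0, None)
    return v_obs, n_trunc


def simulate_velocity_table(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a long-format steady-state velocity table.

    Observed velocities are ``v_model * (1 + eps)`` with
    ``eps ~ N(0, noise_cv)``, plus an optional ``N(0, additive_sd)`` floor,
    truncated at zero (hydrolysis cannot be negative; truncations are
    counted in ``df.attrs["n_truncated"]`` and warned about). The free
    primary-inhibitor concentration is used when an albumin model is
    configured, but the table records the *added* concentration, as an
    experimenter would.
    """
    rng = np.random.default_rng(config.seed)
    grids = [config.substrate_grid, config.inhibitor_grid]
    has_i2 = bool(config.inhibitor2_grid)
    if has_i2:
        grids.append(config.inhibitor2_grid)
    grids.append(range(config.n_replicates))

    mesh = np.array(np.meshgrid(*grids, indexing="ij"), dtype=float)
    cols = mesh.reshape(len(grids), -1)
    S, I1 = cols[0], cols[1]
    I2 = cols[2] if has_i2 else np.zeros_like(S)
    rep = cols[-1].astype(int)

    v_true = np.asarray(_model_velocity(config, S, I1, I2), dtype=float)
    v_obs, n_trunc = _apply_noise(rng, v_true, config)

    data = {"substrate_uM": S, "inhibitor_uM": I1}
    if has_i2:
        data["inhibitor2_uM"] = I2
    data["replicate"] = rep
    data["velocity"] = v_obs
    df = pd.DataFrame(data)
    df.attrs["provenance"] = config.describe()
    df.attrs["n_truncated"] = n_trunc
    return df


def simulate_conc_response(
    config: SimulationConfig, potency: PotencyParameters
) -> pd.DataFrame:
    """Simulate a concentration-response table in % of control.

    A zero-inhibitor control level is always present (prepended if the
    configured grid lacks one). Noisy responses are rescaled so the mean of
    the control rows is exactly 100, mirroring how %-of-control data are
    normalised. When an albumin model is configured the response is
    evaluated at the free concentration while the table records the added
    one, which is what makes the fitted apparent Hill slope steepen.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.inhibitor_grid, dtype=float)
    if not np.any(grid == 0):
        grid = np.concatenate([[0.0], grid])
    conc = np.repeat(grid, config.n_replicates)
    rep = np.tile(np.arange(config.n_replicates), grid.size)

    free = conc if config.albumin is None else np.asarray(
        free_concentration(conc, config.albumin), dtype=float
    )
    with np.errstate(divide="ignore"):
        logc = np.where(free > 0, np.log10(np.where(free > 0, free, 1.0) * 1e-6), -30.0)
    resp_true = np.asarray(four_pl_response(logc, potency), dtype=float)
    resp_obs = resp_true * (1.0 + rng.normal(0.0, config.noise_cv, size=resp_true.shape))
    ctrl = resp_obs[conc == 0].mean()
    if ctrl <= 0:
        raise ValueError("control responses averaged <= 0; cannot normalise")
    resp_obs = resp_obs / ctrl * 100.0

    df = pd.DataFrame(
        {"inhibitor_uM": conc, "replicate": rep, "response_pct": resp_obs}
    )
    df.attrs["provenance"] = config.describe()
    df.attrs["potency"] = asdict(potency)
    return df


def simulate_dilution_experiment(
    preinc_concs_uM,
    fold: float,
    mode: str,
    potency: PotencyParameters,
) -> pd.DataFrame:
    """Expected outcome of a preincubate-then-dilute reversibility protocol.

    Homogenate is preincubated with inhibitor at each listed concentration,
    then diluted ``fold``-fold before the activity assay. Three arms are
    compared per concentration, as % of an uninhibited control:

    * ``undiluted_pct`` -- activity had the assay run at the preincubation
      concentration;
    * ``diluted_pct`` -- activity after dilution: for a ``reversible``
      inhibitor the occupancy re-equilibrates to the diluted concentration,
      for an ``irreversible`` one the inhibition set during preincubation
      persists;
    * ``matched_free_pct`` -- a fresh assay at the post-dilution free
      concentration (conc/fold), the benchmark a reversible compound must
      match.

    Values are the noiseless model expectations.
    """
    if not fold > 1:
        raise ValueError(f"dilution fold must be > 1, got {fold}")
    if mode not in ("reversible", "irreversible"):
        raise ValueError(f"unknown mode {mode!r}")
    conc = np.asarray(preinc_concs_uM, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("preincubation concentrations must be > 0")
    diluted = conc / fold

    def pct(c_uM):
        return np.asarray(
            four_pl_response(np.log10(c_uM * 1e-6), potency), dtype=float
        )

    undiluted = pct(conc)
    matched = pct(diluted)
    diluted_arm = matched if mode == "reversible" else undiluted
    return pd.DataFrame(
        {
            "preinc_uM": conc,
            "diluted_uM": diluted,
            "undiluted_pct": undiluted,
            "diluted_pct": diluted_arm,
            "matched_free_pct": matched,
        }
    )
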