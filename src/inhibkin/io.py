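"""Table I/O, configuration, and pipeline orchestration.

The CSV dialect is deliberately plain: comma-separated, decimal point,
UTF-8, one header row. Mandatory columns for a velocity table are
``substrate_uM``, ``inhibitor_uM``, ``replicate`` and ``velocity``;
``inhibitor2_uM`` is optional and marks a two-inhibitor design. Unknown
columns survive a round trip (they are carried in the frame), and all
concentrations are micromolar inside the package — a ``units`` argument
converts nM or M on ingest.

:func:`run_pipeline` executes the analysis stages a study of this kind
chains together — potency fitting, global inhibition-kinetics fitting with
model selection, Dixon median-intersection Ki, two-inhibitor exclusivity —
from a single declarative configuration (a TOML file or an equivalent
mapping), and emits a JSON-serialisable report.
"""

from __future__ import annotations

import json
import logging
import math
import tomllib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import dixon as dixon_mod
from .albumin_depletion import AlbuminBindingModel, free_concentration
from .curve_fitting import fit_inhibition_kinetics, fit_potency
from .kinetic_models import (
    InhibitionParameters,
    MMParameters,
    PotencyParameters,
)
from .synthetic_assay import (
    SimulationConfig,
    TwoInhibitorParameters,
    simulate_conc_response,
    simulate_velocity_table,
)

__all__ = [
    "SchemaError",
    "ConfigError",
    "read_velocity_csv",
    "write_velocity_csv",
    "AnalysisReport",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("inhibkin")

MANDATORY_COLUMNS = ("substrate_uM", "inhibitor_uM", "replicate", "velocity")
_UNIT_FACTORS = {"uM": 1.0, "nM": 1e-3, "M": 1e6}
_CONC_COLUMNS = ("substrate_uM", "inhibitor_uM", "inhibitor2_uM")


class SchemaError(ValueError):
    """The file does not match the velocity-table schema."""


class ConfigError(ValueError):
    """The pipeline configuration is inconsistent or incomplete."""


def read_velocity_csv(path, units: str = "uM") -> pd.DataFrame:
    """Read a long-format velocity table, validating the schema.

    Raises :class:`SchemaError` naming any missing mandatory column, and a
    parse error locating the first non-numeric cell by row number.
    ``units`` applies to the concentration columns only.
    """
    if units not in _UNIT_FACTORS:
        raise ValueError(f"unknown units {units!r}; expected one of {list(_UNIT_FACTORS)}")
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    numeric_cols = [c for c in df.columns if c in MANDATORY_COLUMNS + ("inhibitor2_uM",)]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at file row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise SchemaError(f"{path}: empty cell in column {col!r} at file row {row}")
        df[col] = coerced
    factor = _UNIT_FACTORS[units]
    if factor != 1.0:
        for col in _CONC_COLUMNS:
            if col in df.columns:
                df[col] = df[col] * factor
    if not np.all(np.isfinite(df["velocity"])):
        raise SchemaError(f"{path}: non-finite velocity value(s)")
    df["replicate"] = df["replicate"].astype(int)
    df.attrs["provenance"] = {"source": str(path), "units_in": units}
    return df


def write_velocity_csv(table: pd.DataFrame, path) -> None:
    """Write a velocity table in the package CSV dialect (uM, UTF-8)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"table to write is missing column(s) {missing}")
    table.to_csv(path, index=False)


def _package_version() -> str:
    try:
        return version("inhibkin")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class AnalysisReport:
    """JSON-serialisable record of one pipeline run."""

    provenance: dict
    config_echo: dict
    results: dict = field(default_factory=dict)
    decisions: list[str] = field(default_factory=list)
    software_version: str = field(default_factory=_package_version)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True, **kwargs)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path) -> "AnalysisReport":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**d)


def _json_safe(x):
    if isinstance(x, float) and math.isinf(x):
        return None
    if isinstance(x, dict):
        return {k: _json_safe(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_json_safe(v) for v in x]
    return x


def _mm_from_cfg(sim: dict) -> MMParameters:
    return MMParameters(Km=sim.get("Km", 1.5), Vmax=sim.get("Vmax", 1.0))


def _sim_config_from_cfg(cfg: dict) -> SimulationConfig:
    sim = cfg.get("simulation", {})
    model = sim.get("model", "mixed")
    mm = _mm_from_cfg(sim)
    inhib = None
    two = None
    if model in ("mixed", "competitive"):
        inhib = InhibitionParameters(
            Ki=sim.get("Ki", 0.8),
            alpha=sim.get("alpha", 3.2) if model == "mixed" else math.inf,
            mode=model,
        )
    elif model == "two_inhibitor":
        two = TwoInhibitorParameters(
            K1=sim.get("K1", 0.8),
            K2=sim.get("K2", 30.0),
            beta=sim.get("beta", math.inf),
        )
    elif model != "mm":
        raise ConfigError(f"unknown simulation model {model!r}")
    albumin = None
    alb = cfg.get("albumin", {})
    if alb.get("enabled", False):
        albumin = AlbuminBindingModel(
            albumin_capacity=alb.get("capacity_uM", 2.25), kd=alb.get("kd_uM", 0.1)
        )
    kwargs = {}
    for key in (
        "substrate_grid",
        "inhibitor_grid",
        "inhibitor2_grid",
        "n_replicates",
        "noise_cv",
        "additive_sd",
    ):
        if key in sim:
            val = sim[key]
            kwargs[key] = tuple(val) if isinstance(val, list) else val
    return SimulationConfig(
        seed=int(cfg.get("seed", sim.get("seed", 0))),
        mm=mm,
        inhib=inhib,
        two_inhibitor=two,
        albumin=albumin,
        **kwargs,
    )


def load_config(path) -> dict:
    """Load a TOML pipeline configuration."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def run_pipeline(config: dict | str | Path, seed: int | None = None) -> AnalysisReport:
    """Execute the configured analysis stages and assemble a report.

    ``config`` is a mapping (or a path to a TOML file) with blocks:

    * ``input.velocity_csv`` *or* ``simulation`` — where the table comes from;
    * ``stages`` — booleans ``kinetics``, ``dixon``, ``exclusivity``,
      ``potency`` (kinetics and dixon default on for single-inhibitor data);
    * ``albumin`` — optional depletion model applied in simulation;
    * ``seed`` — overridable by the ``seed`` argument.

    Stage requests inconsistent with the data (e.g. exclusivity on a
    single-inhibitor table) raise :class:`ConfigError`.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config = {**config, "seed": int(seed)}

    decisions: list[str] = []
    provenance: dict = {}
    table = None

    if "input" in config and config["input"].get("velocity_csv"):
        path = config["input"]["velocity_csv"]
        table = read_velocity_csv(path, units=config["input"].get("units", "uM"))
        provenance["input"] = table.attrs["provenance"]
        log.info("loaded %d observations from %s", len(table), path)
    elif "simulation" in config:
        sim_cfg = _sim_config_from_cfg(config)
        table = simulate_velocity_table(sim_cfg)
        provenance["simulation"] = table.attrs["provenance"]
        log.info("simulated %d observations (seed=%d)", len(table), sim_cfg.seed)
    else:
        raise ConfigError("config needs an [input] velocity_csv or a [simulation] block")

    stages = config.get("stages", {})
    has_i2 = "inhibitor2_uM" in table.columns and table["inhibitor2_uM"].nunique() > 1
    do_kinetics = stages.get("kinetics", not has_i2)
    do_dixon = stages.get("dixon", not has_i2)
    do_exclusivity = stages.get("exclusivity", has_i2)
    do_potency = stages.get("potency", False)

    results: dict = {}

    if do_exclusivity and not has_i2:
        raise ConfigError(
            "exclusivity stage requested but the table has no varying inhibitor2_uM"
        )
    if do_dixon and table["substrate_uM"].nunique() < 2:
        raise ConfigError("dixon stage requested but the table has a single substrate level")

    if do_kinetics:
        if has_i2:
            raise ConfigError("kinetics stage expects a single-inhibitor table")
        comparison = fit_inhibition_kinetics(table)
        best = comparison.best
        log.info(
            "kinetics: selected %s model (dAIC=%s)",
            best.model_label,
            [round(d, 2) for d in comparison.delta_aic],
        )
        decisions.append(f"kinetics: AIC selected the {best.model_label} model")
        results["kinetics"] = {
            "selected": best.model_label,
            "candidates": [
                {
                    "model": c.model_label,
                    "Km": c.mm.Km,
                    "Vmax": c.mm.Vmax,
                    "Ki": c.inhib.Ki,
                    "alpha": None
                    if c.model_label == "competitive"
                    else c.inhib.alpha,
                    "se": _json_safe(c.se),
                    "aic": c.aic,
                    "rss": c.rss,
                    "delta_aic": comparison.delta_aic[i],
                }
                for i, c in enumerate(comparison.candidates)
            ],
        }

    if do_dixon:
        family = dixon_mod.build_dixon_family(table)
        inter = dixon_mod.pairwise_intersections(family)
        if inter.excluded_pairs:
            decisions.append(
                f"dixon: excluded {len(inter.excluded_pairs)} near-parallel pair(s)"
            )
        est = dixon_mod.median_intersection_ki(inter)
        log.info("dixon: median-intersection Ki = %.4g uM (n=%d)", est.ki, est.n_used)
        results["dixon"] = {
            "ki_uM": est.ki,
            "median_x": est.median_x,
            "median_y": est.median_y,
            "n_intersections_used": est.n_used,
            "n_expected": inter.n_expected,
            "n_excluded": len(inter.excluded_pairs),
            "lines": {
                str(s): {"slope": lf.slope, "intercept": lf.intercept, "method": lf.method}
                for s, lf in family.lines.items()
            },
        }

    if do_exclusivity:
        res = dixon_mod.exclusivity_analysis(table)
        log.info(
            "exclusivity: verdict=%s (F=%.3g, p=%.3g, dAIC=%.3g)",
            res.verdict,
            res.f_statistic,
            res.p_value,
            res.delta_aic,
        )
        decisions.append(f"exclusivity: verdict {res.verdict}")
        results["exclusivity"] = {
            "verdict": res.verdict,
            "f_statistic": res.f_statistic,
            "p_value": res.p_value,
            "delta_aic": res.delta_aic,
            "common_slope": res.common_slope,
            "lines": {
                str(l): {"slope": lf.slope, "intercept": lf.intercept}
                for l, lf in res.family.items()
            },
        }

    if do_potency:
        pot_cfg = config.get("potency", {})
        potency = PotencyParameters(
            pIC50=pot_cfg.get("pIC50", 6.13),
            hill_slope=pot_cfg.get("hill_slope", 1.0),
        )
        sim_cfg = _sim_config_from_cfg(config)
        cr = simulate_conc_response(sim_cfg, potency)
        fits = [
            fit_potency(cr["inhibitor_uM"], cr["response_pct"], bottom_mode=m)
            for m in ("fixed_zero", "floating")
        ]
        from .curve_fitting import select_by_aic

        cmp_ = select_by_aic(fits)
        best = cmp_.best
        decisions.append(f"potency: AIC selected bottom_mode={best.bottom_mode}")
        results["potency"] = {
            "pIC50": best.params.pIC50,
            "IC50_uM": best.ic50_uM,
            "hill_slope": best.params.hill_slope,
            "bottom": best.params.bottom,
            "bottom_mode": best.bottom_mode,
            "se": _json_safe(best.se),
            "aic": best.aic,
        }

    report = AnalysisReport(
        provenance=provenance,
        config_echo=_json_safe(
            {k: v for k, v in config.items()} | {"seed": config.get("seed", 0)}
        ),
        results=results,
        decisions=decisions,
    )

    out = config.get("output", {})
    if out.get("report"):
        report.to_json(out["report"])
        log.info("wrote report to %s", out["report"])
    if out.get("velocity_csv"):
        write_velocity_csv(table, out["velocity_csv"])
    return report
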