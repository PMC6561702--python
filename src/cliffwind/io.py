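"""CSV formats, TOML configuration and the pipeline driver.

Everything on disk is plain text: observation tables, wind grids and
bearing lists are CSV; configuration is TOML.  The observation schema
is one row per landing attempt:

    colony, day, species, ledge, height, wind, turbulence, success

with ISO-8601 dates, lower-case factor tokens (``large | long_narrow |
small``; ``guillemot | razorbill``; ``h1..h4`` bottom-to-top), wind in
m s⁻¹ and success in {0, 1}.  Deposited tables with different headers
are accepted through a ``[columns]`` mapping and a ``[levels]``
mapping in the config.
"""

from __future__ import annotations

import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from cliffwind import energetics as en
from cliffwind import glmm, landing, orientation, synthetic, windfield

logger = logging.getLogger("cliffwind")

REQUIRED_COLUMNS = synthetic.OBS_COLUMNS
FACTOR_LEVELS = {
    "species": set(synthetic.SPECIES_LEVELS),
    "ledge": set(synthetic.LEDGE_LEVELS),
    "height": set(synthetic.HEIGHT_LEVELS),
}


class ObservationTableError(ValueError):
    """Raised when an observation CSV fails schema validation."""


def read_observations(
    path,
    column_map: Mapping[str, str] | None = None,
    level_map: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Read and validate a landing-observation CSV.

    ``column_map`` renames external headers to the canonical schema
    (``{"Ledge type": "ledge", ...}``); ``level_map`` recodes factor
    values per column.  Malformed rows are reported with their file
    line numbers (header = line 1).  Missing columns and unknown factor
    levels are rejected with the offender named.
    """
    table = pd.read_csv(path, dtype={"colony": str, "day": str})
    if column_map:
        table = table.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ObservationTableError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    if level_map:
        for col, mapping in level_map.items():
            table[col] = table[col].astype(str).replace(dict(mapping))
    table = table[REQUIRED_COLUMNS].copy()

    problems: list[str] = []
    wind = pd.to_numeric(table["wind"], errors="coerce")
    for idx in table.index[wind.isna() | (wind < 0)]:
        problems.append(f"line {idx + 2}: wind must be a number >= 0 "
                        f"(got {table.at[idx, 'wind']!r})")
    succ = pd.to_numeric(table["success"], errors="coerce")
    for idx in table.index[~succ.isin([0, 1])]:
        problems.append(f"line {idx + 2}: success must be 0 or 1 "
                        f"(got {table.at[idx, 'success']!r})")
    for col, levels in FACTOR_LEVELS.items():
        bad = ~table[col].astype(str).isin(levels)
        for idx in table.index[bad]:
            problems.append(
                f"line {idx + 2}: unknown {col} level {table.at[idx, col]!r} "
                f"(expected one of {sorted(levels)})")
    if problems:
        raise ObservationTableError(
            f"{path}: {len(problems)} malformed row(s):\n" + "\n".join(problems))

    table["wind"] = wind.astype(float)
    table["turbulence"] = pd.to_numeric(table["turbulence"]).astype(float)
    table["success"] = succ.astype(int)
    return table


def write_observations(table: pd.DataFrame, path) -> None:
    """Write an observation table; ``read_observations`` round-trips it."""
    table.to_csv(path, index=False)


def read_wind_grid(path) -> pd.DataFrame:
    """Read a gridded wind-field CSV with at least U and k columns."""
    grid = pd.read_csv(path)
    for col in ("U", "k"):
        if col not in grid.columns:
            raise ValueError(f"{path}: wind grid is missing column {col!r}")
    return grid


def read_bearings(path) -> pd.DataFrame:
    """Read a colony-bearing CSV with columns ``colony, bearing_deg``."""
    df = pd.read_csv(path)
    for col in ("colony", "bearing_deg"):
        if col not in df.columns:
            raise ValueError(f"{path}: bearings table is missing column {col!r}")
    return df


@dataclass
class PipelineConfig:
    """Settings for the end-to-end analysis run.

    When ``observations_path`` is unset the synthetic generator supplies
    the table; likewise bearings.  ``scaling_ratio`` is the cliff/sea
    wind ratio from the airflow modelling, ``ti`` the turbulence
    intensity used for the at-sea landing curves.
    """

    seed: int = 0
    n_attempts: int = 6000
    observations_path: str | None = None
    bearings_path: str | None = None
    column_map: dict = dc_field(default_factory=dict)
    level_map: dict = dc_field(default_factory=dict)
    ti: float = 0.2
    scaling_ratio: float = 0.7
    max_attempts: int = 20
    sea_winds: tuple = tuple(float(w) for w in range(0, 17))
    profile_ledge: str = "long_narrow"
    profile_species: str = "guillemot"
    profile_height: str = "h4"
    flight_power_w: float = 4900.0 / 34.0
    loop_duration_s: float = 34.0
    prey_energy_kj: float = 29.4
    n_orientations: int = 11
    quad_points: int = 7


def load_config(path) -> PipelineConfig:
    """Load a TOML config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    column_map = raw.pop("columns", {})
    level_map = raw.pop("levels", {})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "sea_winds" in raw:
        raw["sea_winds"] = tuple(float(w) for w in raw["sea_winds"])
    return PipelineConfig(column_map=column_map, level_map=level_map, **raw)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run simulate -> fit -> collapse -> attempt curves -> energetics ->
    orientation, writing every stage's output under ``outdir``.

    Returns the report bundle as a dict of in-memory results; identical
    seed and inputs give identical numerical outputs.  A stage failure
    aborts the run with the stage named.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    bundle: dict = {}
    stage = "setup"
    log_lines = [f"seed={config.seed}",
                 f"numpy={np.__version__} pandas={pd.__version__} "
                 f"python={sys.version.split()[0]}"]
    try:
        stage = "simulate"
        if config.observations_path:
            table = read_observations(config.observations_path,
                                      config.column_map, config.level_map)
        else:
            table = synthetic.generate_observations(
                synthetic.SimulationConfig(n_attempts=config.n_attempts,
                                           seed=config.seed))
        write_observations(table, out / "observations.csv")
        bundle["observations"] = table
        log_lines.append(f"simulate: {len(table)} attempts")

        stage = "fit"
        fit = glmm.fit_landing_glmm(table, quad_points=config.quad_points)
        fit.summary().to_csv(out / "glmm_fit.csv", index=False)
        r2m, r2c = glmm.r2_nakagawa(fit)
        bundle["fit"] = fit
        bundle["r2"] = (r2m, r2c)
        log_lines.append(
            f"fit: logLik={fit.loglik:.3f} AIC={fit.aic:.1f} "
            f"sd={fit.random_intercept_sd:.3f} R2m={r2m:.3f} R2c={r2c:.3f} "
            f"converged={fit.converged}")

        stage = "collapse"
        profile = {"ledge": config.profile_ledge,
                   "species": config.profile_species,
                   "height": config.profile_height}
        model = landing.logistic_from_glmm(fit, profile)
        bundle["logistic"] = model
        log_lines.append(f"collapse: a={model.a:.4f} b={model.b:.4f}")

        stage = "attempt-curves"
        scaling = windfield.ScalingConstant(ratio=config.scaling_ratio)
        curves = landing.landing_curve_at_sea(
            model, config.ti, scaling, config.sea_winds,
            max_attempts=config.max_attempts)
        curves.to_csv(out / "landing_curves.csv", index=False)
        bundle["curves"] = curves

        stage = "energetics"
        cost = en.cost_per_attempt(config.flight_power_w, config.loop_duration_s)
        rows = []
        for _, row in curves.iterrows():
            att = landing.AttemptDistribution(P=max(row["P"], 1e-12))
            expected, quants = en.expected_bout_cost(cost, att)
            rows.append({"sea_wind": row["sea_wind"], "P": row["P"],
                         "expected_cost_kj": expected,
                         **{f"q{int(100 * p)}_kj": v for p, v in quants.items()}})
        edf = pd.DataFrame(rows)
        edf.to_csv(out / "energetics.csv", index=False)
        bundle["energetics"] = edf
        bundle["attempts_per_prey"] = en.attempts_per_prey_item(
            config.prey_energy_kj, cost)
        log_lines.append(
            f"energetics: cost/loop={cost:.2f} kJ, "
            f"prey covers {bundle['attempts_per_prey']:.2f} attempts")

        stage = "orientation"
        if config.bearings_path:
            bearings = read_bearings(config.bearings_path)["bearing_deg"].to_numpy()
        else:
            bearings = synthetic.generate_orientations(
                config.n_orientations, seed=config.seed)
        sample = orientation.CircularSample(tuple(bearings))
        mean_dir, rbar = orientation.circular_summary(sample)
        z, p = orientation.rayleigh_test(sample)
        pd.DataFrame([{"n": sample.n, "mean_direction_deg": mean_dir,
                       "resultant_length": rbar, "rayleigh_Z": z,
                       "rayleigh_p": p}]).to_csv(
            out / "orientation.csv", index=False)
        bundle["orientation"] = {"n": sample.n, "mean_direction": mean_dir,
                                 "rbar": rbar, "Z": z, "p": p}
        log_lines.append(f"orientation: n={sample.n} Rbar={rbar:.3f} "
                         f"Z={z:.3f} p={p:.3f}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_lines.append(f"elapsed: {time.time() - t0:.1f} s")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out / "run_summary.json", "w") as fh:
        json.dump({
            "seed": config.seed,
            "n_attempts": int(len(bundle["observations"])),
            "loglik": bundle["fit"].loglik,
            "aic": bundle["fit"].aic,
            "random_intercept_sd": bundle["fit"].random_intercept_sd,
            "r2_marginal": bundle["r2"][0],
            "r2_conditional": bundle["r2"][1],
            "logistic_a": bundle["logistic"].a,
            "logistic_b": bundle["logistic"].b,
            "attempts_per_prey": bundle["attempts_per_prey"],
            "rayleigh": bundle["orientation"],
        }, fh, indent=2)
    return bundle
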