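"""CSV / YAML serialization of sweeps, fit results and run configuration.

Canonical sweep format: UTF-8 CSV, one-line header
``plant,hour,replicate,frequency_hz,resistance_ohm,reactance_ohm``,
'.' decimal separator, rows sorted by (plant, hour, replicate, frequency).
Floats are written with 17 significant digits so read(write(x)) is
bit-exact.  An LCR-export dialect additionally tolerates '#'-prefixed
metadata lines, a |Z|/theta column pair (``zabs_ohm``, ``theta_deg``)
converted to R/X, and magnitude-only reactance columns which are
sign-normalized to XC <= 0.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregate import ReplicateSweepSet
from .circuit import DSMParams, FrequencyGrid, ImpedanceSpectrum, ParameterBounds, default_grid
from .fitting import FitConfig, FitResult
from .simulate import NoiseConfig, TrajectoryConfig

__all__ = [
    "SweepFormatError",
    "SWEEP_COLUMNS",
    "FIT_COLUMNS",
    "GridSpec",
    "RunConfig",
    "read_sweeps",
    "write_sweeps",
    "read_fits",
    "write_fits",
    "read_config",
    "write_config",
]

SWEEP_COLUMNS = [
    "plant",
    "hour",
    "replicate",
    "frequency_hz",
    "resistance_ohm",
    "reactance_ohm",
]

FIT_COLUMNS = [
    "plant",
    "hour",
    "r1_ohm",
    "r2_ohm",
    "r4_ohm",
    "c3_farad",
    "c5_farad",
    "error_ohm",
    "n_evals",
    "converged",
]

_FLOAT_FORMAT = "%.17g"


class SweepFormatError(ValueError):
    """Malformed sweep/fit file; message carries path and row context."""


def write_sweeps(sweep_sets: list[ReplicateSweepSet], path) -> None:
    """Write replicate sweep sets as canonical CSV (deterministic bytes)."""
    rows = []
    for s in sorted(sweep_sets, key=lambda s: (s.plant, s.hour)):
        freqs = s.grid.frequencies
        for i, rep in enumerate(s.replicates, start=1):
            rows.append(
                pd.DataFrame(
                    {
                        "plant": s.plant,
                        "hour": s.hour,
                        "replicate": i,
                        "frequency_hz": freqs,
                        "resistance_ohm": rep.resistance,
                        "reactance_ohm": rep.reactance,
                    }
                )
            )
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        df = pd.DataFrame(columns=SWEEP_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def read_sweeps(path, dialect: str = "canonical") -> list[ReplicateSweepSet]:
    """Read sweep CSV into replicate sets grouped by (plant, hour).

    ``dialect="canonical"`` expects exactly the columns written by
    :func:`write_sweeps`.  ``dialect="lcr"`` tolerates '#' metadata lines,
    accepts ``zabs_ohm``/``theta_deg`` instead of R/X, and sign-normalizes
    reactance columns stored as magnitudes |XC|.
    """
    path = Path(path)
    if dialect not in ("canonical", "lcr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path,
            comment="#" if dialect == "lcr" else None,
            float_precision="round_trip",
        )
    except Exception as exc:
        raise SweepFormatError(f"{path}: cannot parse CSV ({exc})") from exc

    if dialect == "lcr" and {"zabs_ohm", "theta_deg"}.issubset(df.columns):
        theta = np.radians(df["theta_deg"].to_numpy(dtype=float))
        zabs = df["zabs_ohm"].to_numpy(dtype=float)
        df = df.assign(resistance_ohm=zabs * np.cos(theta), reactance_ohm=zabs * np.sin(theta))

    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise SweepFormatError(f"{path}: missing columns {missing}")
    df = df[SWEEP_COLUMNS]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~df.isna().all(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
        raise SweepFormatError(f"{path}: non-numeric fields at line(s) {lines}")
    df = numeric
    if (df["frequency_hz"] <= 0).any():
        line = int(df.index[df["frequency_hz"] <= 0][0]) + 2
        raise SweepFormatError(f"{path}: non-positive frequency at line {line}")

    if dialect == "lcr" and (df["reactance_ohm"] >= 0).all() and (df["reactance_ohm"] > 0).any():
        # Instrument exported |XC|; capacitive reactance is negative.
        df["reactance_ohm"] = -df["reactance_ohm"]

    keys = ["plant", "hour", "replicate", "frequency_hz"]
    dup = df.duplicated(subset=keys, keep="first")
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise SweepFormatError(
            f"{path}: duplicated (plant, hour, replicate, frequency) at line {line}"
        )

    sets: list[ReplicateSweepSet] = []
    for (plant, hour), cell in df.groupby(["plant", "hour"], sort=True):
        replicates = []
        grid = None
        for rep_idx, rep in cell.groupby("replicate", sort=True):
            rep = rep.sort_values("frequency_hz")
            try:
                rep_grid = FrequencyGrid(rep["frequency_hz"].to_numpy())
            except ValueError as exc:
                raise SweepFormatError(
                    f"{path}: plant {plant} hour {hour} replicate {rep_idx}: {exc}"
                ) from exc
            if grid is None:
                grid = rep_grid
            elif rep_grid != grid:
                raise SweepFormatError(
                    f"{path}: plant {plant} hour {hour} replicate {rep_idx} "
                    "uses a different frequency grid than the first replicate"
                )
            replicates.append(
                ImpedanceSpectrum(
                    rep_grid,
                    rep["resistance_ohm"].to_numpy(dtype=float),
                    rep["reactance_ohm"].to_numpy(dtype=float),
                )
            )
        sets.append(ReplicateSweepSet(plant=int(plant), hour=int(hour), replicates=replicates))
    return sets


def write_fits(results: list[FitResult], path) -> None:
    """Write fit results as CSV, one row per (plant, hour), sorted."""
    rows = []
    for r in sorted(results, key=lambda r: (r.plant or 0, r.hour or 0)):
        p = r.params
        rows.append(
            {
                "plant": r.plant,
                "hour": r.hour,
                "r1_ohm": p.r1 if p else math.nan,
                "r2_ohm": p.r2 if p else math.nan,
                "r4_ohm": p.r4 if p else math.nan,
                "c3_farad": p.c3 if p else math.nan,
                "c5_farad": p.c5 if p else math.nan,
                "error_ohm": r.final_error,
                "n_evals": r.n_evals,
                "converged": bool(r.converged),
            }
        )
    df = pd.DataFrame(rows, columns=FIT_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def read_fits(path) -> pd.DataFrame:
    """Read a fit-result CSV back into a DataFrame."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise SweepFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise SweepFormatError(f"{path}: missing columns {missing}")
    df["converged"] = df["converged"].astype(bool)
    return df


@dataclass(frozen=True)
class GridSpec:
    """Frequency-sweep specification (201 log points, 500 Hz–300 kHz)."""

    n_points: int = 201
    f_min: float = 500.0
    f_max: float = 3.0e5

    def build(self) -> FrequencyGrid:
        return default_grid(self.n_points, self.f_min, self.f_max)


@dataclass
class RunConfig:
    """Everything needed to reproduce a study run from one file + seed."""

    grid: GridSpec = field(default_factory=GridSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    output_dir: str = "results"
    log_level: str = "INFO"
    schema_version: int = 1


def write_config(config: RunConfig, path) -> None:
    """Serialize a run configuration as versioned YAML (deterministic)."""
    payload = dataclasses.asdict(config)
    payload["trajectory"]["hours"] = list(config.trajectory.hours)
    payload["fit"]["free_parameters"] = list(config.fit.free_parameters)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_config(path) -> RunConfig:
    """Load a YAML run configuration, rebuilding the nested dataclasses."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if payload.get("schema_version", 1) != 1:
        raise ValueError(f"{path}: unsupported schema_version {payload['schema_version']}")
    fit = dict(payload["fit"])
    fit["bounds"] = ParameterBounds(**fit["bounds"])
    fit["free_parameters"] = tuple(fit["free_parameters"])
    trajectory = dict(payload["trajectory"])
    trajectory["hours"] = tuple(trajectory["hours"])
    trajectory["baseline"] = DSMParams(**trajectory["baseline"])
    return RunConfig(
        grid=GridSpec(**payload["grid"]),
        fit=FitConfig(**fit),
        trajectory=TrajectoryConfig(**trajectory),
        noise=NoiseConfig(**payload["noise"]),
        output_dir=payload["output_dir"],
        log_level=payload["log_level"],
        schema_version=payload["schema_version"],
    )
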