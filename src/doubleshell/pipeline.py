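"""Study orchestration: simulate -> aggregate -> fit -> report.

Runs the 4-plant, 16-hour design end to end, producing one fit per
(plant, hour), per-parameter cross-plant averages and the summary
resistance ratios r1/r2, r1/r4, r2/r4 (ratios of grand-mean resistances
over converged fits).  Plants are processed independently; a per-plant
failure flags that plant's rows and never aborts the study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import ReplicateSweepSet
from .circuit import PARAM_NAMES
from .fitting import FitResult, fit_timeseries
from .simulate import simulate_study
from .sweep_io import RunConfig, read_sweeps, write_fits, write_sweeps

__all__ = ["StudyResult", "run_study", "summarize_ratios", "write_summary"]

_PARAM_COLUMNS = {"r1": "r1_ohm", "r2": "r2_ohm", "r4": "r4_ohm", "c3": "c3_farad", "c5": "c5_farad"}


@dataclass
class StudyResult:
    """Fitted trajectories plus cross-plant summary of one study run."""

    fits: pd.DataFrame  # one row per (plant, hour)
    results: list[FitResult]
    ratios: dict[str, float]
    grand_means: dict[str, float]  # over converged fits
    n_excluded: int  # non-converged fits excluded from the averages
    truth: dict | None = None  # generating parameters when simulated


def _fits_dataframe(results: list[FitResult]) -> pd.DataFrame:
    rows = []
    for r in sorted(results, key=lambda r: (r.plant or 0, r.hour or 0)):
        row = {"plant": r.plant, "hour": r.hour}
        for name, col in _PARAM_COLUMNS.items():
            row[col] = getattr(r.params, name) if r.params is not None else math.nan
        row.update(
            error_ohm=r.final_error,
            relative_error=r.relative_error,
            n_evals=r.n_evals,
            converged=r.converged,
            message=r.message,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_ratios(fits) -> tuple[float, float, float]:
    """Resistance ratios (r1/r2, r1/r4, r2/r4) of grand-mean resistances.

    The grand mean pools every converged (plant, hour) fit — ratio of
    means, not mean of ratios, matching how the study reports one average
    resistance per parameter and then their quotients.
    """
    if isinstance(fits, list):
        fits = _fits_dataframe(fits)
    converged = fits[fits["converged"].astype(bool)]
    if converged.empty:
        raise ValueError("no converged fits: ratios are undefined")
    r1, r2, r4 = (float(converged[c].mean()) for c in ("r1_ohm", "r2_ohm", "r4_ohm"))
    return r1 / r2, r1 / r4, r2 / r4


def run_study(
    config: RunConfig | None = None,
    input_path=None,
    seed: int | None = None,
    output_dir=None,
    plots: bool = False,
) -> StudyResult:
    """Execute the full chain for every plant.

    ``input_path`` reads instrument-style sweeps from CSV; otherwise the
    study is simulated from ``config.trajectory``/``config.noise`` (with
    ``seed`` overriding the configured noise seed).  With ``output_dir``
    set, writes ``sweeps.csv`` (simulated runs), ``fits.csv`` and
    ``summary.csv`` — byte-deterministic for a fixed config and seed —
    plus trajectory/spectrum plots when ``plots=True``.
    """
    config = config or RunConfig()
    truth = None
    if input_path is not None:
        sweep_sets = read_sweeps(input_path)
    else:
        sweep_sets, truth = simulate_study(
            config.trajectory, config.noise, config.grid.build(), seed=seed
        )

    by_plant: dict[int, list[ReplicateSweepSet]] = {}
    for s in sweep_sets:
        by_plant.setdefault(s.plant, []).append(s)

    results: list[FitResult] = []
    for plant in sorted(by_plant):
        try:
            results.extend(fit_timeseries(by_plant[plant], config.fit))
        except Exception as exc:  # noqa: BLE001 — isolate per-plant failures
            for s in by_plant[plant]:
                results.append(
                    FitResult(
                        plant=s.plant,
                        hour=s.hour,
                        params=None,
                        final_error=math.nan,
                        relative_error=math.nan,
                        n_evals=0,
                        converged=False,
                        message=f"plant failed: {exc}",
                    )
                )

    fits = _fits_dataframe(results)
    converged = fits[fits["converged"].astype(bool)]
    n_excluded = int(len(fits) - len(converged))
    if converged.empty:
        ratios = {k: math.nan for k in ("r1_over_r2", "r1_over_r4", "r2_over_r4")}
        grand_means = {name: math.nan for name in PARAM_NAMES}
    else:
        r12, r14, r24 = summarize_ratios(fits)
        ratios = {"r1_over_r2": r12, "r1_over_r4": r14, "r2_over_r4": r24}
        grand_means = {
            name: float(converged[col].mean()) for name, col in _PARAM_COLUMNS.items()
        }

    result = StudyResult(
        fits=fits,
        results=results,
        ratios=ratios,
        grand_means=grand_means,
        n_excluded=n_excluded,
        truth=truth,
    )

    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        if input_path is None:
            write_sweeps(sweep_sets, outdir / "sweeps.csv")
        write_fits(results, outdir / "fits.csv")
        write_summary(result, outdir / "summary.csv")
        if plots:
            plot_trajectories(result, outdir / "trajectories.png")
            plot_spectra(sweep_sets, outdir / "spectra.png")
    return result


def write_summary(result: StudyResult, path) -> None:
    """Summary CSV: grand mean and per-plant means per parameter + ratios."""
    fits = result.fits
    converged = fits[fits["converged"].astype(bool)]
    plants = sorted(p for p in fits["plant"].dropna().unique())
    rows = []
    for name, col in _PARAM_COLUMNS.items():
        row = {"parameter": name, "grand_mean": result.grand_means[name]}
        for plant in plants:
            sub = converged[converged["plant"] == plant]
            row[f"plant_{int(plant)}_mean"] = float(sub[col].mean()) if len(sub) else math.nan
        rows.append(row)
    for key, value in result.ratios.items():
        rows.append({"parameter": key, "grand_mean": value})
    rows.append({"parameter": "n_excluded_fits", "grand_mean": result.n_excluded})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def plot_trajectories(result: StudyResult, path) -> None:
    """Five-panel figure of fitted (and true, if known) parameter trajectories."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    units = {"r1": "MΩ", "r2": "MΩ", "r4": "MΩ", "c3": "pF", "c5": "pF"}
    scale = {"r1": 1e-6, "r2": 1e-6, "r4": 1e-6, "c3": 1e12, "c5": 1e12}
    fig, axes = plt.subplots(1, 5, figsize=(20, 3.5))
    for ax, name in zip(axes, PARAM_NAMES):
        col = _PARAM_COLUMNS[name]
        for plant, sub in result.fits.groupby("plant"):
            ax.plot(sub["hour"], sub[col] * scale[name], "o-", ms=3, label=f"plant {plant}")
        if result.truth:
            for plant, by_hour in result.truth.items():
                hours = sorted(by_hour)
                ax.plot(
                    hours,
                    [getattr(by_hour[h], name) * scale[name] for h in hours],
                    "k--",
                    lw=0.8,
                )
        ax.set_xlabel("hour of day")
        ax.set_ylabel(f"{name} ({units[name]})")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectra(sweep_sets: list[ReplicateSweepSet], path, plant: int = 1) -> None:
    """Resistance and reactance vs frequency for one plant, all hours."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .aggregate import mean_spectrum

    fig, (ax_r, ax_x) = plt.subplots(1, 2, figsize=(10, 4))
    for s in sweep_sets:
        if s.plant != plant:
            continue
        ms = mean_spectrum(s).spectrum
        f = ms.grid.frequencies
        ax_r.semilogx(f, ms.resistance * 1e-6, lw=0.8)
        ax_x.semilogx(f, ms.reactance * 1e-6, lw=0.8)
    ax_r.set_xlabel("frequency (Hz)")
    ax_r.set_ylabel("resistance (MΩ)")
    ax_x.set_xlabel("frequency (Hz)")
    ax_x.set_ylabel("reactance (MΩ)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
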