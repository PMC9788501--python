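"""Synthetic 16-hour leaf-monitoring study generator.

Emulates the study design exactly: four plants, hourly sampling from hour 5
to hour 20, five successive replicate sweeps per (plant, hour), 201
log-spaced frequencies on 500 Hz–300 kHz.  Two scheduled events drive the
ground-truth parameter trajectories:

* **water uptake** at hour 5.5 — a step increase of the resistances and
  decrease of the capacitances, fully applied by hour 6 (turgor recovery
  raises extracellular and cytoplasmic resistance);
* **LED on** at hour 7.5 — exponential relaxation of every parameter
  toward a hydrated, illuminated target (gradual resistance decrease and
  capacitance increase while the light drives photosynthesis).

The vacuole resistance ``r4`` gets deliberately smaller multipliers: the
study observed only minor changes in it.

Measurement noise is an explicit model assumption (the study discusses
electrode-contact error only qualitatively): each replicate sweep is the
true spectrum times a per-replicate contact scale (one Gaussian scalar,
sd 2%) with independent per-point multiplicative Gaussian noise (sd 1%) on
resistance and reactance.  Multiplicative noise preserves the sign of both
components; any draw that would flip a sign is redrawn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .aggregate import ReplicateSweepSet
from .circuit import DSMParams, FrequencyGrid, ImpedanceSpectrum, default_grid, dsm_impedance

__all__ = [
    "TrajectoryConfig",
    "NoiseConfig",
    "default_truth",
    "simulate_trajectory",
    "simulate_measurements",
    "simulate_study",
]


def default_truth() -> DSMParams:
    """Study-average circuit parameters used as the simulator baseline.

    Resistances are the study-average values for dehydrated lettuce
    leaves (R1 = 159.07 MΩ, R2 = 4.76 MΩ, R4 = 1.49 MΩ).  No comparable
    average pins the capacitances; they are chosen so that both membrane
    relaxations fall inside the
    500 Hz–300 kHz analysis band — otherwise they would be unidentifiable
    from the sweeps and recovery tests would be vacuous:
    C3 = 0.5 pF puts the plasma-membrane dispersion at
    1/(2π·R1·C3) ≈ 2.0 kHz, and C5 = 1 pF puts the tonoplast dispersion at
    1/(2π·(R2+R4)·C5) ≈ 25 kHz.
    """
    return DSMParams(r1=159.07e6, r2=4.76e6, r4=1.49e6, c3=0.5e-12, c5=1.0e-12)


def _uniform_rates(rate: float) -> dict[str, float]:
    return {name: rate for name in ("r1", "r2", "r4", "c3", "c5")}


@dataclass
class TrajectoryConfig:
    """Ground-truth parameter trajectories and event schedule.

    Defaults are the study conditions: hours 5..20, watering at hour 5.5,
    LED on at hour 7.5, four plants.  Multipliers are relative to the
    dehydrated baseline; the LED relaxation runs at ``relaxation_rates``
    (1/h) toward ``baseline * target_multipliers``.
    """

    hours: tuple = tuple(range(5, 21))
    baseline: DSMParams = field(default_factory=default_truth)
    water_event_hour: float = 5.5
    water_multipliers: dict = field(
        default_factory=lambda: {"r1": 1.4, "r2": 1.4, "r4": 1.15, "c3": 0.7, "c5": 0.7}
    )
    led_event_hour: float = 7.5
    relaxation_rates: dict = field(default_factory=lambda: _uniform_rates(0.15))
    target_multipliers: dict = field(
        default_factory=lambda: {"r1": 0.8, "r2": 0.8, "r4": 0.95, "c3": 1.15, "c5": 1.15}
    )
    n_plants: int = 4
    plant_jitter_sd: float = 0.0  # log-normal impedance-scale spread across plants

    def __post_init__(self) -> None:
        self.hours = tuple(sorted(self.hours))
        if not self.hours:
            raise ValueError("hours must be non-empty")
        lo, hi = min(self.hours), max(self.hours)
        for label, h in (("water", self.water_event_hour), ("led", self.led_event_hour)):
            if not lo <= h <= hi:
                raise ValueError(f"{label} event hour {h} outside measured hours [{lo}, {hi}]")
        for mapping in (self.water_multipliers, self.target_multipliers):
            if any(v <= 0 for v in mapping.values()):
                raise ValueError("multipliers must be strictly positive")
        if any(v < 0 for v in self.relaxation_rates.values()):
            raise ValueError("relaxation rates must be non-negative")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.plant_jitter_sd < 0:
            raise ValueError("plant_jitter_sd must be non-negative")


@dataclass
class NoiseConfig:
    """Replicate measurement-noise model (simulator plumbing)."""

    point_sd: float = 0.01  # per-point multiplicative sd on R and X
    contact_sd: float = 0.02  # per-replicate contact scale sd
    n_replicates: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.point_sd < 0 or self.contact_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _params_at_hour(baseline: DSMParams, config: TrajectoryConfig, hour: float) -> DSMParams:
    if hour < config.water_event_hour:
        return baseline
    watered = {
        name: getattr(baseline, name) * config.water_multipliers[name]
        for name in ("r1", "r2", "r4", "c3", "c5")
    }
    if hour < config.led_event_hour:
        return DSMParams(**watered)
    dt = hour - config.led_event_hour
    values = {}
    for name, post_water in watered.items():
        target = getattr(baseline, name) * config.target_multipliers[name]
        decay = math.exp(-config.relaxation_rates[name] * dt)
        values[name] = target + (post_water - target) * decay
    return DSMParams(**values)


def simulate_trajectory(
    config: TrajectoryConfig | None = None, seed: int | None = None
) -> dict[int, dict[int, DSMParams]]:
    """True per-hour parameters for every plant.

    Piecewise trajectory per parameter: baseline before the water event, a
    step to ``baseline * water_multipliers`` at the first measured hour
    after it, then exponential relaxation toward the hydrated target once
    the LED is on.  Plants are indexed 1..n_plants; with
    ``plant_jitter_sd > 0`` each plant's whole impedance is scaled by a
    seeded log-normal factor (resistances multiplied, capacitances
    divided), reproducing plant-to-plant dynamic-range differences.
    """
    config = config or TrajectoryConfig()
    truth: dict[int, dict[int, DSMParams]] = {}
    for plant in range(1, config.n_plants + 1):
        if config.plant_jitter_sd > 0:
            rng = np.random.default_rng([0 if seed is None else seed, plant])
            scale = float(np.exp(rng.normal(0.0, config.plant_jitter_sd)))
            base = config.baseline.scale_impedance(scale)
        else:
            base = config.baseline
        truth[plant] = {h: _params_at_hour(base, config, h) for h in config.hours}
    return truth


def _positive_factors(rng: np.random.Generator, sd: float, size=None) -> np.ndarray:
    """1 + Gaussian(0, sd) draws, redrawing any factor that is not positive."""
    if sd == 0.0:
        return np.ones(size) if size is not None else 1.0
    factors = 1.0 + rng.normal(0.0, sd, size)
    if size is None:
        while factors <= 0.0:
            factors = 1.0 + rng.normal(0.0, sd)
        return factors
    bad = factors <= 0.0
    while np.any(bad):
        factors[bad] = 1.0 + rng.normal(0.0, sd, int(bad.sum()))
        bad = factors <= 0.0
    return factors


def simulate_measurements(
    truth: Mapping[int, DSMParams],
    grid: FrequencyGrid | None = None,
    noise: NoiseConfig | None = None,
    plant: int = 1,
    seed: int | None = None,
) -> list[ReplicateSweepSet]:
    """Noisy replicate sweeps for one plant's per-hour true parameters.

    Per replicate, the true spectrum is multiplied by one contact-scale
    factor and then by independent per-point factors on resistance and
    reactance.  Reproducible: the generator for each (plant, hour) cell is
    seeded with ``[seed, plant, hour]``, so a plant's data do not depend on
    which other plants are simulated.
    """
    grid = grid or default_grid()
    noise = noise or NoiseConfig()
    base_seed = noise.rng_seed if seed is None else seed
    sets = []
    for hour in sorted(truth):
        true_spectrum = dsm_impedance(truth[hour], grid)
        rng = np.random.default_rng([base_seed, plant, hour])
        replicates = []
        for _ in range(noise.n_replicates):
            contact = _positive_factors(rng, noise.contact_sd)
            r = true_spectrum.resistance * contact * _positive_factors(
                rng, noise.point_sd, len(grid)
            )
            x = true_spectrum.reactance * contact * _positive_factors(
                rng, noise.point_sd, len(grid)
            )
            replicates.append(ImpedanceSpectrum(grid, r, x))
        sets.append(ReplicateSweepSet(plant=plant, hour=hour, replicates=replicates))
    return sets


def simulate_study(
    trajectory: TrajectoryConfig | None = None,
    noise: NoiseConfig | None = None,
    grid: FrequencyGrid | None = None,
    seed: int | None = None,
):
    """Full synthetic study: all plants, all hours.

    Returns ``(sweep_sets, truth)`` where ``sweep_sets`` is a flat list of
    :class:`ReplicateSweepSet` (ordered by plant, then hour) and ``truth``
    the generating parameters from :func:`simulate_trajectory`.
    """
    trajectory = trajectory or TrajectoryConfig()
    noise = noise or NoiseConfig()
    grid = grid or default_grid()
    truth = simulate_trajectory(trajectory, seed=seed)
    sets: list[ReplicateSweepSet] = []
    for plant in sorted(truth):
        sets.extend(simulate_measurements(truth[plant], grid, noise, plant=plant, seed=seed))
    return sets, truth
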