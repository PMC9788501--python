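"""Double-shell equivalent-circuit forward model for plant tissue impedance.

The double-shell model (DSM) describes a plant cell as five lumped elements:

* ``r1`` — resistance of the cell wall and extracellular fluid (ECF), Ω
* ``r2`` — cytoplasmic resistance, Ω
* ``r4`` — vacuole resistance, Ω
* ``c3`` — plasma-membrane capacitance, F
* ``c5`` — vacuolar-membrane (tonoplast) capacitance, F

The extracellular resistor ``r1`` sits in parallel with the intracellular
ladder: the plasma-membrane capacitor ``c3`` in series with the cytoplasm
resistor ``r2``, which is itself in parallel with the series pair of the
tonoplast capacitor ``c5`` and the vacuole resistor ``r4``::

    Z(w) = [ 1/r1 + 1/Z_intra(w) ]^-1
    Z_intra(w) = 1/(j w c3) + r2 (r4 + 1/(j w c5)) / (r2 + r4 + 1/(j w c5))

At DC both capacitors are open and only the extracellular path conducts, so
``Z -> r1``; at infinite frequency both membranes are shorted and the three
resistors conduct in parallel, ``Z -> (1/r1 + 1/r2 + 1/r4)^-1``.  In between,
each membrane capacitance produces one dispersion (a transition between
resistive plateaus).

Elementary relations used throughout the package:

* impedance ``Z(w) = R(w) + j XC(w)`` with resistance ``R`` and (negative,
  capacitive) reactance ``XC``;
* capacitive reactance ``XC = -1/(2 pi f C)``;
* phase angle ``theta = arctan(XC / R)`` (radians internally, degrees in
  human-readable reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PARAM_UNITS",
    "ParameterBounds",
    "DSMParams",
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "default_grid",
    "capacitive_reactance",
    "phase_angle",
    "dsm_impedance",
    "model_limits",
]

_TWO_PI = 2.0 * math.pi

#: Canonical coordinate order of the five circuit parameters.
PARAM_NAMES = ("r1", "r2", "r4", "c3", "c5")

PARAM_UNITS = {"r1": "ohm", "r2": "ohm", "r4": "ohm", "c3": "farad", "c5": "farad"}


@dataclass(frozen=True)
class ParameterBounds:
    """Physical box constraints on the five circuit parameters.

    Defaults cover plant-tissue measurements with macroscopic electrodes:
    resistances in [1 kΩ, 1 TΩ], capacitances in [0.1 pF, 1 µF].
    """

    r_min: float = 1e3
    r_max: float = 1e12
    c_min: float = 1e-13
    c_max: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max and 0 < self.c_min < self.c_max):
            raise ValueError("bounds must satisfy 0 < lower < upper")

    def lower(self, name: str) -> float:
        return self.r_min if name.startswith("r") else self.c_min

    def upper(self, name: str) -> float:
        return self.r_max if name.startswith("r") else self.c_max

    def contains(self, params: "DSMParams") -> bool:
        return all(
            self.lower(n) <= getattr(params, n) <= self.upper(n) for n in PARAM_NAMES
        )

    def clip(self, name: str, value: float) -> float:
        return min(max(value, self.lower(name)), self.upper(name))


@dataclass(frozen=True)
class DSMParams:
    """The five double-shell circuit parameters at one time point.

    All values must be strictly positive and finite; whether they lie inside
    a particular :class:`ParameterBounds` box is checked by the consumer
    (the fitter discards out-of-bounds candidates, the simulator validates
    its ground truth).
    """

    r1: float
    r2: float
    r4: float
    c3: float
    c5: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            try:
                value = float(value)
            except (TypeError, ValueError):
                raise ValueError(f"{name} must be a number, got {value!r}") from None
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
            object.__setattr__(self, name, value)

    def as_array(self) -> np.ndarray:
        """Parameter vector in canonical order (r1, r2, r4, c3, c5)."""
        return np.array([self.r1, self.r2, self.r4, self.c3, self.c5])

    @classmethod
    def from_array(cls, values) -> "DSMParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ValueError(f"expected 5 parameters, got shape {values.shape}")
        return cls(*values.tolist())

    def replace(self, **changes: float) -> "DSMParams":
        return _dc_replace(self, **changes)

    def scale_impedance(self, factor: float) -> "DSMParams":
        """Scale the whole impedance by ``factor``.

        Multiplying every resistance by ``factor`` and dividing every
        capacitance by it multiplies Z(w) by ``factor`` at all frequencies.
        """
        return DSMParams(
            self.r1 * factor,
            self.r2 * factor,
            self.r4 * factor,
            self.c3 / factor,
            self.c5 / factor,
        )


class FrequencyGrid:
    """Strictly increasing sweep frequencies (Hz) with angular frequencies.

    Parameters
    ----------
    frequencies : array_like
        Strictly increasing, strictly positive frequencies in Hz.
    """

    __slots__ = ("frequencies", "omega")

    def __init__(self, frequencies) -> None:
        f = np.array(frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0.0):
            raise ValueError("frequencies must be finite and strictly positive")
        if np.any(np.diff(f) <= 0.0):
            raise ValueError("frequencies must be strictly increasing (no duplicates)")
        f.setflags(write=False)
        self.frequencies = f
        omega = _TWO_PI * f
        omega.setflags(write=False)
        self.omega = omega

    def __len__(self) -> int:
        return self.frequencies.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return np.array_equal(self.frequencies, other.frequencies)

    def __hash__(self) -> int:  # consistent with value equality
        return hash(self.frequencies.tobytes())

    def __repr__(self) -> str:
        f = self.frequencies
        return f"FrequencyGrid({len(self)} points, {f[0]:g}..{f[-1]:g} Hz)"


def default_grid(
    n_points: int = 201, f_min: float = 500.0, f_max: float = 3.0e5
) -> FrequencyGrid:
    """The study's analysis sweep: 201 log-spaced points on 500 Hz–300 kHz.

    The instrument itself scans 20 Hz–300 kHz; pass ``f_min=20.0`` for the
    full instrument band.
    """
    return FrequencyGrid(np.logspace(math.log10(f_min), math.log10(f_max), n_points))


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Paired frequency / complex-impedance samples for one sweep.

    ``resistance`` holds the real part R(w) and ``reactance`` the imaginary
    part XC(w), both in Ω.  Model-generated spectra always satisfy
    ``resistance > 0`` and ``reactance <= 0``; measured (noisy) spectra are
    stored as-is.
    """

    grid: FrequencyGrid
    resistance: np.ndarray
    reactance: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.resistance, dtype=float)
        x = np.asarray(self.reactance, dtype=float)
        if r.shape != (len(self.grid),) or x.shape != (len(self.grid),):
            raise ValueError(
                "resistance and reactance must match the grid length "
                f"({len(self.grid)}); got {r.shape} and {x.shape}"
            )
        object.__setattr__(self, "resistance", r)
        object.__setattr__(self, "reactance", x)

    @property
    def z(self) -> np.ndarray:
        """Complex impedance Z = R + j·XC per frequency."""
        return self.resistance + 1j * self.reactance

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.resistance, self.reactance)

    @property
    def phase_rad(self) -> np.ndarray:
        return np.arctan2(self.reactance, self.resistance)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(self.phase_rad)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ImpedanceSpectrum):
            return NotImplemented
        return (
            self.grid == other.grid
            and np.array_equal(self.resistance, other.resistance)
            and np.array_equal(self.reactance, other.reactance)
        )


def capacitive_reactance(f, c):
    """Reactance XC = -1/(2 pi f C) of a capacitance ``c`` (F) at ``f`` (Hz).

    Always strictly negative; vectorized over either argument.
    """
    f = np.asarray(f, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0.0):
        raise ValueError("frequency f must be finite and strictly positive")
    if np.any(~np.isfinite(c)) or np.any(c <= 0.0):
        raise ValueError("capacitance c must be finite and strictly positive")
    return -1.0 / (_TWO_PI * f * c)


def phase_angle(resistance, reactance, degrees: bool = False):
    """Phase angle theta = arctan(XC / R).

    Radians by default; ``degrees=True`` for reports.  The quotient is
    undefined at R = 0, and negative resistances are unphysical here, so
    both raise.
    """
    r = np.asarray(resistance, dtype=float)
    x = np.asarray(reactance, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("resistance must be strictly positive (theta undefined at R = 0)")
    theta = np.arctan(x / r)
    return np.degrees(theta) if degrees else theta


def _dsm_impedance_array(r1, r2, r4, c3, c5, omega: np.ndarray) -> np.ndarray:
    """Complex DSM impedance at angular frequencies ``omega``.

    Parameters may be scalars or broadcastable arrays (used for vectorized
    candidate screening).  The intracellular branch is combined through one
    guarded parallel product so in-bounds inputs never produce non-finite
    output across the full double-precision frequency range.
    """
    jw = 1j * omega
    z_c3 = 1.0 / (jw * c3)
    z_inner = r4 + 1.0 / (jw * c5)  # vacuole + tonoplast in series
    z_cyto = (r2 * z_inner) / (r2 + z_inner)  # parallel with the cytoplasm
    z_intra = z_c3 + z_cyto
    return 1.0 / (1.0 / r1 + 1.0 / z_intra)


def dsm_impedance(params: DSMParams, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate the double-shell circuit on a frequency grid.

    Returns a spectrum satisfying passivity (``Re Z > 0``, ``Im Z <= 0``)
    and ``|Z| <= r1`` at every frequency: the total admittance has real part
    at least ``1/r1`` because the extracellular resistor is always in
    parallel with the (passive) intracellular ladder.
    """
    z = _dsm_impedance_array(params.r1, params.r2, params.r4, params.c3, params.c5, grid.omega)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite impedance from in-bounds parameters")
    return ImpedanceSpectrum(grid, z.real, z.imag)


def model_limits(params: DSMParams) -> tuple[float, float]:
    """Low- and high-frequency resistive limits of the circuit.

    Returns ``(r1, (1/r1 + 1/r2 + 1/r4)^-1)``: at DC only the extracellular
    path conducts; at infinite frequency both membranes short and the three
    resistors conduct in parallel.  Used for fit initialization and sanity
    checks.
    """
    high = 1.0 / (1.0 / params.r1 + 1.0 / params.r2 + 1.0 / params.r4)
    return params.r1, high
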