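"""Replicate averaging of successive sweeps.

Each (plant, hour) cell of the study holds N successive replicate sweeps
(N = 5 in the study design), taken to average out electrode contact error.
The mean spectrum is the plain arithmetic mean of the replicate resistances
and reactances per frequency — no trimming, no weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import ImpedanceSpectrum

__all__ = ["ReplicateSweepSet", "MeanSpectrum", "mean_spectrum"]


@dataclass
class ReplicateSweepSet:
    """The N replicate sweeps measured for one (plant, hour) cell."""

    plant: int
    hour: int
    replicates: list[ImpedanceSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(
                f"plant {self.plant} hour {self.hour}: at least one replicate required"
            )
        grid = self.replicates[0].grid
        for i, rep in enumerate(self.replicates[1:], start=2):
            if rep.grid != grid:
                raise ValueError(
                    f"plant {self.plant} hour {self.hour}: replicate {i} has a "
                    "different frequency grid than replicate 1"
                )

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def grid(self):
        return self.replicates[0].grid


@dataclass
class MeanSpectrum:
    """Replicate-averaged spectrum for one (plant, hour) cell."""

    plant: int
    hour: int
    spectrum: ImpedanceSpectrum


def mean_spectrum(replicates: ReplicateSweepSet) -> MeanSpectrum:
    """Average the replicate sweeps into one spectrum.

    Per frequency, the output resistance is the arithmetic mean of the
    replicate resistances and likewise for the reactances; the actual
    replicate count N is used, so incomplete cells (N < 5) average over
    whatever was measured.
    """
    reps = replicates.replicates
    # anchored at the first replicate so N identical sweeps average exactly
    r = reps[0].resistance + np.mean([rep.resistance - reps[0].resistance for rep in reps], axis=0)
    x = reps[0].reactance + np.mean([rep.reactance - reps[0].reactance for rep in reps], axis=0)
    return MeanSpectrum(
        replicates.plant, replicates.hour, ImpedanceSpectrum(replicates.grid, r, x)
    )
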