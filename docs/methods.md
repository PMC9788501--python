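# Methods

## Circuit model

The double-shell model treats a leaf-tissue sample between two electrodes
as five lumped elements: cell-wall/extracellular resistance R1 (Ω),
cytoplasm resistance R2 (Ω), vacuole resistance R4 (Ω), plasma-membrane
capacitance C3 (F) and tonoplast capacitance C5 (F).  The wiring is the
classic double-shell ladder: R1 in parallel with
[C3 in series with (R2 ∥ (C5 in series with R4))].  This topology
reproduces the two expected behaviours: at low frequency current is
confined to the extracellular fluid (Z → R1), and at high frequency both
membranes are transparent so all three resistors conduct
(Z → (1/R1 + 1/R2 + 1/R4)⁻¹, dominated by the smallest resistance — the
vacuole).  The impedance is evaluated in double precision with the
intracellular branch combined through a guarded parallel product; the
admittance form keeps the evaluation finite from sub-µHz to THz for any
in-bounds parameters.  An alternative wiring (fully series intracellular
branch) would change the high-frequency limit to R1 ∥ (R2 + R4); the
topology is isolated in one function (`circuit._dsm_impedance_array`) so
it can be swapped if a different variant is needed.

Sign conventions: capacitive reactance is stored negative,
X_C = −1/(2πfC); phase angles are radians internally and degrees in
reports.  Model spectra satisfy passivity (Re Z > 0, Im Z ≤ 0) and
|Z| ≤ R1 (the total admittance has real part ≥ 1/R1); both are enforced
by property tests over the full physical parameter box
(resistances 1 kΩ–1 TΩ, capacitances 0.1 pF–1 µF).

## Replicate averaging

Each (plant, hour) cell holds N successive sweeps (N = 5 by design),
taken to average out electrode-contact error.  The mean spectrum is the
plain per-frequency arithmetic mean of resistance and reactance — no
trimming, weighting or outlier rejection — computed anchored at the first
replicate so that N identical sweeps average to exactly themselves.
Incomplete cells are averaged over the actual N.

## Fitting

The objective is the absolute impedance error Z′err = Σ_f |Zm − Ze|
(complex modulus of the difference; an |ΔR| + |ΔX| variant is available
via `FitConfig.error_metric="components"` for sensitivity analysis).

The optimizer is a pattern search over the five coordinates:

* **Step semantics.** Steps are multiplicative: a candidate moves one
  coordinate by α·(current value)·direction, direction ∈ {−1, +1}.  A
  dimensionless percentage step is the only way a single scalar α can be
  meaningful across parameters spanning 18 orders of magnitude.
* **Acceptance.** All ten proposals are evaluated and the single best
  strictly-improving one is taken (best-improvement, not Gauss–Seidel);
  ties break by the fixed order r1, r2, r4, c3, c5, then +1 before −1.
* **Line search.** The accepted move is extended by successive doubling
  of the step fraction (2α, 4α, …) while the error strictly decreases and
  bounds hold.
* **Schedule.** α starts at 10% and divides by 10 whenever a full
  screening pass finds no improvement, down to the 0.1% floor.
* **Termination and acceptance threshold.** By default the search runs
  until the step floor (or the 10,000-evaluation budget) and the
  threshold — default 2.1% of Σ_f |Zm|, configurable in relative or
  absolute mode — acts as the *fit-acceptance* condition
  (`converged = final error < threshold`).  The alternative reading, in
  which the loop exits as soon as the error crosses the threshold, is
  available as `FitConfig.stop_at_threshold=True`; it is not the default
  because the error sum is dominated by the low-frequency plateau, so an
  early exit leaves the weakly weighted parameters (R4, C5 — a few
  percent of the error sum) essentially wherever they started, which
  defeats trajectory monitoring.
* **Bounds.** Out-of-bounds candidates are discarded, never projected,
  so accepted iterates always satisfy the physical box.

Out of scope by design: gradient-based or global optimizers as the
primary path (a dense grid search appears only as a test oracle),
constant-phase elements, Cole–Cole dispersion, electrode-polarization
correction, and uncertainty quantification (point estimates only).

### Initialization

Hours are fitted in order.  With two or more previous fits each parameter
is linearly extrapolated from the last two (clamped to bounds); with one
it is reused.  The cold start (first hour) reads R1 off the low-frequency
plateau |Z|(f_min), seeds R2 and R4 from the |Z| value at the highest
frequency split by the average cytoplasm-to-vacuole resistance ratio
(R2/R4 ≈ 3.19), and screens a log grid of
(intracellular-conductance scale, C3, C5) combinations, keeping the
lowest-error one.  Two details matter:

* the sweep ends before the high-frequency plateau is reached, so
  |Z|(f_max) overestimates the plateau (by ~58% at the default
  parameters); the scale axis of the screen (×0.32 … ×3.2) absorbs that
  bias;
* screened capacitances are restricted to values whose relaxation
  frequency 1/(2πRC) lies inside the measured band.  A capacitance
  relaxing outside the band is unidentifiable from the sweep, and the
  out-of-band corners of the screen contain degenerate one-dispersion
  lookalikes (e.g. a fully shorted tonoplast) that trap the subsequent
  search in ~2.6%-misfit local minima.

## Synthetic study generator

The generator emulates the study design exactly: 4 plants, hourly sweeps
from hour 5 to hour 20, 5 replicates per cell, 201 log-spaced frequencies
on 500 Hz–300 kHz (the instrument band extends to 20 Hz and is available
via `GridSpec`).

**Baseline.** The dehydrated baseline uses the study-average resistances
R1 = 159.07 MΩ, R2 = 4.76 MΩ, R4 = 1.49 MΩ.  The capacitances were never
reported and are chosen as C3 = 0.5 pF, C5 = 1 pF so that both membrane
relaxations fall inside the band (1/(2πR1C3) ≈ 2.0 kHz,
1/(2π(R2+R4)C5) ≈ 25.5 kHz); with out-of-band capacitances those
parameters would be unidentifiable and every recovery test vacuous.
Sub-picofarad values are the expected scale for a two-electrode leaf
measurement at 3 cm spacing (small effective membrane area in series).

**Events.** Watering at hour 5.5 steps the parameters to
baseline × water multipliers, fully applied by hour 6 (defaults: R1, R2
×1.4; R4 ×1.15; C3, C5 ×0.7 — turgor recovery raises resistances and
lowers capacitances, with only minor vacuole changes).  LED-on at hour
7.5 starts an exponential relaxation at 0.15/h toward a hydrated,
illuminated target (defaults: R1, R2 ×0.8; R4 ×0.95; C3, C5 ×1.15).
Before the water event nothing changes.  These shapes reproduce the
observed phenomenology — the rapid post-watering resistance rise and
capacitance drop, then the gradual reversal under light — as qualitative
trajectory shapes only; no turgor or ion-transport physics is modelled.

**Noise.** Each replicate sweep is the true spectrum multiplied by one
Gaussian contact-scale factor (sd 2%, one scalar per replicate,
mimicking electrode-contact variability) and by independent per-point
multiplicative Gaussian factors (sd 1%) on resistance and reactance.
Draws that would flip a sign are redrawn.  Per-(plant, hour) generator
streams are seeded as [seed, plant, hour], so any plant's data are
independent of which other plants are simulated.  An optional per-plant
log-normal impedance-scale jitter (off by default) reproduces
plant-to-plant dynamic-range differences.

**What the simulator does not emulate** — and hence what passing tests do
not demonstrate about real leaves: electrode polarization, temperature
drift, fringe effects, frequency-correlated instrument error, drift
across the five replicates, and any real turgor dynamics.  In particular
the noise model is exactly the family the circuit can absorb (the contact
scale is a pure impedance scale), so real-data misfits will be larger
than the simulated ones.

## Numerical choices

* Error evaluations are vectorized over the grid; candidate screens and
  grid oracles are vectorized over parameter sets in chunks.
* The search is fully deterministic given (spectrum, init, config); the
  only randomness in the package is the simulator's, always behind an
  explicit seed.
* CSV writers sort rows (plant, hour, replicate, frequency), write floats
  with 17 significant digits, and produce byte-identical files for equal
  inputs; readers parse with correctly-rounded floats, so
  read(write(x)) = x bit-exactly.  YAML run configs round-trip every
  field and carry a schema version.
* Study summaries pool converged fits only (the excluded count is
  reported) and compute resistance ratios as ratios of grand means over
  all plants and hours — ratio of means, not mean of ratios.

## Measured behaviour at the default settings

(all recomputed by `scripts/acceptance.py` and the test suite at run
time): noiseless recovery from inits up to ×2 off succeeds for all five
parameters within 1%; with the default noise the median per-parameter
error over 20 seeds is ≈1% and the achieved relative misfit is ≈0.4% —
the replicate-averaged noise floor E|ΔZ|/Σ|Z| ≈ 0.85·0.01/√5.  Fitted
16-hour trajectories track the generating ones with rank correlation
> 0.95 per plant and parameter.

## Known limitations

* The pattern search is local; pathological cold starts can still end in
  a local minimum (flagged `converged=False`), and no multi-start is
  attempted by default.
* With the threshold interpreted as an early-stopping rule
  (`stop_at_threshold=True`), weakly weighted parameters are left near
  their initialization; use it only when runtime matters more than R4/C5
  accuracy.
* The unweighted absolute-error objective makes low-frequency points
  dominate; a frequency-weighted or relative objective would balance the
  parameters better but is deliberately not the default, to keep the
  method's canonical objective.
* Hour indices are integers (hour-of-day); sub-hourly sampling works
  through the same API but warm-start extrapolation assumes equal spacing
  only in the cold-start-free path.
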