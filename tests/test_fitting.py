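"""Coordinate-search fitter tests: error metric, proposals, line search,
full-search recovery, initialization and the model/results wrapper."""

import math

import numpy as np
import pandas as pd
import pytest

import doubleshell as ds
from doubleshell.aggregate import mean_spectrum
from doubleshell.fitting import propose_candidates

ALL_PARAMS = ("r1", "r2", "r4", "c3", "c5")


def _offset_spectrum(spec, dr, dx):
    return ds.ImpedanceSpectrum(spec.grid, spec.resistance + dr, spec.reactance + dx)


class TestImpedanceError:
    def test_zero_iff_identical(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        assert ds.impedance_error(spec, spec) == 0.0
        assert ds.impedance_error(spec, _offset_spectrum(spec, 1.0, 0.0)) > 0.0

    def test_constant_real_offset(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        shifted = _offset_spectrum(spec, 7.5, 0.0)
        assert ds.impedance_error(spec, shifted) == pytest.approx(len(small_grid) * 7.5)

    def test_pythagorean_offset_over_201_points(self, truth, band_grid):
        """A (3, -4) Ω offset at 201 points sums to exactly 201*5 = 1005 Ω."""
        spec = ds.dsm_impedance(truth, band_grid)
        shifted = _offset_spectrum(spec, 3.0, -4.0)
        assert ds.impedance_error(spec, shifted) == 1005.0

    def test_symmetry_and_components_metric(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        shifted = _offset_spectrum(spec, 3.0, -4.0)
        assert ds.impedance_error(spec, shifted) == ds.impedance_error(shifted, spec)
        # |dR| + |dX| = 7 per point for the same offset
        assert ds.impedance_error(spec, shifted, metric="components") == pytest.approx(
            len(small_grid) * 7.0
        )

    def test_matches_independent_oracle_on_random_pairs(self, small_grid):
        rng = np.random.default_rng(11)
        for _ in range(20):
            r1, x1 = rng.uniform(1, 1e6, len(small_grid)), -rng.uniform(1, 1e6, len(small_grid))
            r2, x2 = rng.uniform(1, 1e6, len(small_grid)), -rng.uniform(1, 1e6, len(small_grid))
            a = ds.ImpedanceSpectrum(small_grid, r1, x1)
            b = ds.ImpedanceSpectrum(small_grid, r2, x2)
            oracle = math.fsum(
                math.sqrt((r1[j] - r2[j]) ** 2 + (x1[j] - x2[j]) ** 2)
                for j in range(len(small_grid))
            )
            assert ds.impedance_error(a, b) == pytest.approx(oracle, rel=1e-12)

    def test_grid_mismatch_rejected(self, truth, small_grid, band_grid):
        a = ds.dsm_impedance(truth, small_grid)
        b = ds.dsm_impedance(truth, band_grid)
        with pytest.raises(ValueError):
            ds.impedance_error(a, b)


class TestProposeCandidates:
    def test_zero_direction_is_center(self, truth):
        proposals, _ = propose_candidates(truth, 0.1)
        zero = [p for p, _, d in proposals if d == 0]
        assert all(p == truth for p in zero) and len(zero) == 5

    def test_multiplicative_update_moves_one_coordinate(self):
        center = ds.DSMParams(100e6, 5e6, 1e6, 1e-12, 1e-12)
        proposals, _ = propose_candidates(center, 0.10)
        (cand,) = [p for p, n, d in proposals if n == "r1" and d == +1]
        assert cand.r1 == pytest.approx(110e6)
        assert (cand.r2, cand.r4, cand.c3, cand.c5) == (
            center.r2,
            center.r4,
            center.c3,
            center.c5,
        )

    def test_out_of_bounds_candidates_discarded_and_reported(self):
        bounds = ds.ParameterBounds()
        center = ds.DSMParams(bounds.r_min, 5e6, 1e6, 1e-12, 1e-12)
        proposals, discarded = propose_candidates(center, 0.10, bounds)
        assert not any(n == "r1" and d == -1 for _, n, d in proposals)
        assert ("r1", -1, pytest.approx(bounds.r_min * 0.9)) in discarded

    def test_respects_free_parameter_mask(self, truth):
        proposals, _ = propose_candidates(truth, 0.1, free_parameters=("r1", "c3"))
        assert {n for _, n, _ in proposals} == {"r1", "c3"}


class TestLineSearch:
    @staticmethod
    def _quadratic_error(target_factor):
        base = 100e6

        def err(p):
            return (p.r1 - target_factor * base) ** 2

        return base, err

    def test_doubling_matches_brute_force_scan(self):
        """1-D quadratic with minimum at +35%: doubling visits 10%, 20%, 40%
        cumulative factors 1.1, 1.32, 1.848; the scan confirms the stop."""
        base, err = self._quadratic_error(1.35)
        center = ds.DSMParams(base * 1.1, 5e6, 1e6, 1e-12, 1e-12)  # after the first move
        e0 = err(center)
        out, e_out, used = ds.line_search(err, center, e0, "r1", +1, 0.10)
        # brute-force replay of the same doubling schedule
        factors, cur = [], 1.1
        step = 0.2
        while True:
            nxt = cur * (1 + step)
            if err(ds.DSMParams(base * nxt, 5e6, 1e6, 1e-12, 1e-12)) < err(
                ds.DSMParams(base * cur, 5e6, 1e6, 1e-12, 1e-12)
            ):
                cur = nxt
                step *= 2
            else:
                break
        assert out.r1 == pytest.approx(base * cur)
        assert e_out <= e0

    def test_immediately_worse_step_returns_input_state(self):
        base, err = self._quadratic_error(1.12)
        center = ds.DSMParams(base * 1.1, 5e6, 1e6, 1e-12, 1e-12)
        e0 = err(center)
        out, e_out, used = ds.line_search(err, center, e0, "r1", +1, 0.10)
        assert out == center and e_out == e0 and used == 1

    def test_negative_direction_never_crosses_zero(self):
        def err(p):
            return p.r1  # always improves downward

        center = ds.DSMParams(1e6, 5e6, 1e6, 1e-12, 1e-12)
        out, e_out, _ = ds.line_search(err, center, err(center), "r1", -1, 0.10)
        assert out.r1 >= ds.ParameterBounds().r_min


class TestCoordinateSearch:
    def test_init_at_truth_returns_unchanged_and_converged(self, truth, band_grid):
        spec = ds.dsm_impedance(truth, band_grid)
        res = ds.coordinate_search(spec, truth)
        assert res.params == truth
        assert res.converged
        assert res.final_error == 0.0

    def test_noiseless_recovery_from_scaled_init(self, truth, band_grid):
        spec = ds.dsm_impedance(truth, band_grid)
        init = ds.DSMParams(*(1.5 * truth.as_array()))
        res = ds.coordinate_search(spec, init)
        assert res.converged
        for name in ALL_PARAMS:
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.01
            )

    def test_error_never_exceeds_initial_error(self, truth, band_grid):
        spec = ds.dsm_impedance(truth, band_grid)
        init = ds.DSMParams(*(0.6 * truth.as_array()))
        e_init = ds.impedance_error(spec, ds.dsm_impedance(init, band_grid))
        res = ds.coordinate_search(spec, init)
        assert res.final_error <= e_init

    def test_deterministic(self, truth, band_grid):
        sets = ds.simulate_measurements({8: truth}, band_grid, ds.NoiseConfig(), seed=3)
        ms = mean_spectrum(sets[0])
        init = ds.initialize_center(ms)
        a = ds.coordinate_search(ms, init)
        b = ds.coordinate_search(ms, init)
        assert a.params == b.params
        assert a.final_error == b.final_error and a.n_evals == b.n_evals

    def test_step_floor_exit_is_a_local_minimum(self, truth, band_grid):
        """After a step-floor exit, no ±alpha_min probe strictly improves."""
        spec = ds.dsm_impedance(truth, band_grid)
        init = ds.DSMParams(*(1.3 * truth.as_array()))
        cfg = ds.FitConfig(threshold_mode="absolute", threshold_value=0.0)  # floor exit
        res = ds.coordinate_search(spec, init, cfg)
        assert not res.converged  # error cannot go below an absolute 0 threshold
        proposals, _ = propose_candidates(res.params, cfg.alpha_min, cfg.bounds)
        for cand, _, d in proposals:
            if d == 0:
                continue
            e = ds.impedance_error(spec, ds.dsm_impedance(cand, band_grid))
            assert e >= res.final_error

    def test_stop_at_threshold_mode_stops_early(self, truth, band_grid):
        spec = ds.dsm_impedance(truth, band_grid)
        init = ds.DSMParams(*(1.5 * truth.as_array()))
        full = ds.coordinate_search(spec, init)
        early = ds.coordinate_search(spec, init, ds.FitConfig(stop_at_threshold=True))
        assert early.converged
        assert early.n_evals < full.n_evals
        assert early.relative_error < 0.021

    def test_budget_exhaustion_flags_not_converged(self, truth, band_grid):
        spec = ds.dsm_impedance(truth, band_grid)
        init = ds.DSMParams(*(1.5 * truth.as_array()))
        res = ds.coordinate_search(spec, init, ds.FitConfig(max_evaluations=20))
        assert not res.converged
        assert res.n_evals <= 20
        assert "budget" in res.message

    def test_out_of_bounds_init_rejected(self, truth, band_grid):
        spec = ds.dsm_impedance(truth, band_grid)
        with pytest.raises(ValueError):
            ds.coordinate_search(spec, truth.replace(r1=1e13))


class TestInitializeCenter:
    def test_linear_extrapolation_from_two_fits(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        fits = [
            ds.FitResult(1, 6, truth.replace(r1=100e6), 0, 0, 1, True),
            ds.FitResult(1, 7, truth.replace(r1=110e6), 0, 0, 1, True),
        ]
        init = ds.initialize_center(spec, fits, hour=8)
        assert init.r1 == pytest.approx(120e6)

    def test_single_previous_fit_reused_exactly(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        prev = truth.replace(r2=9e6)
        init = ds.initialize_center(spec, [ds.FitResult(1, 6, prev, 0, 0, 1, True)])
        assert init == prev

    def test_extrapolation_clamped_to_bounds(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        b = ds.ParameterBounds()
        fits = [
            ds.FitResult(1, 6, truth.replace(r1=2e3), 0, 0, 1, True),
            ds.FitResult(1, 7, truth.replace(r1=1.2e3), 0, 0, 1, True),
        ]
        init = ds.initialize_center(spec, fits, hour=8)
        assert init.r1 == b.r_min

    def test_cold_start_reads_plateau(self, truth, band_grid):
        """With both dispersions in band, |Z|(500 Hz) sits within 5% of r1."""
        spec = ds.dsm_impedance(truth, band_grid)
        init = ds.initialize_center(spec)
        assert init.r1 == pytest.approx(truth.r1, rel=0.05)


class TestFitTimeseries:
    def test_single_hour_equals_direct_search(self, truth, band_grid):
        sets = ds.simulate_measurements({8: truth}, band_grid, ds.NoiseConfig(), seed=4)
        series = ds.fit_timeseries(sets)
        ms = mean_spectrum(sets[0])
        direct = ds.coordinate_search(ms, ds.initialize_center(ms))
        assert series[0].params == direct.params
        assert series[0].final_error == direct.final_error

    def test_noiseless_trajectory_recovery_within_1pct(self, band_grid):
        cfg = ds.TrajectoryConfig(hours=tuple(range(5, 10)), n_plants=1)
        truth_by_hour = ds.simulate_trajectory(cfg)[1]
        noise = ds.NoiseConfig(point_sd=0.0, contact_sd=0.0, n_replicates=1)
        sets = ds.simulate_measurements(truth_by_hour, band_grid, noise, plant=1)
        results = ds.fit_timeseries(sets)
        for res in results:
            t = truth_by_hour[res.hour]
            assert res.converged
            for name in ALL_PARAMS:
                assert getattr(res.params, name) == pytest.approx(
                    getattr(t, name), rel=0.01
                )

    def test_per_hour_failures_are_flagged_not_fatal(self, truth, band_grid):
        good = ds.simulate_measurements({8: truth}, band_grid, ds.NoiseConfig(), seed=4)
        broken_spec = ds.ImpedanceSpectrum(
            band_grid, np.full(201, np.nan), np.zeros(201)
        )
        broken = ds.ReplicateSweepSet(plant=1, hour=9, replicates=[broken_spec])
        results = ds.fit_timeseries(good + [broken])
        assert len(results) == 2
        assert results[0].converged
        assert results[1].params is None and not results[1].converged
        assert results[1].message

    def test_mixed_plants_rejected(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        sets = [
            ds.ReplicateSweepSet(plant=1, hour=8, replicates=[spec]),
            ds.ReplicateSweepSet(plant=2, hour=8, replicates=[spec]),
        ]
        with pytest.raises(ValueError):
            ds.fit_timeseries(sets)


class TestModelResultsAPI:
    def test_fit_and_summary(self, truth, band_grid):
        sets = ds.simulate_measurements({8: truth}, band_grid, ds.NoiseConfig(), seed=6)
        model = ds.DoubleShellModel(mean_spectrum(sets[0]))
        res = model.fit()
        assert res.converged
        text = res.summary()
        for token in ("r1", "c5", "relative error", "converged"):
            assert token in text
        ratios = res.resistance_ratios()
        assert ratios["r2_over_r4"] == pytest.approx(truth.r2 / truth.r4, rel=0.1)

    def test_from_dataframe_round_trip(self, truth, small_grid):
        spec = ds.dsm_impedance(truth, small_grid)
        df = pd.DataFrame(
            {
                "frequency_hz": small_grid.frequencies,
                "resistance_ohm": spec.resistance,
                "reactance_ohm": spec.reactance,
            }
        )
        model = ds.DoubleShellModel.from_dataframe(df)
        res = model.fit(start_params=truth)
        assert res.params == truth
        predicted = res.predict()
        np.testing.assert_allclose(predicted.z, spec.z, rtol=1e-12)
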