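"""Simulator contracts: determinism, closed-form rates, ground truth."""

import numpy as np
import pytest

from fcscreen import (
    AggregationScenario,
    DiffusionComponent,
    FcsModelParams,
    SimulationConfig,
    SpeciesSpec,
    count_rate,
    evaluate_model,
    simulate_curve,
    simulate_dose_response,
    simulate_timelapse,
    simulate_trace,
)
from fcscreen.synthetic_data import expected_count_rate, four_parameter_logistic


def small_config(brightness=(2e4,), background=(0.0,), copies=2.0,
                 triplet_fraction=0.0):
    sp = SpeciesSpec(
        label="s", diffusion_coefficient=20.0, mean_copies=copies,
        brightness=brightness, triplet_fraction=triplet_fraction,
        triplet_time=5e-6,
    )
    return SimulationConfig(
        species=(sp,), bin_time=5e-5, duration=2.0,
        lateral_radius=0.25, axial_radius=1.25, background=background,
    )


class TestSimulateTrace:
    def test_dark_limit_is_pure_background(self):
        cfg = small_config(brightness=(0.0,), background=(500.0,))
        trace = simulate_trace(cfg, seed=4)
        rate = count_rate(trace)
        se = np.sqrt(500.0 / trace.duration)
        assert abs(rate - 500.0) < 4 * se

    def test_dark_species_and_no_background_gives_zero(self):
        cfg = small_config(brightness=(0.0,), background=(0.0,))
        trace = simulate_trace(cfg, seed=4)
        assert trace.counts.sum() == 0

    def test_mean_rate_matches_closed_form(self):
        cfg = small_config()
        expected = expected_count_rate(cfg)
        rates = [count_rate(simulate_trace(cfg, seed=100 + i))
                 for i in range(10)]
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - expected) < 3 * max(se, 1e-9)

    def test_same_seed_bit_identical(self):
        cfg = small_config()
        a = simulate_trace(cfg, seed=7)
        b = simulate_trace(cfg, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_different_seeds_differ(self):
        cfg = small_config()
        a = simulate_trace(cfg, seed=7)
        b = simulate_trace(cfg, seed=8)
        assert not np.array_equal(a.counts, b.counts)

    def test_triplet_blinking_reduces_mean_rate(self):
        bright = small_config(copies=4.0)
        dark = small_config(copies=4.0, triplet_fraction=0.3)
        r_bright = np.mean(
            [count_rate(simulate_trace(bright, seed=i)) for i in range(5)]
        )
        r_dark = np.mean(
            [count_rate(simulate_trace(dark, seed=i)) for i in range(5)]
        )
        assert r_dark == pytest.approx(0.7 * r_bright, rel=0.15)

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(species=(), bin_time=1e-4, duration=1.0)

    def test_small_box_warns(self):
        sp = SpeciesSpec("s", 20.0, 1.0, (1e4,))
        with pytest.warns(UserWarning, match="box"):
            SimulationConfig(
                species=(sp,), bin_time=1e-4, duration=1.0,
                box=(1.0, 1.0, 1.0),
            )

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            simulate_trace(small_config())

    def test_colabeled_species_cross_correlates(self):
        from fcscreen import autocorrelate, cross_correlate

        sp = SpeciesSpec("oligomer", 20.0, 2.0, (2e4, 2e4))
        cfg = SimulationConfig(
            species=(sp,), bin_time=5e-5, duration=6.0,
            lateral_radius=0.25, axial_radius=1.25,
            background=(0.0, 0.0),
        )
        trace = simulate_trace(cfg, seed=6)
        auto = autocorrelate(trace, "A", n_segments=0)
        cross = cross_correlate(trace, "A", "B", n_segments=0)
        # shared positions drive both channels: full cross-correlation
        amp_auto = np.mean(auto.g[:3]) - 1.0
        amp_cross = np.mean(cross.g[:3]) - 1.0
        assert amp_cross == pytest.approx(amp_auto, rel=0.15)


class TestSimulateCurve:
    def params(self):
        return FcsModelParams(
            n_particles=3.0,
            components=(DiffusionComponent(1.0, 2e-4),),
            triplet_fraction=0.15,
            triplet_time=4e-6,
        )

    def test_noiseless_equals_model(self, lag_grid):
        curve = simulate_curve(self.params(), lag_grid, noise_level=0.0)
        np.testing.assert_array_equal(
            curve.g, evaluate_model(self.params(), lag_grid)
        )

    def test_noisy_mean_unbiased(self, lag_grid):
        truth = evaluate_model(self.params(), lag_grid)
        reps = np.array([
            simulate_curve(self.params(), lag_grid, 0.05, seed=i).g
            for i in range(100)
        ])
        se = reps.std(axis=0, ddof=1) / 10.0
        assert np.all(np.abs(reps.mean(axis=0) - truth) < 4 * se + 1e-12)

    def test_seed_reproducible(self, lag_grid):
        a = simulate_curve(self.params(), lag_grid, 0.05, seed=3)
        b = simulate_curve(self.params(), lag_grid, 0.05, seed=3)
        np.testing.assert_array_equal(a.g, b.g)


class TestSimulateTimelapse:
    def scenario(self, **kw):
        defaults = dict(
            time_points_h=(0.0, 4.0, 8.0, 12.0, 16.0),
            lag_time_h=8.0, growth_rate_per_h=0.8, repeats=6,
            curve_noise=0.02,
        )
        defaults.update(kw)
        return AggregationScenario(**defaults)

    def test_repeats_honored(self):
        series = simulate_timelapse(self.scenario(), seed=1)
        assert len(series) == 5
        assert all(s.n_repeats == 6 for s in series)
        assert all(len(s.count_rates) == 6 for s in series)

    def test_zero_growth_is_flat(self):
        from fcscreen import fit_series

        series = simulate_timelapse(
            self.scenario(growth_rate_per_h=0.0), seed=2
        )
        summaries = [fit_series(s, n_components=2, triplet=False)
                     for s in series]
        medians = [s.count_rate_median for s in summaries]
        bands = [(s.count_rate_q25, s.count_rate_q75) for s in summaries]
        mid = np.median(medians)
        for med, (q25, q75) in zip(medians, bands):
            assert q25 - (q75 - q25) < mid < q75 + (q75 - q25)

    def test_plateau_doubling_doubles_endpoint(self):
        s1 = simulate_timelapse(
            self.scenario(time_points_h=(20.0, 24.0), repeats=20), seed=3
        )
        s2 = simulate_timelapse(
            self.scenario(time_points_h=(20.0, 24.0), repeats=20,
                          plateau_intensity=4.0e4), seed=4
        )
        m1 = np.median(s1[-1].count_rates)
        m2 = np.median(s2[-1].count_rates)
        assert m2 / m1 == pytest.approx(2.0, rel=0.12)

    def test_duplicate_time_points_rejected(self):
        with pytest.raises(ValueError, match="time points"):
            AggregationScenario(time_points_h=(0.0, 4.0, 4.0))


class TestSimulateDoseResponse:
    def test_midpoint_and_zero_concentration(self):
        table = simulate_dose_response(
            ic50=100.0, hill=1.3, top=1.4, bottom=0.4,
            concentrations=np.array([0.0, 100.0]), noise=0.0,
            n_replicates=1,
        )
        at0 = table.loc[table.concentration == 0.0, "cpp"].iloc[0]
        at_ic50 = table.loc[table.concentration == 100.0, "cpp"].iloc[0]
        assert at0 == pytest.approx(1.4, rel=1e-15)
        assert at_ic50 == pytest.approx((1.4 + 0.4) / 2.0, rel=1e-12)

    def test_noiseless_on_curve(self):
        conc = np.array([1.0, 10.0, 100.0, 1000.0])
        table = simulate_dose_response(
            ic50=50.0, hill=1.0, top=1.0, bottom=0.2,
            concentrations=conc, noise=0.0, n_replicates=2,
        )
        truth = four_parameter_logistic(conc, 1.0, 0.2, 50.0, 1.0)
        for c, t in zip(conc, truth):
            vals = table.loc[table.concentration == c, "cpp"]
            np.testing.assert_allclose(vals, t, rtol=1e-15)

    def test_inverted_asymptotes_rejected(self):
        with pytest.raises(ValueError, match="descending"):
            simulate_dose_response(ic50=10.0, top=0.1, bottom=1.0, seed=1)

    def test_seed_reproducible(self):
        a = simulate_dose_response(ic50=100.0, seed=5)
        b = simulate_dose_response(ic50=100.0, seed=5)
        assert a.equals(b)
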