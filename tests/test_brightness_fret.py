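"""CPP arithmetic, 4PL dose–response fitting, effect classification."""

import numpy as np
import pytest

from fcscreen import (
    ClassificationConfig,
    SeriesFitSummary,
    classify_effect,
    cpp,
    fit_dose_response,
    simulate_dose_response,
)


class TestCpp:
    def test_ratio_definition(self):
        res = cpp(10_000.0, 10.0)
        assert res.mean == pytest.approx(1000.0, rel=1e-15)

    def test_identity_cpp_times_n_equals_cr(self):
        rng = np.random.default_rng(0)
        cr = rng.uniform(1e3, 1e5, 20)
        n = rng.uniform(0.5, 50.0, 20)
        res = cpp(cr, n)
        np.testing.assert_allclose(
            np.array(res.cpp) * n, cr, rtol=1e-12
        )

    def test_homogeneity_in_count_rate(self):
        a = cpp(5_000.0, 8.0)
        b = cpp(10_000.0, 8.0)
        assert b.mean == pytest.approx(2.0 * a.mean, rel=1e-15)

    def test_replicate_sd_uses_n_minus_1(self):
        res = cpp([100.0, 200.0, 300.0], [1.0, 1.0, 1.0])
        assert res.sd == pytest.approx(100.0, rel=1e-12)

    def test_nonpositive_particle_number_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cpp(1000.0, 0.0)


class TestDoseResponse:
    def test_noiseless_exact_recovery(self):
        table = simulate_dose_response(
            ic50=100.0, hill=1.0, top=1.3, bottom=0.2,
            concentrations=np.geomspace(1.0, 10_000.0, 10),
            noise=0.0, n_replicates=1,
        )
        res = fit_dose_response(table)
        assert res.converged
        assert res.ic50 == pytest.approx(100.0, rel=1e-6)
        assert res.hill == pytest.approx(1.0, rel=1e-6)
        assert res.top == pytest.approx(1.3, rel=1e-6)
        assert res.bottom == pytest.approx(0.2, rel=1e-6)

    def test_midpoint_property_of_fitted_curve(self):
        table = simulate_dose_response(
            ic50=40.0, hill=1.5, noise=0.0, n_replicates=1,
            concentrations=np.geomspace(1.0, 2000.0, 9),
        )
        res = fit_dose_response(table)
        mid = res.predict(np.array([res.ic50]))[0]
        assert mid == pytest.approx((res.top + res.bottom) / 2.0, rel=1e-9)

    def test_scale_equivariance(self):
        table = simulate_dose_response(
            ic50=130.0, hill=1.2, noise=0.0, n_replicates=1,
            concentrations=np.geomspace(2.0, 8000.0, 9),
        )
        scaled = table.copy()
        scaled["cpp"] = scaled["cpp"] * 7.5
        a = fit_dose_response(table)
        b = fit_dose_response(scaled)
        assert b.ic50 == pytest.approx(a.ic50, rel=1e-6)
        assert b.hill == pytest.approx(a.hill, rel=1e-6)
        assert b.top == pytest.approx(7.5 * a.top, rel=1e-6)
        assert b.bottom == pytest.approx(7.5 * a.bottom, rel=1e-6)

    def test_noisy_recovery_median_error_small(self):
        # single-seed errors at 5% noise can reach ~30% (free 4PL); the
        # estimator property worth asserting is a small median error
        errs = []
        for seed in range(15):
            table = simulate_dose_response(ic50=120.0, noise=0.05, seed=seed)
            res = fit_dose_response(table)
            errs.append(abs(res.ic50 - 120.0) / 120.0)
        assert np.median(errs) < 0.10

    def test_too_few_concentrations_rejected(self):
        table = simulate_dose_response(
            ic50=100.0, noise=0.0, n_replicates=2,
            concentrations=np.array([10.0, 100.0, 1000.0]),
        )
        with pytest.raises(ValueError, match="4 distinct"):
            fit_dose_response(table)

    def test_non_monotone_means_flagged_not_fatal(self):
        import pandas as pd

        rows = []
        for c, v in [(1.0, 1.0), (10.0, 0.8), (100.0, 1.4), (1000.0, 0.2)]:
            for rep in range(3):
                rows.append({"concentration": c, "replicate": rep,
                             "cpp": v + 0.001 * rep})
        res = fit_dose_response(pd.DataFrame(rows))
        assert res.poor_fit


def _summary(time_h, median, q25=None, q75=None, rates=None):
    med = float(median)
    return SeriesFitSummary(
        time_h=time_h, condition="x", n_repeats=10, n_excluded=0,
        count_rate_median=med,
        count_rate_q25=med * 0.9 if q25 is None else q25,
        count_rate_q75=med * 1.1 if q75 is None else q75,
        tau_w_median=1e-3, tau_w_q25=9e-4, tau_w_q75=1.1e-3,
        kept_count_rates=tuple(rates if rates is not None else ()),
    )


def _trajectory(medians, times=None):
    times = times or list(range(len(medians)))
    # repeat-level rates spread +-20% around the median so that
    # configurable control quantiles are well defined
    return [
        _summary(float(t), m, rates=np.linspace(0.8 * m, 1.2 * m, 11))
        for t, m in zip(times, medians)
    ]


class TestClassifyEffect:
    sigmoid = [200.0, 300.0, 2_000.0, 10_000.0, 18_000.0, 19_800.0, 20_000.0]

    def test_identical_series_no_effect(self):
        control = _trajectory(self.sigmoid)
        treated = _trajectory(self.sigmoid)
        assert classify_effect(control, treated).label == "no_effect"

    def test_scaled_plateau_is_inhibition(self):
        control = _trajectory(self.sigmoid)
        treated = _trajectory([0.2 * m for m in self.sigmoid])
        call = classify_effect(control, treated)
        assert call.label == "inhibition"
        # rule applied by hand: treated endpoint median 4000 < control
        # lower quartile 0.9 * 20000 at the trailing points
        assert call.endpoint_treated_median == pytest.approx(4000.0)
        assert call.endpoint_control_quantile == pytest.approx(18_000.0)

    def test_time_shift_is_acceleration(self):
        control = _trajectory(self.sigmoid)
        shifted = self.sigmoid[2:] + [self.sigmoid[-1]] * 2
        treated = _trajectory(shifted)
        call = classify_effect(control, treated)
        assert call.label == "acceleration"
        assert call.t_half_treated < call.t_half_control - call.spacing

    def test_misaligned_grids_rejected(self):
        control = _trajectory(self.sigmoid)
        treated = _trajectory(self.sigmoid, times=[0, 1, 2, 3, 4, 5, 7])
        with pytest.raises(ValueError, match="aligned"):
            classify_effect(control, treated)

    def test_too_few_points_rejected(self):
        control = _trajectory([1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            classify_effect(control, control)

    def test_quantile_threshold_configurable(self):
        control = _trajectory(self.sigmoid)
        # mildly reduced plateau: below q25 band but not below q5 band
        treated = _trajectory([0.85 * m for m in self.sigmoid])
        strict = classify_effect(
            control, treated,
            config=ClassificationConfig(endpoint_quantile=25.0),
        )
        lax = classify_effect(
            control, treated,
            config=ClassificationConfig(endpoint_quantile=1.0),
        )
        assert strict.label == "inhibition"
        assert lax.label == "no_effect"
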