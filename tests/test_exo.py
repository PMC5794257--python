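"""Exocytosis kinetics: latency, segmentation, efficiency, endocytosis, curve fits."""

import numpy as np
import pytest

from conftest import make_cm_trace
from ribbonsyn.exo import (
    detect_release_latency,
    segment_components,
    compute_efficiency,
    fit_boltzmann,
    fit_cm_voltage,
    fit_endocytosis,
    fit_gaussian_hist,
)

PERIOD = 2e-4


def ramp_trace(latency=0.204, rate=75.0, step_onset=0.5, step_duration=1.0,
               total=2.0, noise_sd=0.0, rng=None, changepoint=None, rate2=None):
    t = (np.arange(int(total / PERIOD)) + 0.5) * PERIOD
    u = np.clip(t - step_onset, 0.0, step_duration)
    dcm = np.clip(u - latency, 0.0, None) * rate
    if changepoint is not None:
        dcm = dcm + np.clip(u - changepoint, 0.0, None) * (rate2 - rate)
    if noise_sd:
        dcm = dcm + (rng or np.random.default_rng(0)).normal(0, noise_sd, dcm.size)
    return make_cm_trace(dcm, period=PERIOD, step_onset=step_onset,
                         step_duration=step_duration)


class TestLatency:
    def test_noiseless_ramp_onset(self):
        tr = ramp_trace(latency=0.204)
        lat = detect_release_latency(tr)
        assert lat == pytest.approx(0.204, abs=2 * PERIOD + 0.02 / 75.0)

    def test_flat_trace_reports_absent(self):
        tr = ramp_trace(rate=0.0)
        assert detect_release_latency(tr) is None

    def test_noisy_median_near_truth(self):
        rng = np.random.default_rng(42)
        lats = []
        for _ in range(100):
            tr = ramp_trace(latency=0.1, rate=100.0, noise_sd=5.0, rng=rng)
            lat = detect_release_latency(tr)
            if lat is not None:
                lats.append(lat)
        med = np.median(lats)
        # bias = threshold / rate; with 3 SD of 5 fF at 100 fF/s that is 0.15 s
        assert 0.1 - 2 * PERIOD <= med <= 0.1 + 3 * 5.0 / 100.0 + 2 * PERIOD

    def test_latency_nondecreasing_in_threshold(self):
        rng = np.random.default_rng(7)
        tr = ramp_trace(latency=0.1, rate=100.0, noise_sd=3.0, rng=rng)
        lats = [detect_release_latency(tr, k_sd=k) for k in (1.0, 2.0, 3.0, 5.0)]
        lats = [l for l in lats if l is not None]
        assert all(a <= b + 1e-12 for a, b in zip(lats, lats[1:]))


class TestSegmentation:
    def test_noiseless_two_segment_recovery(self):
        tr = ramp_trace(latency=0.05, rate=101.0, changepoint=0.4, rate2=256.0)
        res = segment_components(tr)
        assert res.has_superlinear
        assert res.linear_rate == pytest.approx(101.0, rel=1e-3)
        assert res.super_rate == pytest.approx(256.0, rel=1e-3)
        assert res.super_onset_t == pytest.approx(0.4, abs=2 * PERIOD)

    def test_pure_linear_reports_single_component(self):
        tr = ramp_trace(latency=0.05, rate=101.0)
        res = segment_components(tr)
        assert not res.has_superlinear
        assert res.linear_rate == pytest.approx(101.0, rel=1e-3)

    def test_magnitudes_sum_to_total(self):
        tr = ramp_trace(latency=0.05, rate=101.0, changepoint=0.4, rate2=256.0,
                        noise_sd=2.0, rng=np.random.default_rng(3))
        res = segment_components(tr)
        if res.has_superlinear:
            assert res.linear_mag + res.super_mag == pytest.approx(res.total_mag, rel=1e-9)

    def test_false_positive_rate_controlled(self):
        """On purely linear noisy tracks the superlinear component is accepted
        at most ~alpha of the time (alpha = 0.01; 500 tracks)."""
        rng = np.random.default_rng(2024)
        n_fp = 0
        for _ in range(500):
            t = (np.arange(600) + 0.5) * PERIOD
            y = 100.0 * t + rng.normal(0, 2.0, t.size)
            tr = make_cm_trace(np.concatenate([np.zeros(100), y]),
                               period=PERIOD, step_onset=0.02, step_duration=0.12)
            res = segment_components(tr, latency=0.0)
            n_fp += res.has_superlinear
        assert n_fp <= 500 * 0.01 + 3 * np.sqrt(500 * 0.01 * 0.99)  # ≤ ~12

    def test_short_step_falls_back_to_single(self):
        tr = ramp_trace(latency=0.0, rate=100.0, step_duration=0.002, total=0.7)
        res = segment_components(tr, latency=0.0)
        assert not res.has_superlinear


class TestEfficiencyAndEndocytosis:
    def test_efficiency_is_ratio(self):
        n = int(2.0 / PERIOD)
        t = (np.arange(n) + 0.5) * PERIOD
        u = np.clip(t - 0.5, 0, 1.0)
        dcm = u * 45.0                       # 45 fF over the 1 s step
        ica = np.where((t >= 0.5) & (t < 1.5), -50.0, 0.0)  # 50 pC over the step
        tr = make_cm_trace(dcm, ica_pa=ica)
        eff = compute_efficiency(tr, (0.0, 1.0))
        assert eff == pytest.approx(0.9, rel=0.02)

    def test_zero_charge_flagged_undefined(self):
        tr = ramp_trace(latency=0.05, rate=50.0)
        assert compute_efficiency(tr, (0.1, 0.9)) is None

    def test_noiseless_tau_recovery(self):
        n = int(8.0 / PERIOD)
        t = (np.arange(n) + 0.5) * PERIOD
        dcm = np.where(t < 1.5, np.clip(t - 0.5, 0, 1) * 100.0,
                       100.0 * np.exp(-(t - 1.5) / 6.0))
        tr = make_cm_trace(dcm)
        tau, info = fit_endocytosis(tr)
        assert tau == pytest.approx(6.0, rel=1e-6)

    def test_constant_post_step_absent(self):
        n = int(4.0 / PERIOD)
        t = (np.arange(n) + 0.5) * PERIOD
        dcm = np.where(t < 1.5, np.clip(t - 0.5, 0, 1) * 100.0, 100.0)
        assert fit_endocytosis(make_cm_trace(dcm)) is None

    def test_noisy_tau_median_within_ten_percent(self):
        rng = np.random.default_rng(11)
        taus = []
        for _ in range(100):
            n = int(8.0 / PERIOD)
            t = (np.arange(n) + 0.5) * PERIOD
            dcm = np.where(t < 1.5, np.clip(t - 0.5, 0, 1) * 100.0,
                           100.0 * np.exp(-(t - 1.5) / 6.0))
            out = fit_endocytosis(make_cm_trace(dcm + rng.normal(0, 5.0, n)))
            if out:
                taus.append(out[0])
        assert np.median(taus) == pytest.approx(6.0, rel=0.10)


class TestCurveFits:
    def test_cmv_exact_recovery(self):
        x = np.arange(-60.0, -10.0, 2.0)
        y = 0.0 + 250.0 * (1 - np.exp(-np.clip(x - (-45.0), 0, None) / 7.3))
        fit = fit_cm_voltage(list(zip(x, y)))
        assert fit.a1 == pytest.approx(250.0, rel=1e-4)
        assert fit.x0 == pytest.approx(-45.0, abs=0.01)
        assert fit.t == pytest.approx(7.3, rel=1e-3)

    def test_cmv_translation_equivariance(self):
        x = np.arange(-60.0, -10.0, 2.0)

        def curve(x0):
            return 250.0 * (1 - np.exp(-np.clip(x - x0, 0, None) / 7.3))

        f1 = fit_cm_voltage(list(zip(x, curve(-45.0))))
        f2 = fit_cm_voltage(list(zip(x, curve(-40.0))))
        assert f2.x0 - f1.x0 == pytest.approx(5.0, abs=0.05)

    def test_cmv_all_zero_degenerate(self):
        x = np.arange(-60.0, -20.0, 5.0)
        fit = fit_cm_voltage(list(zip(x, np.zeros_like(x))))
        assert fit.degenerate and fit.a1 == 0.0

    def test_gaussian_center_and_symmetry(self):
        rng = np.random.default_rng(5)
        v = rng.normal(-40.0, 5.0, 4000)
        fit = fit_gaussian_hist(v)
        assert fit.xc == pytest.approx(-40.0, abs=0.5)
        mirrored = np.concatenate([v, 2 * fit.xc - v])
        fit2 = fit_gaussian_hist(mirrored)
        assert fit2.xc == pytest.approx(fit.xc, abs=0.3)

    def test_gaussian_width_recovery(self):
        rng = np.random.default_rng(6)
        sigma = 5.0
        v = rng.normal(-40.0, sigma, 10_000)
        fit = fit_gaussian_hist(v)
        assert fit.w == pytest.approx(2 * sigma, rel=0.05)  # w = 2·sigma

    def test_gaussian_too_few_bins_refused(self):
        with pytest.raises(ValueError, match="bins"):
            fit_gaussian_hist(np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0]), bins=3)

    def test_boltzmann_exact(self):
        v = np.arange(-70.0, 0.0, 5.0)
        i = 1.0 / (1 + np.exp((-34.0 - v) / 7.0))
        fit = fit_boltzmann(list(zip(v, i)))
        assert fit.v_half == pytest.approx(-34.0, abs=1e-6)
        assert fit.slope > 0  # activation grows with depolarization
        assert fit.monotonic

    def test_boltzmann_noisy_recovery(self):
        rng = np.random.default_rng(8)
        v = np.arange(-70.0, 0.0, 5.0)
        clean = 1.0 / (1 + np.exp((-34.0 - v) / 7.0))
        errs = []
        for _ in range(100):
            fit = fit_boltzmann(list(zip(v, clean + rng.normal(0, 0.02, v.size))))
            errs.append(fit.v_half + 34.0)
        assert np.median(np.abs(errs)) < 1.0
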