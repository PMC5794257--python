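"""EPSC detection round trip, event metrics, rate rules, mixtures, KS."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ribbonsyn.epsc import (
    EpscEvent,
    RateProfile,
    classify_response,
    compare_distributions,
    detect_events,
    detect_onset,
    fit_amplitude_mixture,
    integrate_response,
    population_stats,
    rate_profile,
    time_to_peak,
)
from ribbonsyn.synth import (
    epsc_from_preset,
    epsc_template,
    generate_epsc_train,
    render_events,
    sample_amplitudes,
)

FS = 50_000.0


def isolated_train(n=20, spacing=0.05, amp_lo=50.0, amp_hi=300.0,
                   rise=0.15, decay=0.45):
    ev = pd.DataFrame({
        "t_s": np.arange(1, n + 1) * spacing,
        "amp_pA": np.linspace(amp_lo, amp_hi, n),
        "rise_ms": rise, "decay_ms": decay,
    })
    trace = render_events(ev, (n + 2) * spacing, FS)
    return trace, ev


class TestDetection:
    def test_noiseless_exact_round_trip(self):
        """Well-separated noiseless events: perfect recall and precision,
        onsets within 0.5 ms, amplitudes within 2%."""
        trace, ev = isolated_train()
        det = detect_events(trace, FS)
        assert len(det) == len(ev)
        t_err = np.abs([d.t_onset for d in det] - ev.t_s.values)
        a_err = np.abs([d.amp for d in det] - ev.amp_pA.values) / ev.amp_pA.values
        assert t_err.max() < 0.5e-3
        assert a_err.max() < 0.02

    def test_flat_noise_only_trace_yields_nothing(self):
        rng = np.random.default_rng(0)
        assert detect_events(rng.normal(0, 5.0, 100_000), FS) == []

    def test_snr10_recall_and_false_positives(self):
        p = epsc_from_preset("ko", k_onset=0.0, baseline_rate=20.0, peak_rate=20.0,
                             time_to_peak=1e-3, sustain_frac=1.0, noise_sd=15.0,
                             small_frac=0.0, small_slow_frac=0.0,
                             main_dist="gaussian", main_params=(150.0, 1e-6))
        train = generate_epsc_train(p, 30.0, seed=21)  # SNR = 150/15 = 10
        det = detect_events(train.trace_pa, train.sample_rate)
        tt = np.array([d.t_onset for d in det])
        gt = train.events.t_s.values
        close = np.abs(tt[:, None] - gt[None, :]) < 1e-3
        recall = close.any(axis=0).mean()
        n_fp = int((~close.any(axis=1)).sum())
        assert recall >= 0.95
        assert n_fp <= 30.0 / 60.0  # ≤ 1 per minute

    def test_overlapping_events_marked_not_simple(self):
        ev = pd.DataFrame({"t_s": [0.05, 0.0512, 0.2], "amp_pA": [200.0, 180.0, 150.0],
                           "rise_ms": 0.15, "decay_ms": 0.45})
        det = detect_events(render_events(ev, 0.3, FS), FS)
        assert len(det) == 3
        assert not det[0].is_simple and not det[1].is_simple
        assert det[2].is_simple


class TestCharacterization:
    def test_decay_tau_self_fit(self):
        t_ms = np.arange(0, 10, 1e3 / FS)
        trace = -200.0 * epsc_template(t_ms - 2.0, 0.15, 0.5)
        det = detect_events(trace, FS)
        assert len(det) == 1
        assert det[0].decay_tau == pytest.approx(0.5, rel=0.01)

    @pytest.mark.parametrize("amp,tau,expected", [
        (80.0, 1.5, True),    # small and slow
        (200.0, 0.4, False),  # large and fast
        (80.0, 0.4, False),
        (200.0, 1.5, False),
    ])
    def test_small_slow_predicate(self, amp, tau, expected):
        ev = EpscEvent(t_onset=0.0, amp=amp, decay_tau=tau)
        assert ev.is_small_slow is expected


class TestRateRules:
    def test_periodic_events_give_exact_rate(self):
        ev = np.arange(0.0, 60.0, 0.1)  # 10 Hz
        prof = rate_profile(ev, (0, 60), baseline_epoch=(0, 10))
        assert np.allclose(prof.rate, 10.0)

    def test_window_counts_conserve_events(self):
        rng = np.random.default_rng(1)
        ev = np.sort(rng.uniform(0, 50, 500))
        prof = rate_profile(ev, (0, 50), baseline_epoch=(0, 5))
        non_overlap = prof.rate[::10]  # stride 0.1 s, window 1 s
        total = non_overlap.sum() * prof.window
        in_span = np.sum((ev >= prof.t[0] - 0.5) & (ev < prof.t[::10][-1] + 0.5))
        assert total == in_span

    def test_onset_within_one_stride_of_jump(self):
        rng = np.random.default_rng(2)
        ev = np.sort(np.concatenate([
            rng.uniform(0, 10, 10),                      # ~1/s baseline
            10.0 + np.sort(rng.exponential(1 / 50.0, 2000)).cumsum()[:0],  # placeholder
            10.0 + np.cumsum(rng.exponential(1 / 50.0, 1500)),
        ]))
        prof = rate_profile(ev, (0, 30), baseline_epoch=(0, 10))
        onset = detect_onset(prof)
        assert onset == pytest.approx(10.0, abs=prof.stride + 1e-9)

    def test_constant_rate_has_no_onset(self):
        ev = np.arange(0.0, 60.0, 0.1)
        prof = rate_profile(ev, (0, 60), baseline_epoch=(0, 10))
        assert detect_onset(prof) is None

    def test_onset_threshold_monotonicity(self):
        t = np.arange(0.5, 59.5, 0.1)
        rate = np.where(t > 20, 30.0, 1.0)
        low = RateProfile(t, rate, 1.0, 0.1, baseline_mean=1.0, baseline_sd=0.5)
        high = RateProfile(t, rate, 1.0, 0.1, baseline_mean=1.0, baseline_sd=10.0)
        o_low, o_high = detect_onset(low), detect_onset(high)
        assert o_high is None or o_high >= o_low

    def test_classification_limits(self):
        t = np.arange(0.5, 59.5, 0.1)
        sustained = RateProfile(t, np.where(t > 10, 40.0, 1.0), 1.0, 0.1, 1.0, 0.5)
        assert classify_response(sustained, 10.0) == "sustained"
        transient = RateProfile(t, np.where((t > 10) & (t < 20), 40.0, 0.0),
                                1.0, 0.1, 1.0, 0.5)
        assert classify_response(transient, 10.0) == "transient"
        with pytest.raises(ValueError, match="horizon"):
            classify_response(sustained, 45.0)

    def test_time_to_peak_triangular_profile(self):
        rng = np.random.default_rng(3)
        # triangular rate: rises 10->peak at 19 s, then falls; spontaneous 1/s
        tgrid = np.linspace(0, 40, 4001)
        rate = np.interp(tgrid, [0, 10, 19, 30, 40], [1, 1, 80, 1, 1])
        lam = np.maximum(rate, 0) * (tgrid[1] - tgrid[0])
        ev = tgrid[rng.poisson(lam) > 0]
        prof = rate_profile(ev, (0, 40), baseline_epoch=(0, 10))
        tp = time_to_peak(ev, prof)
        peak_t = prof.t[np.argmax(prof.rate)]
        assert tp is not None
        assert peak_t - tp == pytest.approx(10.0, abs=1.0)  # start ≈ switch

    def test_time_to_peak_excludes_low_peaks(self):
        t = np.arange(0.5, 59.5, 0.1)
        prof = RateProfile(t, np.where(t > 10, 20.0, 1.0), 1.0, 0.1, 1.0, 0.5)
        assert time_to_peak(np.arange(0, 60, 0.05), prof) is None

    def test_integral_of_constant_rate(self):
        t = np.arange(0.5, 59.5, 0.1)
        prof = RateProfile(t, np.full(t.size, 10.0), 1.0, 0.1, 1.0, 0.5)
        total, truncated = integrate_response(prof, 5.0, span=50.0)
        assert total == pytest.approx(500.0, rel=1e-9)
        assert not truncated
        total2, trunc2 = integrate_response(prof, 30.0, span=50.0)
        assert trunc2

    def test_zero_rate_integrates_to_zero(self):
        t = np.arange(0.5, 59.5, 0.1)
        prof = RateProfile(t, np.zeros(t.size), 1.0, 0.1, 0.0, 0.0)
        assert integrate_response(prof, 5.0)[0] == 0.0


class TestMixture:
    def test_known_mixture_recovery(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(50, 10, 500), rng.normal(200, 40, 9500)])
        fit = fit_amplitude_mixture(x)
        assert fit.small_area_pct == pytest.approx(5.0, abs=1.0)
        assert fit.small_mean == pytest.approx(50.0, abs=5.0)

    def test_unimodal_flagged_single(self):
        rng = np.random.default_rng(5)
        fit = fit_amplitude_mixture(rng.normal(200, 40, 3000))
        assert fit.effectively_single or fit.small_area_pct < 1.5

    def test_too_few_events_refused(self):
        with pytest.raises(ValueError, match="at least"):
            fit_amplitude_mixture(np.full(50, 100.0))

    def test_gamma_main_preferred_on_skewed_body(self):
        amps, _ = sample_amplitudes(epsc_from_preset("ko"), 4000, seed=6)
        fit = fit_amplitude_mixture(amps)
        assert fit.model_choice == "gauss+gamma"
        assert fit.small_area_pct == pytest.approx(5.5, abs=2.5)


class TestPopulationStats:
    def test_symmetric_decays_have_zero_skew(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.5, 0.05, 4001)
        d = np.concatenate([d, 1.0 - d])  # exactly symmetric
        df = pd.DataFrame({"t_s": np.arange(d.size) * 0.01, "amp_pA": 200.0,
                           "decay_ms": d, "duration_ms": 1.0})
        st = population_stats(df)
        assert st.skew_decay == pytest.approx(0.0, abs=1e-6)

    def test_equal_amplitudes_have_zero_cv(self):
        df = pd.DataFrame({"t_s": [0, 1, 2], "amp_pA": 150.0, "decay_ms": 0.4})
        st = population_stats(df)
        assert st.cv_amp == 0.0
        assert st.frac_gt_350 == 0.0

    def test_empty_table_refused(self):
        with pytest.raises(ValueError, match="empty"):
            population_stats(pd.DataFrame({"t_s": [], "amp_pA": [], "decay_ms": []}))


class TestCompareDistributions:
    def test_identical_samples(self):
        x = np.arange(100.0)
        d, p, _ = compare_distributions(x, x)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, p, _ = compare_distributions(np.arange(10.0), np.arange(100.0, 110.0))
        assert d == 1.0

    def test_gaussian_shift_matches_analytic_gap(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        d, p, cdf = compare_distributions(a, b)
        analytic = norm.cdf(0.5) - norm.cdf(-0.5)  # max CDF gap = 0.3829
        assert d == pytest.approx(analytic, rel=0.12)
        assert p < 1e-10
        assert {"x", "cdf_a", "cdf_b"} <= set(cdf.columns)

    def test_empty_sample_refused(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_distributions(np.array([]), np.arange(5.0))
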