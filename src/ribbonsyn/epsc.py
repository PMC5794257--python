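"""EPSC detection, characterization and population statistics.

The detector is a matched-filter / derivative-threshold hybrid: a unit-energy
difference-of-exponentials kernel is correlated with the (negated) trace,
candidate peaks above a threshold expressed in robust noise-SD units are then
refined on the raw trace (local baseline, 10–90% rise, single-exponential
decay fit from the peak).  Rate profiles use sliding 1 s windows at 100 ms
stride; response onset, sustained/transient classification, time-to-peak and
the 50 s integral implement the corresponding threshold rules.  Amplitude
histograms are fitted with a two-component mixture — a small Gaussian peak
plus a Gaussian or gamma main body, selected by BIC — via EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, special, stats

from .synth.epsc import epsc_template

__all__ = [
    "EpscEvent",
    "RateProfile",
    "MixtureFit",
    "PopulationStats",
    "detect_events",
    "characterize_event",
    "events_to_frame",
    "rate_profile",
    "detect_onset",
    "classify_response",
    "time_to_peak",
    "integrate_response",
    "fit_amplitude_mixture",
    "population_stats",
    "compare_distributions",
]


@dataclass
class EpscEvent:
    """One detected postsynaptic event (amplitudes positive magnitudes of
    inward current)."""

    t_onset: float                  # s
    amp: float                      # pA
    rise_time: float | None = None  # ms, 10-90%
    decay_tau: float | None = None  # ms
    duration: float | None = None   # ms, onset -> 90% of the decay completed
    is_simple: bool = True
    fit_quality: float | None = None

    @property
    def is_small_slow(self) -> bool:
        return (self.decay_tau is not None and self.amp < 100.0 and self.decay_tau > 1.0)


# --------------------------------------------------------------------------
# detection

def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust noise SD from the median absolute first difference (MAD)."""
    d = np.diff(trace)
    return float(np.median(np.abs(d - np.median(d))) / 0.6744897501960817 / np.sqrt(2.0))


def detect_events(
    trace: np.ndarray,
    sample_rate: float,
    threshold_sd: float = 5.0,
    threshold_floor_pa: float = 10.0,
    template_taus_ms: tuple[float, float] = (0.15, 0.5),
    min_separation_ms: float = 0.3,
    characterize: bool = True,
) -> list[EpscEvent]:
    """Detect inward events on a current trace (pA, inward negative).

    Candidates are peaks of the matched-filter output exceeding
    ``max(threshold_sd·noise_sd, threshold_floor_pa)`` (filter units are pA
    since the kernel has unit sum of squares times peak normalization); each
    candidate is refined by :func:`characterize_event`.  Events whose decay is
    interrupted by a neighbor are marked not simple.
    """
    trace = np.asarray(trace, dtype=float)
    x = -(trace - np.median(trace))  # positive-going events, baseline ~0
    rise, dec = template_taus_ms
    dt_ms = 1e3 / sample_rate
    tt = np.arange(0.0, dec * 8.0, dt_ms)
    kern = epsc_template(tt, rise, dec)
    kern_peak_gain = float(np.sum(kern**2)) / float(np.max(kern))
    score = signal.fftconvolve(x, kern[::-1], mode="full")[kern.size - 1 :] / kern_peak_gain
    # score ≈ event amplitude at the event peak for isolated template-shaped events

    sd = estimate_noise_sd(trace)
    thr = max(threshold_sd * sd, threshold_floor_pa)
    min_sep = max(int(round(min_separation_ms / dt_ms)), 1)
    peaks, _ = signal.find_peaks(score, height=thr, distance=min_sep)
    if peaks.size == 0:
        return []

    # the score peaks at the event onset; the raw peak sits ~argmax(kern) later
    lag = int(np.argmax(kern))
    events: list[EpscEvent] = []
    for p in peaks:
        i0 = p
        i1 = min(p + 2 * lag + 2, x.size)
        local = x[i0:i1]
        if local.size == 0:
            continue
        pk = i0 + int(np.argmax(local))
        if characterize:
            ev = characterize_event(trace, sample_rate, pk, template_taus_ms=template_taus_ms)
            if ev is None:
                continue
        else:
            ev = EpscEvent(t_onset=(pk - lag) / sample_rate, amp=float(x[pk]))
        events.append(ev)

    # dedupe refined peaks that collapsed onto the same sample, keep order
    seen: dict[float, EpscEvent] = {}
    for ev in events:
        seen.setdefault(round(ev.t_onset * sample_rate), ev)
    events = sorted(seen.values(), key=lambda e: e.t_onset)

    # neighbor within the decay span interrupts the event: not simple
    overlap_s = dec * 6e-3
    for a, b in zip(events, events[1:]):
        if b.t_onset - a.t_onset < overlap_s:
            a.is_simple = False
            b.is_simple = False
    return events


def characterize_event(
    trace: np.ndarray,
    sample_rate: float,
    peak_index: int,
    template_taus_ms: tuple[float, float] = (0.15, 0.5),
    baseline_ms: tuple[float, float] = (1.2, 0.3),
) -> EpscEvent | None:
    """Measure one event around ``peak_index``: local-baseline amplitude,
    10–90% rise time, single-exponential decay τ (fit over the 30%→5%
    falling phase), duration (onset to 90%-completed decay)."""
    x = -np.asarray(trace, dtype=float)
    dt_ms = 1e3 / sample_rate
    n = x.size
    b0 = max(peak_index - int(baseline_ms[0] / dt_ms), 0)
    b1 = max(peak_index - int(baseline_ms[1] / dt_ms), b0 + 1)
    base = float(np.median(x[b0:b1]))
    # 3-point mean at the peak: suppresses the select-the-max noise bias
    amp = float(x[max(peak_index - 1, 0): peak_index + 2].mean() - base)
    if amp <= 0:
        return None

    # onset: walk back to the 10% crossing of the rising phase
    i = peak_index
    lo_thr = base + 0.1 * amp
    hi_thr = base + 0.9 * amp
    t10 = t90 = None
    while i > b0:
        if x[i] <= hi_thr and t90 is None:
            t90 = i + (hi_thr - x[i]) / max(x[i + 1] - x[i], 1e-12)
        if x[i] <= lo_thr:
            t10 = i + (lo_thr - x[i]) / max(x[i + 1] - x[i], 1e-12)
            break
        i -= 1
    if t10 is None:
        t10 = float(i)
    if t90 is None:
        t90 = float(peak_index)
    rise_time = (t90 - t10) * dt_ms
    onset = t10 * dt_ms * 1e-3

    # decay fit region: 30% down to 5% of the amplitude — late enough that the
    # rising exponential no longer contaminates the single-exponential tail
    j = peak_index
    j_hi = j_lo = j_dur = None
    stop = min(peak_index + int(template_taus_ms[1] * 14 / dt_ms), n - 1)
    while j < stop:
        v = x[j] - base
        if j_hi is None and v <= 0.3 * amp:
            j_hi = j
        if j_dur is None and v <= 0.1 * amp:
            j_dur = j
        if v <= 0.05 * amp:
            j_lo = j
            break
        j += 1
    decay_tau = None
    fit_quality = None
    duration = None
    if j_dur is not None:
        duration = (j_dur - t10) * dt_ms  # onset to 90%-completed decay
    if j_hi is not None and j_lo is not None and j_lo - j_hi >= 3:
        seg = x[j_hi:j_lo] - base
        tseg = np.arange(j_lo - j_hi) * dt_ms
        pos = seg > 0
        if pos.sum() >= 3:
            slope, intercept = np.polyfit(tseg[pos], np.log(seg[pos]), 1)
            if slope < 0:
                try:
                    popt, _ = optimize.curve_fit(
                        lambda t, a, tau: a * np.exp(-t / tau),
                        tseg, seg, p0=[float(np.exp(intercept)), -1.0 / slope],
                        maxfev=5000,
                    )
                    decay_tau = float(popt[1])
                    fit_quality = float(np.sqrt(np.mean(
                        (popt[0] * np.exp(-tseg / popt[1]) - seg) ** 2))) / amp
                except RuntimeError:
                    decay_tau = None
    return EpscEvent(t_onset=onset, amp=amp, rise_time=float(rise_time),
                     decay_tau=decay_tau, duration=duration,
                     fit_quality=fit_quality)


def events_to_frame(events: list[EpscEvent]) -> pd.DataFrame:
    return pd.DataFrame({
        "t_s": [e.t_onset for e in events],
        "amp_pA": [e.amp for e in events],
        "rise_ms": [e.rise_time for e in events],
        "decay_ms": [e.decay_tau for e in events],
        "duration_ms": [e.duration for e in events],
        "simple": [int(e.is_simple) for e in events],
        "small_slow": [int(e.is_small_slow) for e in events],
    })


# --------------------------------------------------------------------------
# rate profiles and response classification

@dataclass
class RateProfile:
    """Sliding-window event frequency (1 s windows, 100 ms stride by default).

    ``t`` holds window centers; threshold rules quote times at the trailing
    edge of the first qualifying window (t + window/2), i.e. the earliest
    moment by which the windowed rate has exceeded the criterion.
    """

    t: np.ndarray
    rate: np.ndarray
    window: float
    stride: float
    baseline_mean: float
    baseline_sd: float
    baseline_epoch: tuple = (0.0, 0.0)
    meta: dict = field(default_factory=dict)


def rate_profile(
    event_times: np.ndarray,
    t_span: tuple[float, float],
    baseline_epoch: tuple[float, float],
    window: float = 1.0,
    stride: float = 0.1,
) -> RateProfile:
    """Event frequency over sliding windows plus baseline-epoch statistics."""
    ev = np.sort(np.asarray(event_times, dtype=float))
    lo, hi = t_span
    centers = np.arange(lo + window / 2.0, hi - window / 2.0 + 1e-9, stride)
    counts = np.searchsorted(ev, centers + window / 2.0) - np.searchsorted(ev, centers - window / 2.0)
    rate = counts / window

    b0, b1 = baseline_epoch
    bmask = (centers - window / 2.0 >= b0) & (centers + window / 2.0 <= b1)
    if not bmask.any():
        raise ValueError("baseline epoch contains no complete window")
    return RateProfile(t=centers, rate=rate.astype(float), window=window, stride=stride,
                       baseline_mean=float(rate[bmask].mean()),
                       baseline_sd=float(rate[bmask].std()),
                       baseline_epoch=(float(b0), float(b1)))


def detect_onset(profile: RateProfile, k_sd: float = 2.0,
                 hold_windows: int | None = None) -> float | None:
    """Trailing edge of the first window whose rate exceeds baseline mean +
    ``k_sd``·SD; None if the criterion is never met.

    Because consecutive windows overlap, a chance cluster of baseline events
    stays above threshold for up to window/stride windows; the crossing must
    therefore persist for ``hold_windows`` consecutive windows (default:
    window/stride + 2) to count as the response start.
    """
    thr = profile.baseline_mean + k_sd * profile.baseline_sd
    if hold_windows is None:
        hold_windows = int(round(profile.window / profile.stride)) + 2
    above = profile.rate > thr
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= hold_windows:
            return float(profile.t[i - hold_windows + 1] + profile.window / 2.0)
    return None


def classify_response(
    profile: RateProfile,
    onset_t: float,
    horizon: float = 20.0,
    k_sd: float = 2.0,
    persist_frac: float = 0.5,
) -> str:
    """'sustained' when the rate stays above baseline mean + k_sd·SD in at
    least ``persist_frac`` of the windows beyond ``onset_t + horizon``."""
    end_of_record = profile.t[-1] + profile.window / 2.0
    if end_of_record < onset_t + horizon:
        raise ValueError("recording shorter than the classification horizon")
    thr = profile.baseline_mean + k_sd * profile.baseline_sd
    m = profile.t - profile.window / 2.0 >= onset_t + horizon
    frac = float((profile.rate[m] > thr).mean()) if m.any() else 0.0
    return "sustained" if frac >= persist_frac else "transient"


def time_to_peak(
    event_times: np.ndarray,
    profile: RateProfile,
    spontaneous_stats: tuple[float, float] | None = None,
    k_sd: float = 3.0,
    subwindow: float = 0.2,
    min_peak_rate: float = 30.0,
) -> float | None:
    """Time from response start to the profile maximum.

    Response start: the first moment the rate in two overlapping 200 ms
    windows exceeds the spontaneous mean + ``k_sd``·SD, with the spontaneous
    statistics computed on the same 200 ms windows over the baseline epoch
    (or passed explicitly).  Fibers whose peak rate never reaches
    ``min_peak_rate`` are excluded (None).
    """
    if profile.rate.max() < min_peak_rate:
        return None
    ev = np.sort(np.asarray(event_times, dtype=float))
    lo = profile.t[0] - profile.window / 2.0
    hi = profile.t[-1] + profile.window / 2.0
    centers = np.arange(lo + subwindow / 2.0, hi - subwindow / 2.0 + 1e-9, subwindow / 2.0)
    counts = np.searchsorted(ev, centers + subwindow / 2.0) - np.searchsorted(ev, centers - subwindow / 2.0)
    fine = counts / subwindow
    if spontaneous_stats is None:
        b0, b1 = profile.baseline_epoch
        bm = (centers - subwindow / 2.0 >= b0) & (centers + subwindow / 2.0 <= b1)
        if not bm.any():
            raise ValueError("no baseline fine windows; pass spontaneous_stats")
        spontaneous_stats = (float(fine[bm].mean()), float(fine[bm].std()))
    thr = spontaneous_stats[0] + k_sd * spontaneous_stats[1]
    hit = (fine[:-1] > thr) & (fine[1:] > thr)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return None
    start = centers[idx[0]] - subwindow / 2.0
    t_peak = profile.t[int(np.argmax(profile.rate))]
    return float(t_peak - start)


def integrate_response(
    profile: RateProfile,
    onset_t: float,
    span: float = 50.0,
) -> tuple[float, bool]:
    """Trapezoidal integral of the rate over [onset, onset+span] → event count.
    Returns (total, truncated_flag)."""
    end = onset_t + span
    record_end = profile.t[-1]
    truncated = record_end < end
    stop = min(end, record_end)
    grid = np.arange(onset_t, stop + 1e-9, profile.stride)
    vals = np.interp(grid, profile.t, profile.rate)
    return float(np.trapezoid(vals, grid)), bool(truncated)


# --------------------------------------------------------------------------
# amplitude mixture

@dataclass
class MixtureFit:
    """Two-component amplitude mixture: a small Gaussian peak plus the main
    body (Gaussian or gamma, chosen by BIC)."""

    small_mean: float
    small_sd: float
    small_weight: float
    main_kind: str               # 'gaussian' | 'gamma'
    main_params: tuple
    model_choice: str            # 'gauss+gauss' | 'gauss+gamma'
    n_events: int
    loglik: float
    bic: float
    effectively_single: bool = False

    @property
    def small_area_pct(self) -> float:
        return 100.0 * self.small_weight


def _em_two_component(x: np.ndarray, main: str, n_iter: int = 500, tol: float = 1e-10):
    """EM for w·N(μs,σs) + (1−w)·Main; 'small' is pinned to the lower mean."""
    n = x.size
    lo = x <= np.quantile(x, 0.1)
    mu_s, sd_s = float(x[lo].mean()), float(max(x[lo].std(), 2.0))
    w = 0.1
    hi = ~lo
    if main == "gaussian":
        theta = [float(x[hi].mean()), float(max(x[hi].std(), 2.0))]
    else:
        m, v = float(x[hi].mean()), float(max(x[hi].var(), 4.0))
        theta = [m * m / v, v / m]  # shape, scale

    def main_logpdf(th):
        if main == "gaussian":
            return stats.norm.logpdf(x, th[0], th[1])
        return stats.gamma.logpdf(x, th[0], scale=th[1])

    ll_old = -np.inf
    for _ in range(n_iter):
        la = np.log(max(w, 1e-300)) + stats.norm.logpdf(x, mu_s, sd_s)
        lb = np.log(max(1.0 - w, 1e-300)) + main_logpdf(theta)
        mx = np.maximum(la, lb)
        ll = float(np.sum(mx + np.log(np.exp(la - mx) + np.exp(lb - mx))))
        r = np.exp(la - mx) / (np.exp(la - mx) + np.exp(lb - mx))  # resp. of small
        w = float(r.mean())
        if r.sum() > 1e-8:
            mu_s = float(np.average(x, weights=r))
            sd_s = float(max(np.sqrt(np.average((x - mu_s) ** 2, weights=r)), 1.0))
        r2 = 1.0 - r
        if main == "gaussian":
            mu = float(np.average(x, weights=r2))
            sd = float(max(np.sqrt(np.average((x - mu) ** 2, weights=r2)), 1.0))
            theta = [mu, sd]
        else:
            mbar = float(np.average(x, weights=r2))
            lbar = float(np.average(np.log(x), weights=r2))
            s = np.log(mbar) - lbar
            k = theta[0]
            for _ in range(50):  # Newton on ln(k) − ψ(k) = s
                f = np.log(k) - special.digamma(k) - s
                fp = 1.0 / k - special.polygamma(1, k)
                step = f / fp
                k = max(k - step, 1e-3)
                if abs(step) < 1e-12:
                    break
            theta = [float(k), float(mbar / k)]
        if abs(ll - ll_old) < tol * max(abs(ll), 1.0):
            ll_old = ll
            break
        ll_old = ll

    # enforce the 'small' label on the lower-mean component
    main_mean = theta[0] if main == "gaussian" else theta[0] * theta[1]
    if mu_s > main_mean and main == "gaussian":
        (mu_s, sd_s), theta, w = (theta[0], theta[1]), [mu_s, sd_s], 1.0 - w
    k_params = 5
    bic = -2.0 * ll_old + k_params * np.log(n)
    return dict(small=(mu_s, sd_s, w), main=tuple(theta), loglik=ll_old, bic=bic)


def fit_amplitude_mixture(amps: np.ndarray, n_min: int = 100,
                          models: tuple = ("gaussian", "gamma")) -> MixtureFit:
    """Fit both sanctioned mixtures (the smaller peak is always Gaussian),
    select by BIC, and report the integrated small-peak area as a percentage.
    Refused below ``n_min`` events."""
    x = np.asarray(amps, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < n_min:
        raise ValueError(f"mixture fit requires at least {n_min} events (got {x.size})")
    fits = {m: _em_two_component(x, m) for m in models}
    best = min(fits, key=lambda m: fits[m]["bic"])
    f = fits[best]
    mu_s, sd_s, w = f["small"]
    # a mixture that does not beat the best single-component model by BIC is
    # effectively single (no resolvable small peak)
    n = x.size
    ll_norm = float(np.sum(stats.norm.logpdf(x, x.mean(), max(x.std(), 1e-6))))
    a_g, _, b_g = stats.gamma.fit(x, floc=0.0)
    ll_gam = float(np.sum(stats.gamma.logpdf(x, a_g, scale=b_g)))
    bic_single = -2.0 * max(ll_norm, ll_gam) + 2.0 * np.log(n)
    single = w < 0.005 or bic_single <= f["bic"]
    return MixtureFit(
        small_mean=mu_s, small_sd=sd_s, small_weight=w,
        main_kind=best, main_params=f["main"],
        model_choice="gauss+gauss" if best == "gaussian" else "gauss+gamma",
        n_events=int(x.size), loglik=f["loglik"], bic=f["bic"],
        effectively_single=bool(single),
    )


# --------------------------------------------------------------------------
# population statistics

@dataclass
class PopulationStats:
    median_amp: float
    cv_amp: float
    skew_decay: float | None
    frac_gt_350: float          # %
    frac_small_slow: float      # %
    n_events: int
    peak_rate: float | None = None
    time_to_peak_s: float | None = None
    total_events_50s: float | None = None
    response_class: str | None = None


def population_stats(events: pd.DataFrame | list, profile: RateProfile | None = None,
                     event_times: np.ndarray | None = None) -> PopulationStats:
    """Per-recording event statistics (and profile metrics when given)."""
    df = events_to_frame(events) if isinstance(events, list) else events
    if len(df) == 0:
        raise ValueError("empty event table")
    amps = df["amp_pA"].to_numpy(dtype=float)
    decays = df["decay_ms"].to_numpy(dtype=float)
    dec_ok = np.isfinite(decays)
    skew = float(stats.skew(decays[dec_ok], bias=False)) if dec_ok.sum() >= 3 else None
    small_slow = (amps < 100.0) & np.where(dec_ok, decays > 1.0, False)

    peak_rate = t_pk = total = cls = None
    if profile is not None:
        peak_rate = float(profile.rate.max())
        onset = detect_onset(profile)
        times = event_times if event_times is not None else df["t_s"].to_numpy()
        t_pk = time_to_peak(times, profile)
        if onset is not None:
            total = integrate_response(profile, onset)[0]
            try:
                cls = classify_response(profile, onset)
            except ValueError:
                cls = None
    return PopulationStats(
        median_amp=float(np.median(amps)),
        cv_amp=float(amps.std() / amps.mean()),
        skew_decay=skew,
        frac_gt_350=float(100.0 * (amps > 350.0).mean()),
        frac_small_slow=float(100.0 * small_slow.mean()),
        n_events=int(len(df)),
        peak_rate=peak_rate, time_to_peak_s=t_pk,
        total_events_50s=total, response_class=cls,
    )


def compare_distributions(sample_a: np.ndarray, sample_b: np.ndarray):
    """Two-sample Kolmogorov–Smirnov test plus cumulative-distribution tables.

    Returns (ks_stat, p_value, cdf_table) where the table has the pooled
    support and both empirical CDFs.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="auto")
    support = np.unique(np.concatenate([a, b]))
    cdf = pd.DataFrame({
        "x": support,
        "cdf_a": np.searchsorted(a, support, side="right") / a.size,
        "cdf_b": np.searchsorted(b, support, side="right") / b.size,
    })
    return float(res.statistic), float(res.pvalue), cdf
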