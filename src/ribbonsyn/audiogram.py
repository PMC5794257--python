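"""ABR and DPOAE threshold analysis.

ABR epochs are band-pass filtered (300–3000 Hz, zero phase), trial-averaged,
and wave 1 is read as the first positive peak (p1) in a search window followed
by the next trough (n1).  The audiogram threshold is the lowest level — after
monotone piecewise-linear interpolation of the p1–n1 growth function — at
which the response exceeds a criterion multiple of the noise floor; if no
level qualifies, the threshold defaults to 80 dB SPL and is flagged.

DPOAE microphone spectra are evaluated at the cubic distortion frequency
2f1−f2; the noise floor is the mean of the 20 adjacent FFT bins (10 per side,
the distortion-product bin excluded) and the DPOAE threshold is the lowest
(interpolated) level at which the distortion product exceeds the floor mean
by three floor SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synth.audio import P_REF, AbrSeries

__all__ = [
    "AveragedAbr",
    "Wave1Result",
    "AudiogramResult",
    "DpoaeResult",
    "average_abr",
    "wave1_metrics",
    "abr_threshold",
    "dpoae_extract",
    "dpoae_threshold",
    "normalize_growth",
]

DEFAULT_LEVEL_CEILING = 80.0  # dB SPL assigned when no response is detected


@dataclass
class AveragedAbr:
    waveform: np.ndarray      # µV
    sample_rate: float
    noise_rms: float          # µV, residual noise of the average (pre-stimulus)
    filter_band: tuple | None


@dataclass
class Wave1Result:
    p1_amp: float             # µV
    n1_amp: float             # µV
    p1n1: float               # µV
    p1_latency: float         # ms


@dataclass
class AudiogramResult:
    threshold: float          # dB SPL
    criterion: str
    defaulted: bool
    freq_khz: float | None = None
    levels: np.ndarray | None = None
    p1n1: np.ndarray | None = None
    noise_floor: float | None = None  # µV
    meta: dict = field(default_factory=dict)


def average_abr(
    epochs: np.ndarray,
    sample_rate: float,
    filter_band: tuple | None = (300.0, 3000.0),
    prestim: float = 0.8e-3,
) -> AveragedAbr:
    """Band-pass filter (zero-phase) then average ABR trials.

    ``prestim`` seconds at the start of the epoch — before the earliest wave —
    estimate the residual noise RMS of the average.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 2:
        raise ValueError("ABR averaging requires at least 2 trials")
    if filter_band is not None:
        sos = signal.butter(2, filter_band, btype="bandpass", fs=sample_rate, output="sos")
        epochs = signal.sosfiltfilt(sos, epochs, axis=1)
    avg = epochs.mean(axis=0)
    n_pre = max(int(prestim * sample_rate), 2)
    noise_rms = float(np.sqrt(np.mean((avg[:n_pre] - avg[:n_pre].mean()) ** 2)))
    return AveragedAbr(waveform=avg, sample_rate=sample_rate,
                       noise_rms=noise_rms, filter_band=filter_band)


def wave1_metrics(
    waveform: np.ndarray,
    sample_rate: float,
    search_window: tuple = (1.0, 2.5),
    n1_span: float = 1.5,
) -> Wave1Result | None:
    """p1 = maximum in the search window (ms), n1 = following minimum.

    Returns None when the window holds no interior extremum (monotone
    waveform — no identifiable wave).
    """
    w = np.asarray(waveform, dtype=float)
    i0 = int(search_window[0] * 1e-3 * sample_rate)
    i1 = min(int(search_window[1] * 1e-3 * sample_rate) + 1, w.size)
    if i1 - i0 < 3:
        raise ValueError("search window too short")
    seg = w[i0:i1]
    ip = i0 + int(np.argmax(seg))
    if ip in (i0, i1 - 1) and (np.all(np.diff(seg) >= 0) or np.all(np.diff(seg) <= 0)):
        return None
    j1 = min(ip + 1 + int(n1_span * 1e-3 * sample_rate), w.size)
    if j1 - ip < 2:
        return None
    inn = ip + 1 + int(np.argmin(w[ip + 1 : j1]))
    return Wave1Result(
        p1_amp=float(w[ip]), n1_amp=float(w[inn]),
        p1n1=float(w[ip] - w[inn]), p1_latency=float(ip / sample_rate * 1e3),
    )


def abr_threshold(
    series: AbrSeries,
    criterion_multiplier: float = 5.0,
    criterion_mode: str = "rms",
    noise_rms: float | None = None,
    search_window: tuple = (1.0, 2.5),
    default_level: float = DEFAULT_LEVEL_CEILING,
) -> AudiogramResult:
    """Interpolated level at which the p1–n1 growth function reaches the
    criterion.

    The criterion is ``criterion_multiplier`` × the RMS noise floor of the
    averaged traces (mode 'rms'; mode 'mean_sd' uses mean + k·SD of the
    per-level floors).  ``noise_rms`` overrides the estimated floor.  Because
    a max-minus-min peak picker reads a positive amplitude even from pure
    noise, the mean peak-to-peak amplitude of a matched-length stimulus-free
    window late in the epoch is subtracted from every p1–n1 before the
    criterion is applied.  When fewer than two levels show a measurable wave,
    or the growth function never reaches the criterion, the threshold
    defaults to ``default_level`` and is flagged.
    """
    p1n1 = np.full(series.levels.size, np.nan)
    floors = np.full(series.levels.size, np.nan)
    refs = np.full(series.levels.size, np.nan)
    span = search_window[1] - search_window[0]
    epoch_ms = None
    for i, ep in enumerate(series.epochs):
        avg = average_abr(ep, series.sample_rate, filter_band=series.filter_band)
        floors[i] = avg.noise_rms
        epoch_ms = avg.waveform.size / series.sample_rate * 1e3
        res = wave1_metrics(avg.waveform, series.sample_rate, search_window=search_window)
        if res is not None:
            p1n1[i] = res.p1n1
        tail = wave1_metrics(avg.waveform, series.sample_rate,
                             search_window=(epoch_ms - 1.0 - span, epoch_ms - 1.0))
        refs[i] = tail.p1n1 if tail is not None else 0.0
    noise_p1n1 = float(np.nanmean(refs)) if np.isfinite(refs).any() else 0.0
    p1n1 = np.clip(p1n1 - noise_p1n1, 0.0, None)

    if noise_rms is not None:
        floor = float(noise_rms)
    elif criterion_mode == "mean_sd":
        floor = float(np.nanmean(floors) + np.nanstd(floors))
    else:
        floor = float(np.sqrt(np.nanmean(floors**2)))
    criterion = criterion_multiplier * floor

    ok = np.isfinite(p1n1)
    result = AudiogramResult(
        threshold=default_level, criterion=f"{criterion_multiplier}x {criterion_mode} noise floor",
        defaulted=True, freq_khz=series.freq_khz, levels=series.levels.copy(),
        p1n1=p1n1, noise_floor=floor,
    )
    if ok.sum() < 2:
        return result
    levels = series.levels[ok]
    growth = np.maximum.accumulate(p1n1[ok])  # monotone interpolant
    above = growth >= criterion
    if not above.any():
        return result
    j = int(np.argmax(above))
    if j == 0:
        thr = float(levels[0])
    else:
        l0, l1 = levels[j - 1], levels[j]
        g0, g1 = growth[j - 1], growth[j]
        thr = float(l0 + (criterion - g0) * (l1 - l0) / (g1 - g0)) if g1 > g0 else float(l1)
    result.threshold = thr
    result.defaulted = False
    return result


@dataclass
class DpoaeResult:
    level: float              # dB SPL of the primaries
    dp_amp: float             # dB SPL at 2f1-f2
    noise_floor_mean: float   # dB SPL, mean of the 20 adjacent bins
    noise_floor_sd: float     # dB SPL
    f_dp: float


def dpoae_extract(
    mic_trace: np.ndarray,
    f1: float,
    f2: float,
    sample_rate: float,
    level: float = np.nan,
    n_floor_bins: int = 20,
) -> DpoaeResult:
    """FFT magnitude at the cubic distortion frequency 2f1−f2.

    Requires the trace length to hold integer cycles of f1, f2 and 2f1−f2
    (e.g. a 1 s record with integer-Hz primaries).  The noise floor is the
    mean of ``n_floor_bins`` adjacent bins (half per side, DP bin excluded);
    extraction is refused when the DP bin collides with a primary.
    """
    x = np.asarray(mic_trace, dtype=float)
    n = x.size
    df = sample_rate / n
    f_dp = 2.0 * f1 - f2
    bins = {}
    for name, f in (("f1", f1), ("f2", f2), ("dp", f_dp)):
        b = f / df
        if abs(b - round(b)) > 1e-6:
            raise ValueError(f"{name} = {f} Hz is not an integer FFT bin (df = {df} Hz)")
        bins[name] = int(round(b))
    if bins["dp"] in (bins["f1"], bins["f2"]):
        raise ValueError("distortion-product bin collides with a primary")

    spec = np.abs(np.fft.rfft(x)) * 2.0 / n      # peak amplitude per bin, Pa
    half = n_floor_bins // 2
    idx = [bins["dp"] + k for k in range(-half, half + 1)
           if k != 0 and 0 < bins["dp"] + k < spec.size
           and bins["dp"] + k not in (bins["f1"], bins["f2"])]
    idx = idx[:n_floor_bins]

    def to_db(a_peak):
        return 20.0 * np.log10(np.maximum(a_peak / np.sqrt(2.0), 1e-30) / P_REF)

    floor_db = to_db(spec[np.asarray(idx)])
    return DpoaeResult(
        level=float(level), dp_amp=float(to_db(spec[bins["dp"]])),
        noise_floor_mean=float(floor_db.mean()), noise_floor_sd=float(floor_db.std()),
        f_dp=f_dp,
    )


def dpoae_threshold(results: list[DpoaeResult], k_sd: float = 3.0) -> float | None:
    """Lowest (interpolated) primary level at which the distortion product
    exceeds the noise-floor mean + ``k_sd``·SD; None when never exceeded."""
    res = sorted(results, key=lambda r: r.level)
    levels = np.array([r.level for r in res])
    margin = np.array([r.dp_amp - (r.noise_floor_mean + k_sd * r.noise_floor_sd) for r in res])
    above = margin > 0
    if not above.any():
        return None
    j = int(np.argmax(above))
    if j == 0:
        return float(levels[0])
    l0, l1 = levels[j - 1], levels[j]
    m0, m1 = margin[j - 1], margin[j]
    return float(l0 + (0.0 - m0) * (l1 - l0) / (m1 - m0)) if m1 > m0 else float(l1)


def normalize_growth(levels: np.ndarray, amps: np.ndarray, reference_level: float = 60.0):
    """Divide each wave-1 amplitude by the amplitude at the reference level."""
    levels = np.asarray(levels, dtype=float)
    amps = np.asarray(amps, dtype=float)
    at_ref = np.flatnonzero(np.isclose(levels, reference_level))
    if at_ref.size == 0 or not np.isfinite(amps[at_ref[0]]) or amps[at_ref[0]] == 0:
        raise ValueError(f"no usable amplitude at the {reference_level} dB reference level")
    return amps / amps[at_ref[0]]
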