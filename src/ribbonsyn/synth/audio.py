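"""Synthetic ABR epochs and DPOAE microphone records.

ABR: per sound level, every trial is the programmed evoked waveform (biphasic
p1–n1 deflections at the configured wave latencies, amplitude growing linearly
above the true threshold) plus independent Gaussian noise.  DPOAE: two primary
tones f1 and f2 = 1.2·f1 plus a cubic distortion component at 2f1−f2 at a
configured gain below the primaries, plus microphone noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._util import child_seed

__all__ = [
    "AbrSynthParams",
    "AbrSeries",
    "DpoaeSynthParams",
    "synthesize_abr_series",
    "synthesize_dpoae",
]

P_REF = 20e-6  # Pa, SPL reference


@dataclass(frozen=True)
class AbrSynthParams:
    levels: tuple = (10, 20, 30, 40, 50, 60, 70, 80)  # dB SPL
    growth_slope: float = 0.05       # µV per dB above threshold (p1-n1)
    threshold_level_true: float = 30.0
    wave_latencies: tuple = (1.5,)   # ms, p1 of each wave
    noise_rms: float = 5.0           # µV per trial
    n_trials: int = 260
    sample_rate: float = 10_000.0
    epoch_duration: float = 0.010    # s
    freq_khz: float = 23.0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if self.noise_rms <= 0:
            raise ValueError("noise_rms must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class AbrSeries:
    """Level series of raw ABR trial epochs (µV), one (n_trials, n_samples) matrix per level."""

    freq_khz: float
    levels: np.ndarray
    epochs: list
    sample_rate: float
    filter_band: tuple = (300.0, 3000.0)
    meta: dict = field(default_factory=dict)


def _biphasic(t_s: np.ndarray, latency_ms: float, width_ms: float = 0.15,
              separation_ms: float = 0.5) -> np.ndarray:
    """p1-n1 deflection with unit peak-to-peak amplitude."""
    t = t_s * 1e3
    g = lambda mu: np.exp(-0.5 * ((t - mu) / width_ms) ** 2)
    w = g(latency_ms) - g(latency_ms + separation_ms)
    return w / (w.max() - w.min())


def abr_signal(params: AbrSynthParams, level_db: float, t: np.ndarray) -> np.ndarray:
    """Noiseless evoked waveform (µV) at one level."""
    amp = params.growth_slope * max(0.0, level_db - params.threshold_level_true)
    sig = np.zeros_like(t)
    for i, lat in enumerate(params.wave_latencies):
        sig += amp / (i + 1) * _biphasic(t, lat)
    return sig


def synthesize_abr_series(params: AbrSynthParams, seed: int | None = None) -> AbrSeries:
    rng = np.random.default_rng(child_seed(seed, 3))
    n = int(round(params.epoch_duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    epochs = []
    for level in params.levels:
        sig = abr_signal(params, level, t)
        noise = rng.normal(0.0, params.noise_rms, size=(params.n_trials, n))
        epochs.append(sig[None, :] + noise)
    return AbrSeries(freq_khz=params.freq_khz, levels=np.asarray(params.levels, float),
                     epochs=epochs, sample_rate=params.sample_rate,
                     meta={"params": params, "seed": seed})


@dataclass(frozen=True)
class DpoaeSynthParams:
    f1: float = 10_000.0             # Hz; f2 = 1.2*f1, DP at 2f1-f2 = 0.8*f1
    levels: tuple = (20, 30, 40, 50, 60, 70, 80)
    dp_gain: float = -20.0           # dB of the 2f1-f2 component re primaries; -inf disables
    noise_floor_rms: float = 2e-5    # Pa
    duration: float = 1.0
    sample_rate: float = 200_000.0

    def __post_init__(self) -> None:
        if self.duration < 1.0 - 1e-12:
            raise ValueError("duration must be >= 1 s for 1 Hz FFT resolution")

    @property
    def f2(self) -> float:
        return 1.2 * self.f1

    @property
    def f_dp(self) -> float:
        return 2.0 * self.f1 - self.f2


def synthesize_dpoae(params: DpoaeSynthParams, level_db: float,
                     seed: int | None = None) -> np.ndarray:
    """Microphone trace (Pa) for one primary level (l1 = l2 = level_db)."""
    rng = np.random.default_rng(child_seed(seed, 4))
    n = int(round(params.duration * params.sample_rate))
    t = np.arange(n) / params.sample_rate
    a_primary = np.sqrt(2.0) * P_REF * 10.0 ** (level_db / 20.0)
    trace = a_primary * (np.sin(2 * np.pi * params.f1 * t) + np.sin(2 * np.pi * params.f2 * t))
    if np.isfinite(params.dp_gain):
        a_dp = np.sqrt(2.0) * P_REF * 10.0 ** ((level_db + params.dp_gain) / 20.0)
        trace = trace + a_dp * np.sin(2 * np.pi * params.f_dp * t)
    if params.noise_floor_rms:
        trace = trace + rng.normal(0.0, params.noise_floor_rms, n)
    return trace
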