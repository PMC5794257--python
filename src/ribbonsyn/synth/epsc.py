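"""Synthetic postsynaptic (EPSC) recordings with ground truth.

Event times follow an inhomogeneous Poisson process whose rate jumps from a
spontaneous baseline to an evoked profile at the high-K⁺ switch: a linear rise
to the peak rate over ``time_to_peak`` followed by an exponential relaxation
toward a plateau (a fraction of the peak; ~50% for sustained fibers, ~0 for
transient ones).  Each event is a difference-of-exponentials inward current;
amplitudes come from a two-component mixture (a small Gaussian peak plus a
Gaussian or gamma main body) and a subset of the small events carries a slow
decay, mirroring the small-slow subpopulation seen at ribbonless synapses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._util import child_seed

__all__ = [
    "EpscTrainParams",
    "EpscTrain",
    "epsc_rate",
    "sample_amplitudes",
    "epsc_template",
    "render_events",
    "generate_epsc_train",
]


@dataclass(frozen=True)
class EpscTrainParams:
    """Event-train and event-shape parameters (rates 1/s, amplitudes pA, taus ms)."""

    baseline_rate: float = 1.0
    peak_rate: float = 57.0
    time_to_peak: float = 21.0
    decay_mode: str = "sustained"       # or "transient"
    rate_decay_tau: float = 20.0
    sustain_frac: float | None = None   # plateau/peak; default by decay_mode
    k_onset: float = 10.0               # time of high-K+ switch, s
    small_frac: float = 0.01
    small_mean: float = 50.0
    small_sd: float = 12.0
    main_dist: str = "gaussian"         # or "gamma"
    main_params: tuple = (173.5, 45.0)  # gaussian: (mean, sd); gamma: (shape, scale)
    rise_tau: float = 0.15
    decay_tau_main: float = 0.45
    small_slow_frac: float = 0.0044     # overall fraction, drawn among small events
    decay_tau_slow: float = 1.5
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.small_frac <= 1.0 and 0.0 <= self.small_slow_frac <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.baseline_rate, self.peak_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if self.decay_mode not in ("sustained", "transient"):
            raise ValueError("decay_mode must be 'sustained' or 'transient'")
        if self.main_dist not in ("gaussian", "gamma"):
            raise ValueError("main_dist must be 'gaussian' or 'gamma'")

    @property
    def plateau_rate(self) -> float:
        frac = self.sustain_frac
        if frac is None:
            frac = 0.5 if self.decay_mode == "sustained" else 0.0
        return frac * self.peak_rate


def epsc_rate(params: EpscTrainParams, t) -> np.ndarray:
    """Programmed event rate (events/s) at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    u = t - params.k_onset
    rise = params.baseline_rate + (params.peak_rate - params.baseline_rate) * np.clip(
        u / max(params.time_to_peak, 1e-9), 0.0, 1.0
    )
    p = params.plateau_rate
    fall = p + (params.peak_rate - p) * np.exp(
        -np.clip(u - params.time_to_peak, 0.0, None) / max(params.rate_decay_tau, 1e-9)
    )
    evoked = np.where(u < params.time_to_peak, rise, fall)
    return np.where(u < 0, params.baseline_rate, evoked)


def sample_amplitudes(params: EpscTrainParams, n: int, seed: int | None = None,
                      rng: np.random.Generator | None = None):
    """Draw ``n`` amplitudes (pA, positive magnitudes) and subpopulation labels."""
    if rng is None:
        rng = np.random.default_rng(child_seed(seed, 1))
    small = rng.random(n) < params.small_frac
    amps = np.empty(n)
    amps[small] = rng.normal(params.small_mean, params.small_sd, small.sum())
    n_main = int((~small).sum())
    if params.main_dist == "gaussian":
        mu, sd = params.main_params
        amps[~small] = rng.normal(mu, sd, n_main)
    else:
        shape, scale = params.main_params
        amps[~small] = rng.gamma(shape, scale, n_main)
    np.clip(amps, 5.0, None, out=amps)  # physical floor: positive magnitudes

    labels = np.where(small, "small", "main").astype(object)
    if params.small_frac > 0 and params.small_slow_frac > 0:
        p_slow = min(params.small_slow_frac / params.small_frac, 1.0)
        slow = small & (rng.random(n) < p_slow)
        labels[slow] = "small_slow"
    return amps, labels


def epsc_template(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials (positive), zero for t < 0."""
    t = np.clip(np.asarray(t_ms, dtype=float), 0.0, None)
    shape = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    tp = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-tp / decay_tau) - np.exp(-tp / rise_tau)
    out = shape / peak
    out[np.asarray(t_ms) < 0] = 0.0
    return out


def render_events(events: pd.DataFrame, duration: float, sample_rate: float) -> np.ndarray:
    """Noiseless trace (pA, inward negative) reconstructed from an event table."""
    n = int(round(duration * sample_rate))
    trace = np.zeros(n)
    dt_ms = 1e3 / sample_rate
    for t0, amp, rise, dec in zip(events["t_s"], events["amp_pA"],
                                  events["rise_ms"], events["decay_ms"]):
        i0 = int(np.ceil(t0 * sample_rate))
        span = int(round((dec * 10.0 + 5.0 * rise) / dt_ms))
        i1 = min(i0 + span, n)
        if i0 >= n:
            continue
        tt = (np.arange(i0, i1) / sample_rate - t0) * 1e3
        trace[i0:i1] -= amp * epsc_template(tt, rise, dec)
    return trace


@dataclass
class EpscTrain:
    sample_rate: float
    trace_pa: np.ndarray
    events: pd.DataFrame
    params: EpscTrainParams
    overlap_flag: bool = False
    meta: dict = field(default_factory=dict)


def generate_epsc_train(
    params: EpscTrainParams,
    duration: float,
    sample_rate: float = 50_000.0,
    seed: int | None = None,
    overlap_density_bound: float = 0.5,
) -> EpscTrain:
    """Simulate a bouton recording: noisy current trace plus ground-truth table.

    The ground truth lists every event's onset time, amplitude, rise/decay
    taus and subpopulation label; ``render_events`` on that table reproduces
    the noiseless trace exactly.
    """
    rng = np.random.default_rng(child_seed(seed, 2))
    rate_max = float(np.max(epsc_rate(params, np.linspace(0, duration, 2049))))
    n_cand = rng.poisson(rate_max * duration) if rate_max > 0 else 0
    t_cand = np.sort(rng.random(n_cand) * duration)
    keep = rng.random(n_cand) * rate_max < epsc_rate(params, t_cand)
    t_ev = t_cand[keep]
    n = t_ev.size

    amps, labels = sample_amplitudes(params, n, rng=rng)
    decays = np.where(labels == "small_slow", params.decay_tau_slow, params.decay_tau_main)
    rises = np.full(n, params.rise_tau)

    events = pd.DataFrame({
        "t_s": t_ev, "amp_pA": amps, "rise_ms": rises,
        "decay_ms": decays, "label": labels.astype(str),
    })

    overlap = rate_max * (params.decay_tau_main * 5e-3) > overlap_density_bound
    if overlap:
        warnings.warn("expected event density implies superposed EPSCs", stacklevel=2)

    trace = render_events(events, duration, sample_rate)
    if params.noise_sd:
        trace = trace + rng.normal(0.0, params.noise_sd, trace.shape)
    return EpscTrain(sample_rate=sample_rate, trace_pa=trace, events=events,
                     params=params, overlap_flag=bool(overlap),
                     meta={"duration_s": duration, "seed": seed})
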