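"""Forward model of a voltage-clamped hair cell under a two-sine protocol.

The electrical model is the standard three-element patch-clamp circuit: a
series (access) resistance Rs feeding the parallel combination of the membrane
resistance Rm and the membrane capacitance Cm(t).  Exocytosis is represented
phenomenologically as a prescribed capacitance trajectory ΔCm(t) added to the
resting Cm: a release latency, a linear ramp (the readily releasable, linear
component), an additional superlinear ramp from a configurable onset, and a
single-exponential return toward baseline after the step (endocytosis).

A Boltzmann-gated Ca²⁺ current is added from the *sine-free* command: channel
gating is slow compared with the kHz capacitance probe, so the Ca current
tracks the step trajectory only.  This keeps the current at f1 and f2 a purely
passive (RC) response, which is also what makes the dual-sine estimator exact
on noiseless sweeps.

Integration uses the exact exponential update of the (per-sample linear) RC
ODE with the sinusoidal forcing integrated analytically, so the sampled trace
equals the continuous-time solution at sample instants to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .._util import child_seed, first_order_scan

__all__ = [
    "CellModelParams",
    "StimulusProtocol",
    "ExoTrajectoryParams",
    "SweepRecording",
    "make_two_sine_protocol",
    "generate_exo_trajectory",
    "exo_delta_cm",
    "simulate_voltage_clamp",
]


@dataclass(frozen=True)
class CellModelParams:
    """Passive cell parameters plus the steady-state Ca²⁺ conductance.

    Units: cm_base pF, rs/rm MΩ, voltages mV, g_max_ca nS.
    """

    cm_base: float = 10.0
    rs: float = 10.0
    rm: float = 500.0
    e_rev_ca: float = 30.0
    g_max_ca: float = 0.0
    v_half_ca: float = -34.0
    slope_ca: float = 7.0

    def __post_init__(self) -> None:
        if self.cm_base <= 0 or self.rs <= 0 or self.rm <= 0:
            raise ValueError("cm_base, rs and rm must be positive")
        if self.slope_ca <= 0:
            raise ValueError("Boltzmann slope must be positive")

    def ca_current_pa(self, v_mv):
        """Steady-state Ca current (pA, inward negative) at membrane voltage v (mV)."""
        m = 1.0 / (1.0 + np.exp((self.v_half_ca - np.asarray(v_mv)) / self.slope_ca))
        return self.g_max_ca * m * (np.asarray(v_mv) - self.e_rev_ca)

    def admittance(self, freq_hz):
        """Closed-form complex admittance Y(ω) = 1/(Rs + Rm/(1+jωRmCm)) in siemens."""
        w = 2.0 * np.pi * np.asarray(freq_hz, dtype=float)
        rs, rm, cm = self.rs * 1e6, self.rm * 1e6, self.cm_base * 1e-12
        return 1.0 / (rs + rm / (1.0 + 1j * w * rm * cm))


@dataclass(frozen=True)
class StimulusProtocol:
    """Two-sine + step command. Voltages mV, times s, frequencies Hz.

    ``f2`` is 2·f1 by construction; ``amp1``/``amp2`` are the per-sine
    amplitudes (the summed command spans ``amp1+amp2`` around the step).
    """

    holding_v: float
    step_v: float
    step_onset: float
    step_duration: float
    amp1: float
    amp2: float
    f1: float
    sample_rate: float
    total_duration: float
    junction_mv: float = 4.0  # metadata: voltages quoted are junction-corrected

    def __post_init__(self) -> None:
        spp = self.sample_rate / self.f1
        if abs(spp - round(spp)) > 1e-9:
            raise ValueError(
                f"sample_rate must be an integer multiple of f1 "
                f"({self.sample_rate} Hz / {self.f1} Hz = {spp} samples per period)"
            )
        if self.total_duration + 1e-12 < self.step_onset + self.step_duration:
            raise ValueError("total_duration must cover the step")

    @property
    def f2(self) -> float:
        return 2.0 * self.f1

    @property
    def samples_per_period(self) -> int:
        return int(round(self.sample_rate / self.f1))

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration * self.sample_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def dc_voltage(self, t: np.ndarray) -> np.ndarray:
        """Sine-free command (mV): holding plus the step window."""
        v = np.full(t.shape, self.holding_v)
        in_step = (t >= self.step_onset) & (t < self.step_onset + self.step_duration)
        v[in_step] += self.step_v - self.holding_v
        return v

    def command_voltage(self, t: np.ndarray) -> np.ndarray:
        v = self.dc_voltage(t)
        if self.amp1:
            v = v + self.amp1 * np.sin(2 * np.pi * self.f1 * t)
        if self.amp2:
            v = v + self.amp2 * np.sin(2 * np.pi * self.f2 * t)
        return v


def make_two_sine_protocol(
    f1: float = 5000.0,
    sine_amplitude: float = 40.0,
    holding_v: float = -84.0,
    step_v: float = -39.0,
    step_onset: float = 0.5,
    step_duration: float = 1.0,
    sample_rate: float = 200_000.0,
    total_duration: float | None = None,
    split: float = 0.5,
) -> StimulusProtocol:
    """Build a dual-sine protocol.

    ``sine_amplitude`` is the summed sine budget; by default it is split
    equally so each sine has amplitude ``sine_amplitude/2`` (a 40 mV dual
    sinusoid → 20 mV per frequency).  Step edges are snapped to the sample
    grid so period windows containing an edge are well defined.
    """
    spp = sample_rate / f1
    if abs(spp - round(spp)) > 1e-9:
        raise ValueError(
            f"non-integer samples per f1 period: {sample_rate}/{f1} = {spp}"
        )
    dt = 1.0 / sample_rate
    step_onset = round(step_onset / dt) * dt
    step_duration = round(step_duration / dt) * dt
    if total_duration is None:
        total_duration = step_onset + step_duration + 0.5
    return StimulusProtocol(
        holding_v=holding_v,
        step_v=step_v,
        step_onset=step_onset,
        step_duration=step_duration,
        amp1=sine_amplitude * split,
        amp2=sine_amplitude * (1.0 - split),
        f1=f1,
        sample_rate=sample_rate,
        total_duration=total_duration,
    )


@dataclass(frozen=True)
class ExoTrajectoryParams:
    """Ground-truth exocytosis trajectory. Times s, rates fF/s, capacities fF."""

    latency: float = 0.102
    linear_rate: float = 101.0
    linear_capacity: float = 52.0
    superlinear_onset: float = 0.6168515
    superlinear_rate: float = 582.0
    superlinear_capacity: float = 223.0
    endo_tau: float = 6.0

    def __post_init__(self) -> None:
        vals = (self.latency, self.linear_rate, self.linear_capacity,
                self.superlinear_onset, self.superlinear_rate,
                self.superlinear_capacity, self.endo_tau)
        if any(v < 0 for v in vals):
            raise ValueError("all trajectory parameters must be nonnegative")
        if self.superlinear_rate > 0 and self.superlinear_onset < self.latency:
            raise ValueError("superlinear_onset must not precede latency")


def exo_delta_cm(params: ExoTrajectoryParams, t_rel: np.ndarray, step_duration: float) -> np.ndarray:
    """ΔCm (fF) at times ``t_rel`` relative to step onset.

    Release accrues only during the step: a linear ramp from ``latency``
    (capped at its capacity) plus a superlinear ramp from ``superlinear_onset``
    (capped likewise).  After the step, ΔCm decays exponentially with
    ``endo_tau`` toward baseline.
    """
    t = np.asarray(t_rel, dtype=float)
    t_in = np.clip(t, 0.0, step_duration)
    lin = np.clip((t_in - params.latency) * params.linear_rate, 0.0, params.linear_capacity)
    sup = np.clip((t_in - params.superlinear_onset) * params.superlinear_rate,
                  0.0, params.superlinear_capacity)
    dcm = lin + sup
    after = t > step_duration
    if np.any(after):
        if params.endo_tau > 0 and np.isfinite(params.endo_tau):
            dcm = np.where(after, dcm * np.exp(-(t - step_duration) / params.endo_tau), dcm)
        elif params.endo_tau == 0:
            dcm = np.where(after, 0.0, dcm)
    return dcm


def generate_exo_trajectory(
    params: ExoTrajectoryParams,
    step_duration: float,
    post_duration: float,
    dt: float = 2e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled ground-truth trajectory: (t relative to step onset, ΔCm fF)."""
    n = int(round((step_duration + post_duration) / dt)) + 1
    t = np.arange(n) * dt
    return t, exo_delta_cm(params, t, step_duration)


@dataclass
class SweepRecording:
    """One simulated (or loaded) voltage-clamp sweep."""

    sample_rate: float
    command_mv: np.ndarray
    current_pa: np.ndarray
    cm_true_pf: np.ndarray | None = None
    protocol: StimulusProtocol | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.current_pa.size

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def simulate_voltage_clamp(
    cell: CellModelParams,
    protocol: StimulusProtocol,
    exo: ExoTrajectoryParams | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SweepRecording:
    """Simulate the pipette current for a two-sine sweep.

    Returns the sampled command (mV), current (pA), and the ground-truth Cm
    trajectory (pF).  ``noise_sd`` is the white current noise SD in pA.
    """
    if exo is not None and exo.latency >= protocol.step_duration:
        raise ValueError("exocytosis latency extends beyond the step duration")
    fs = protocol.sample_rate
    dt = 1.0 / fs
    t = protocol.times()
    v_dc_mv = protocol.dc_voltage(t)
    v_cmd_mv = protocol.command_voltage(t)

    cm_f = np.full(t.shape, cell.cm_base * 1e-12)
    if exo is not None:
        cm_f = cm_f + exo_delta_cm(exo, t - protocol.step_onset, protocol.step_duration) * 1e-15

    rs = cell.rs * 1e6
    rm = cell.rm * 1e6
    a = (1.0 / rs + 1.0 / rm) / cm_f  # rate constant per sample, s^-1
    decay = np.exp(-a * dt)

    # exact convolution of the exponential kernel with the piecewise-constant
    # DC command and the analytic sines over each sample interval
    b_scale = 1.0 / (rs * cm_f)
    forcing = (v_dc_mv * 1e-3) * b_scale / a * (1.0 - decay)
    for amp_mv, freq in ((protocol.amp1, protocol.f1), (protocol.amp2, protocol.f2)):
        if not amp_mv:
            continue
        w = 2.0 * np.pi * freq
        phase = np.exp(1j * w * t)
        kern = (np.exp(1j * w * dt) - decay) / (a + 1j * w)
        forcing += (amp_mv * 1e-3) * b_scale * np.imag(phase * kern)

    # start from the DC steady state at holding; the residual sine transient
    # decays within ~Rs||Rm · Cm and those first periods are flagged invalid
    # downstream anyway
    vm0 = (protocol.holding_v * 1e-3) * rm / (rs + rm)
    vm = first_order_scan(decay[:-1], forcing[:-1], vm0)

    i_a = (v_cmd_mv * 1e-3 - vm) / rs
    i_pa = i_a * 1e12 + cell.ca_current_pa(v_dc_mv)
    if noise_sd:
        rng = np.random.default_rng(child_seed(seed, 0))
        i_pa = i_pa + rng.normal(0.0, noise_sd, size=i_pa.shape)

    return SweepRecording(
        sample_rate=fs,
        command_mv=v_cmd_mv,
        current_pa=i_pa,
        cm_true_pf=cm_f * 1e12,
        protocol=protocol,
        meta={"noise_sd_pa": noise_sd, "seed": seed,
              "cell": cell, "exo": exo},
    )
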