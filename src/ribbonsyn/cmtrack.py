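"""Dual-sine membrane-capacitance tracking.

Per f1 period, the discrete Fourier coefficients of the command and the
current at f1 and f2 = 2·f1 give two complex admittances.  Those two
admittances determine the three-element model Y(ω) = 1/(Rs + Rm/(1+jωRmCm))
uniquely: writing Z = 1/Y, the condition Re 1/(Z1−Rs) = Re 1/(Z2−Rs) (both
equal 1/Rm) reduces to a quadratic in Rs, after which 1/(Z−Rs) = 1/Rm + jωCm
reads off Rm and Cm.  The time resolution of the Cm track is one f1 period.

The sine-free residual current of each period (its DC Fourier coefficient)
minus a baseline-anchored passive-leak prediction is the Ca²⁺ current; its
running integral over the step is the cumulative Ca charge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth.cell import StimulusProtocol, SweepRecording

__all__ = [
    "AdmittancePoint",
    "AdmittanceSeries",
    "CmTrace",
    "EstimationError",
    "extract_admittance",
    "solve_rc",
    "track_cm",
]

#: command sine amplitude (V) below which admittance extraction is refused
V_AMPLITUDE_FLOOR = 1e-4


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class AdmittancePoint:
    freq: float          # Hz
    y: complex           # admittance, siemens
    period_index: int = 0
    t_mid: float = 0.0   # s


@dataclass
class AdmittanceSeries:
    """Per-period admittances at f1 and f2 plus the DC (sine-free) components."""

    f1: float
    f2: float
    t_mid: np.ndarray       # s, center of each period window
    y1: np.ndarray          # complex, S
    y2: np.ndarray          # complex, S
    i_dc: np.ndarray        # A, period-mean current
    v_dc: np.ndarray        # V, period-mean command

    @property
    def n_periods(self) -> int:
        return self.t_mid.size


def extract_admittance(sweep: SweepRecording, protocol: StimulusProtocol | None = None) -> AdmittanceSeries:
    """Period-by-period complex admittance Y(f) = I(f)/V(f) at f1 and f2."""
    protocol = protocol or sweep.protocol
    if protocol is None:
        raise EstimationError("a stimulus protocol is required")
    n = protocol.samples_per_period
    n_per = sweep.n_samples // n
    if n_per < 1:
        raise EstimationError("sweep shorter than one f1 period")

    i = (sweep.current_pa[: n_per * n] * 1e-12).reshape(n_per, n)
    v = (sweep.command_mv[: n_per * n] * 1e-3).reshape(n_per, n)

    j = np.arange(n)
    e1 = np.exp(-2j * np.pi * j / n)
    e2 = np.exp(-4j * np.pi * j / n)
    vf1 = (2.0 / n) * v @ e1
    vf2 = (2.0 / n) * v @ e2
    if np.abs(vf1).min() < V_AMPLITUDE_FLOOR or np.abs(vf2).min() < V_AMPLITUDE_FLOOR:
        raise EstimationError(
            "command sine amplitude at f1/f2 below numerical floor; "
            "cannot form admittance (division by ~0)"
        )
    if1 = (2.0 / n) * i @ e1
    if2 = (2.0 / n) * i @ e2

    dt = 1.0 / protocol.sample_rate
    t_mid = (np.arange(n_per) + 0.5) * n * dt
    return AdmittanceSeries(
        f1=protocol.f1, f2=protocol.f2, t_mid=t_mid,
        y1=if1 / vf1, y2=if2 / vf2,
        i_dc=i.mean(axis=1), v_dc=v.mean(axis=1),
    )


def _solve_rc_arrays(y1: np.ndarray, y2: np.ndarray, f1: float, f2: float):
    """Vectorized closed-form inversion; returns (cm_pF, rs_MΩ, rm_MΩ, valid)."""
    w1, w2 = 2 * np.pi * f1, 2 * np.pi * f2
    z1 = 1.0 / y1
    z2 = 1.0 / y2
    p1, q1 = z1.real, z1.imag
    p2, q2 = z2.real, z2.imag

    # Re 1/(Z1-Rs) = Re 1/(Z2-Rs)  =>  a·Rs² + b·Rs + c = 0
    a = p2 - p1
    b = -(p2 - p1) * (p1 + p2) + q1**2 - q2**2
    c = (p2 - p1) * p1 * p2 + p1 * q2**2 - p2 * q1**2

    with np.errstate(all="ignore"):
        disc = b**2 - 4 * a * c
        sq = np.sqrt(np.clip(disc, 0.0, None))
        qq = -0.5 * (b + np.sign(b + (b == 0)) * sq)
        roots = np.stack([qq / a, c / qq])  # numerically stable quadratic roots

        pmin = np.minimum(p1, p2)
        ok = np.isfinite(roots) & (roots > 0) & (roots < pmin)
        # if both roots are admissible pick the one most consistent in Cm
        cm_cand = np.full(roots.shape, np.nan)
        rm_cand = np.full(roots.shape, np.nan)
        mismatch = np.full(roots.shape, np.inf)
        for k in range(2):
            rs = roots[k]
            u1 = 1.0 / (z1 - rs)
            u2 = 1.0 / (z2 - rs)
            cm_a = u1.imag / w1
            cm_b = u2.imag / w2
            cm_cand[k] = 0.5 * (cm_a + cm_b)
            with np.errstate(divide="ignore"):
                rm_cand[k] = 2.0 / (u1.real + u2.real)
            mismatch[k] = np.where(ok[k], np.abs(cm_a - cm_b), np.inf)
        pick = np.argmin(mismatch, axis=0)
        idx = np.arange(y1.size)
        rs = roots[pick, idx]
        cm = cm_cand[pick, idx]
        rm = rm_cand[pick, idx]
        valid = (
            ok[pick, idx]
            & np.isfinite(cm) & np.isfinite(rm)
            & (cm > 0) & (rm > 0)
            & (disc >= 0)
            & (np.abs(a) > 1e-12 * np.maximum(np.abs(p1), 1.0))
        )
    return cm * 1e12, rs * 1e-6, rm * 1e-6, valid


def solve_rc(y1: AdmittancePoint, y2: AdmittancePoint):
    """Invert one admittance pair; returns (cm_pF, rs_MΩ, rm_MΩ).

    Raises EstimationError when the pair is inconsistent with a passive RC
    triple (the window should then be flagged invalid, never clamped).
    """
    if abs(y2.freq - 2 * y1.freq) > 1e-6 * y1.freq:
        raise EstimationError("solve_rc requires f2 = 2·f1")
    cm, rs, rm, valid = _solve_rc_arrays(
        np.asarray([y1.y]), np.asarray([y2.y]), y1.freq, y2.freq
    )
    if not valid[0]:
        raise EstimationError("admittance pair inconsistent with a passive RC triple")
    return float(cm[0]), float(rs[0]), float(rm[0])


@dataclass
class CmTrace:
    """Per-period Cm/Rs/Rm track with Ca current and cumulative charge.

    ``dcm_ff`` is referenced to the mean Cm of the baseline window; ``valid``
    flags windows where the inversion succeeded and no command discontinuity
    transient overlaps the window.
    """

    t: np.ndarray            # s, period centers
    cm_pf: np.ndarray
    rs_mohm: np.ndarray
    rm_mohm: np.ndarray
    dcm_ff: np.ndarray
    ica_pa: np.ndarray
    qca_pc: np.ndarray
    valid: np.ndarray
    step_onset: float
    step_duration: float
    baseline_window: tuple
    period: float
    meta: dict = field(default_factory=dict)

    @property
    def step_end(self) -> float:
        return self.step_onset + self.step_duration

    def baseline_stats(self) -> tuple[float, float]:
        """(mean, SD) of ΔCm over valid baseline periods, fF."""
        lo, hi = self.baseline_window
        m = self.valid & (self.t >= lo) & (self.t <= hi)
        return float(self.dcm_ff[m].mean()), float(self.dcm_ff[m].std())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "cm_pF": self.cm_pf, "rs_MOhm": self.rs_mohm,
            "rm_MOhm": self.rm_mohm, "dcm_fF": self.dcm_ff,
            "ica_pA": self.ica_pa, "qca_pC": self.qca_pc,
            "valid": self.valid.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, step_onset: float, step_duration: float,
                   baseline_window: tuple) -> "CmTrace":
        t = df["t_s"].to_numpy()
        period = float(np.median(np.diff(t))) if t.size > 1 else 2e-4
        return cls(
            t=t, cm_pf=df["cm_pF"].to_numpy(), rs_mohm=df["rs_MOhm"].to_numpy(),
            rm_mohm=df["rm_MOhm"].to_numpy(), dcm_ff=df["dcm_fF"].to_numpy(),
            ica_pa=df["ica_pA"].to_numpy(), qca_pc=df["qca_pC"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
            step_onset=step_onset, step_duration=step_duration,
            baseline_window=baseline_window, period=period,
        )


def track_cm(
    sweep: SweepRecording,
    protocol: StimulusProtocol | None = None,
    baseline_window: tuple = (0.05, 0.45),
    drop_periods: int = 6,
) -> CmTrace:
    """Estimate Cm/Rs/Rm per f1 period and derive ΔCm, i_Ca and Q_Ca.

    Periods overlapping a command discontinuity (sweep start, step onset,
    step end) are flagged invalid for ``drop_periods`` periods — the RC
    charging transient violates the per-period stationarity the DFT assumes.
    Invalid windows are propagated as gaps, never interpolated.
    """
    protocol = protocol or sweep.protocol
    adm = extract_admittance(sweep, protocol)
    cm, rs, rm, valid = _solve_rc_arrays(adm.y1, adm.y2, adm.f1, adm.f2)

    period = 1.0 / protocol.f1
    step_end = protocol.step_onset + protocol.step_duration
    for edge in (0.0, protocol.step_onset, step_end):
        trans = (adm.t_mid > edge - 0.5 * period) & (adm.t_mid < edge + drop_periods * period)
        valid &= ~trans

    lo, hi = baseline_window
    if lo >= protocol.step_onset and hi > protocol.step_onset:
        raise EstimationError("baseline window must precede the step")
    base = valid & (adm.t_mid >= lo) & (adm.t_mid <= hi)
    if not base.any():
        raise EstimationError("no valid periods inside the baseline window")

    # medians: the per-period inversion noise on Rm (and to a lesser degree
    # Rs/Cm) is heavy-tailed, which biases means under current noise
    cm_base = float(np.median(cm[base]))
    rs_base = float(np.median(rs[base]))
    rm_base = float(np.median(rm[base]))
    dcm_ff = (cm - cm_base) * 1e3

    # passive leak anchored at the baseline: I0 + g·(V - V0), g = 1/(Rs+Rm)
    i0 = float(np.median(adm.i_dc[base]))
    v0 = adm.v_dc[base].mean()
    g_leak = 1.0 / ((rs_base + rm_base) * 1e6)
    ica_a = adm.i_dc - (i0 + (adm.v_dc - v0) * g_leak)
    ica_pa = ica_a * 1e12

    # cumulative |i_Ca| over the step; invalid periods borrow the nearest
    # valid estimate so edge transients do not masquerade as Ca charge
    ica_fill = ica_pa.copy()
    if (~valid).any() and valid.any():
        idx_valid = np.flatnonzero(valid)
        nearest = idx_valid[np.searchsorted(idx_valid, np.flatnonzero(~valid)).clip(0, idx_valid.size - 1)]
        prev = idx_valid[(np.searchsorted(idx_valid, np.flatnonzero(~valid)) - 1).clip(0, idx_valid.size - 1)]
        bad = np.flatnonzero(~valid)
        use_prev = np.abs(bad - prev) < np.abs(bad - nearest)
        ica_fill[bad] = np.where(use_prev, ica_pa[prev], ica_pa[nearest])
    in_step = (adm.t_mid >= protocol.step_onset) & (adm.t_mid < step_end)
    qca_pc = np.cumsum(np.where(in_step, np.abs(ica_fill) * period, 0.0))  # pA·s = pC

    return CmTrace(
        t=adm.t_mid, cm_pf=cm, rs_mohm=rs, rm_mohm=rm, dcm_ff=dcm_ff,
        ica_pa=ica_pa, qca_pc=qca_pc, valid=valid,
        step_onset=protocol.step_onset, step_duration=protocol.step_duration,
        baseline_window=baseline_window, period=period,
        meta={"cm_base_pf": float(cm_base), "rs_base_mohm": float(rs_base),
              "rm_base_mohm": float(rm_base), "drop_periods": drop_periods},
    )
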