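"""Exocytosis kinetics from a Cm track.

Quantifies, per recording, the measures used to compare ribbon-bearing and
ribbonless hair cells: release latency (threshold-crossing rule), the linear
and superlinear release components (two-segment piecewise-linear fit with an
exhaustively searched changepoint and an F-test for accepting the second
segment), Ca²⁺ efficiency of the linear component (ΔCm/ΔQ_Ca, fF/pC),
the endocytosis time constant (single-exponential decay after the step), and
the population curve fits: the saturating Cm–V exponential, the Gaussian for
the superlinear-onset voltage histogram, and the Boltzmann for activation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .cmtrack import CmTrace

__all__ = [
    "ComponentResult",
    "CmVFitParams",
    "GaussianFitParams",
    "BoltzmannParams",
    "detect_release_latency",
    "segment_components",
    "compute_efficiency",
    "fit_endocytosis",
    "fit_cm_voltage",
    "fit_gaussian_hist",
    "fit_boltzmann",
]


# --------------------------------------------------------------------------
# release latency

def _boxcar_valid(y: np.ndarray, n: int) -> np.ndarray:
    """Centered boxcar over a contiguous sample sequence (edges renormalized)."""
    if n <= 1:
        return y
    kern = np.ones(n)
    return np.convolve(y, kern, mode="same") / np.convolve(np.ones_like(y), kern, mode="same")


def detect_release_latency(
    trace: CmTrace,
    k_sd: float = 3.0,
    hold_periods: int = 5,
    floor_ff: float = 0.02,
    smooth_periods: int = 1,
    baseline_stats: tuple[float, float] | None = None,
) -> float | None:
    """Time (s, re step onset) at which ΔCm first exceeds baseline mean +
    ``k_sd``·SD and stays above for ``hold_periods`` consecutive valid
    periods.  ``floor_ff`` puts an absolute floor on the criterion so the
    rule is defined on noiseless tracks.  ``smooth_periods`` applies an
    optional centered boxcar (in Cm periods) before thresholding — useful on
    noisy tracks, where the per-period SD makes the raw rule insensitive.
    Returns None when no sustained crossing occurs within the step.
    """
    m_base = trace.valid & (trace.t >= trace.baseline_window[0]) & (trace.t <= trace.baseline_window[1])
    m = trace.valid & (trace.t >= trace.step_onset) & (trace.t < trace.step_end)
    if baseline_stats is not None:
        mean, sd = baseline_stats
    else:
        base = _boxcar_valid(trace.dcm_ff[m_base], smooth_periods)
        mean, sd = float(base.mean()), float(base.std())
    thr = mean + max(k_sd * sd, floor_ff)
    t = trace.t[m]
    above = _boxcar_valid(trace.dcm_ff[m], smooth_periods) > thr
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= hold_periods:
            return float(t[i - hold_periods + 1] - trace.step_onset)
    return None


# --------------------------------------------------------------------------
# component segmentation

@dataclass
class ComponentResult:
    """Release components of one depolarization (magnitudes fF, rates fF/s)."""

    linear_mag: float | None = None
    linear_rate: float | None = None
    super_mag: float | None = None
    super_rate: float | None = None
    super_onset_t: float | None = None   # s re step onset
    latency: float | None = None         # s re step onset
    endo_tau: float | None = None
    efficiency: float | None = None      # fF/pC
    total_mag: float | None = None
    f_pvalue: float | None = None
    sse: float | None = None

    @property
    def has_superlinear(self) -> bool:
        return self.super_mag is not None


def _two_segment_scan(t: np.ndarray, y: np.ndarray, min_seg: int):
    """SSE of the continuous two-segment linear model for every admissible
    changepoint, via suffix-sum normal equations.  Returns (sse, beta, idx)."""
    n = t.size
    t0 = t[0]
    x = t - t0
    S1 = float(n)
    Sx, Sxx = x.sum(), (x * x).sum()
    Sy, Sxy, Syy = y.sum(), (x * y).sum(), (y * y).sum()

    cs_x = np.concatenate([[0.0], np.cumsum(x[::-1])])[::-1]      # suffix sums
    cs_xx = np.concatenate([[0.0], np.cumsum((x * x)[::-1])])[::-1]
    cs_y = np.concatenate([[0.0], np.cumsum(y[::-1])])[::-1]
    cs_xy = np.concatenate([[0.0], np.cumsum((x * y)[::-1])])[::-1]
    cs_n = np.arange(n, -1, -1, dtype=float)

    cand = np.arange(min_seg, n - min_seg)
    tc = x[cand]
    ns = cs_n[cand]
    Sxs, Sxxs, Sys, Sxys = cs_x[cand], cs_xx[cand], cs_y[cand], cs_xy[cand]
    Sr = Sxs - tc * ns
    Srr = Sxxs - 2 * tc * Sxs + tc * tc * ns
    Srx = Sxxs - tc * Sxs
    Sry = Sxys - tc * Sys

    M = np.empty((cand.size, 3, 3))
    M[:, 0, 0] = S1; M[:, 0, 1] = Sx;  M[:, 0, 2] = Sr
    M[:, 1, 0] = Sx; M[:, 1, 1] = Sxx; M[:, 1, 2] = Srx
    M[:, 2, 0] = Sr; M[:, 2, 1] = Srx; M[:, 2, 2] = Srr
    v = np.stack([np.full(cand.size, Sy), np.full(cand.size, Sxy), Sry], axis=1)
    try:
        beta = np.linalg.solve(M, v[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.full((cand.size, 3), np.nan)
        for i in range(cand.size):
            try:
                beta[i] = np.linalg.solve(M[i], v[i])
            except np.linalg.LinAlgError:
                pass
    sse = Syy - np.einsum("ij,ij->i", beta, v)
    sse = np.where(np.isfinite(sse), sse, np.inf)
    best = int(np.argmin(sse))
    return float(sse[best]), beta[best], int(cand[best])


def segment_components(
    trace: CmTrace,
    step_window: tuple | None = None,
    alpha: float = 0.01,
    latency: float | None = None,
    min_seg: int = 5,
    latency_kwargs: dict | None = None,
) -> ComponentResult:
    """Two-segment piecewise-linear decomposition of ΔCm during the step.

    The changepoint (superlinear onset) is searched exhaustively over period
    indices; the two-segment model is accepted only when its SSE improvement
    over a single line passes an F-test at ``alpha``.  Because the changepoint
    is selected by minimizing SSE over all candidates, the raw F p-value is
    Bonferroni-adjusted by the candidate count; this keeps the false-positive
    rate on single-segment data at or below ``alpha``.  Magnitudes are the
    fitted ΔCm accrued per segment, so they sum to the total ΔCm over the
    fitted window.
    """
    if latency is None:
        latency = detect_release_latency(trace, **(latency_kwargs or {}))
    if latency is None:
        return ComponentResult(latency=None)
    lo, hi = step_window if step_window is not None else (latency, trace.step_duration)
    m = (
        trace.valid
        & (trace.t >= trace.step_onset + lo)
        & (trace.t <= trace.step_onset + hi)
    )
    t = trace.t[m]
    y = trace.dcm_ff[m]
    if t.size < 2 * min_seg + 2:
        return ComponentResult(latency=latency)

    # single line
    A = np.stack([np.ones_like(t), t - t[0]], axis=1)
    coef1, res1, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse1 = float(res1[0]) if res1.size else float(((A @ coef1 - y) ** 2).sum())

    sse2, beta, ci = _two_segment_scan(t, y, min_seg)
    n = t.size
    scale = max(float((y**2).sum()), 1.0)
    two_seg = False
    pval = None
    if sse2 <= 1e-12 * scale < sse1:
        two_seg, pval = True, 0.0
    elif sse1 > 1e-12 * scale and sse2 < sse1:
        f = ((sse1 - sse2) / 2.0) / (sse2 / (n - 4))
        n_candidates = max(n - 2 * min_seg, 1)
        pval = float(min(stats.f.sf(f, 2, n - 4) * n_candidates, 1.0))
        two_seg = pval < alpha

    # magnitudes are referenced to the pre-step baseline (ΔCm = 0 at release
    # onset), so a late-biased latency estimate does not truncate them
    if two_seg:
        b0, b1, b2 = beta
        tc = t[ci]
        y_cp = b0 + b1 * (tc - t[0])
        y_end = b0 + b1 * (t[-1] - t[0]) + b2 * (t[-1] - tc)
        return ComponentResult(
            linear_mag=float(y_cp), linear_rate=float(b1),
            super_mag=float(y_end - y_cp), super_rate=float(b1 + b2),
            super_onset_t=float(tc - trace.step_onset), latency=latency,
            total_mag=float(y_end), f_pvalue=pval, sse=sse2,
        )
    y_end = coef1[0] + coef1[1] * (t[-1] - t[0])
    return ComponentResult(
        linear_mag=float(y_end), linear_rate=float(coef1[1]),
        latency=latency, total_mag=float(y_end),
        f_pvalue=pval, sse=sse1,
    )


# --------------------------------------------------------------------------
# Ca efficiency and endocytosis

def _window_value(trace: CmTrace, arr: np.ndarray, t_at: float, half_k: int = 2) -> float:
    """Median of the ``2·half_k+1`` valid samples nearest ``t_at``."""
    idx = np.flatnonzero(trace.valid)
    if idx.size == 0:
        raise ValueError("trace has no valid periods")
    order = np.argsort(np.abs(trace.t[idx] - t_at))
    sel = idx[order[: 2 * half_k + 1]]
    return float(np.median(arr[sel]))


def compute_efficiency(trace: CmTrace, window: tuple[float, float],
                       half_k: int = 15) -> float | None:
    """ΔCm / ΔQ_Ca (fF/pC) over ``window`` (s, re step onset).

    Endpoint values are medians over ``2·half_k+1`` neighbouring valid
    periods (centered, so ramps contribute no first-order bias).  Returns
    None (undefined) when no Ca charge accrued over the window.
    """
    t0, t1 = (trace.step_onset + w for w in window)
    dcm = (_window_value(trace, trace.dcm_ff, t1, half_k)
           - _window_value(trace, trace.dcm_ff, t0, half_k))
    dq = (_window_value(trace, trace.qca_pc, t1, half_k)
          - _window_value(trace, trace.qca_pc, t0, half_k))
    if abs(dq) < 1e-9:
        return None
    return dcm / dq


def fit_endocytosis(
    trace: CmTrace,
    post_window: tuple[float, float] | None = None,
) -> tuple[float, dict] | None:
    """Single-exponential decay fit of ΔCm after the step: A·exp(−t/τ).

    ``post_window`` is in seconds relative to step end (default: everything
    after the step).  Returns (tau_s, diagnostics) or None when the trace
    does not decay.
    """
    lo, hi = post_window if post_window is not None else (0.0, np.inf)
    m = trace.valid & (trace.t >= trace.step_end + lo) & (trace.t <= trace.step_end + hi)
    t = trace.t[m] - trace.step_end
    y = trace.dcm_ff[m]
    if t.size < 10 or y.max() <= 0:
        return None
    n4 = max(t.size // 4, 1)
    if y[-n4:].mean() >= 0.9 * y[:n4].mean():
        return None  # not decaying

    pos = y > 0.05 * y[:n4].mean()
    slope, intercept = np.polyfit(t[pos], np.log(np.clip(y[pos], 1e-12, None)), 1)
    tau0 = -1.0 / slope if slope < 0 else t[-1] / 2
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, tau: a * np.exp(-x / tau),
            t, y, p0=[float(np.exp(intercept)), float(abs(tau0))], maxfev=10000,
        )
    except RuntimeError:
        return None
    a, tau = popt
    resid = float(np.sqrt(np.mean((a * np.exp(-t / tau) - y) ** 2)))
    if tau <= 0:
        return None
    return float(tau), {"amplitude_ff": float(a), "rms_residual_ff": resid}


# --------------------------------------------------------------------------
# population curve fits

@dataclass
class CmVFitParams:
    y0: float      # fF baseline
    a1: float      # fF asymptote
    x0: float      # mV, voltage where release is first seen
    t: float       # mV, voltage dependence scale
    rms_residual: float = 0.0
    degenerate: bool = False


def _cmv_saturating(x, y0, a1, x0, t):
    return y0 + a1 * (1.0 - np.exp(-np.clip(x - x0, 0.0, None) / t))


def _cmv_literal(x, y0, a1, x0, t):
    return y0 + a1 * np.exp(-(x - x0) / t)


def fit_cm_voltage(points: Sequence[tuple[float, float]], form: str = "saturating") -> CmVFitParams:
    """Fit the ΔCm-vs-step-voltage relationship with a saturating exponential
    Y = Y0 + A1·(1 − exp(−(x−x0)/t)) for x ≥ x0 (A1 the asymptote, x0 the
    first-release voltage, t the voltage-dependence scale in mV).  The plain
    decaying-exponential form is available as ``form='literal'``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 (voltage, dCm) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(y) < 1e-9:
        return CmVFitParams(y0=float(y.mean()), a1=0.0, x0=float(x.min()),
                            t=1.0, degenerate=True)
    fun = _cmv_saturating if form == "saturating" else _cmv_literal
    rng_y = np.ptp(y)
    above = x[y > y.min() + 0.05 * rng_y]
    x0_guess = float(above.min()) if above.size else float(x.min())
    p0 = [float(y.min()), float(rng_y), x0_guess, max((x.max() - x0_guess) / 3.0, 1.0)]
    popt, _ = optimize.curve_fit(fun, x, y, p0=p0, maxfev=20000)
    resid = float(np.sqrt(np.mean((fun(x, *popt) - y) ** 2)))
    return CmVFitParams(y0=float(popt[0]), a1=float(popt[1]), x0=float(popt[2]),
                        t=float(popt[3]), rms_residual=resid)


@dataclass
class GaussianFitParams:
    y0: float
    a: float       # area
    w: float       # width (2·sigma of the equivalent normal density)
    xc: float      # center, mV
    rms_residual: float = 0.0


def _gauss_form(x, y0, a, w, xc):
    return y0 + (a / (w * np.sqrt(np.pi / 2.0))) * np.exp(-2.0 * ((x - xc) / w) ** 2)


def fit_gaussian_hist(values: np.ndarray, bins="fd") -> GaussianFitParams:
    """Histogram (probability density) of superlinear-onset voltages fitted
    with Y = Y0 + (A/(w·√(π/2)))·exp(−2((x−xc)/w)²); w equals twice the SD of
    the matching normal density."""
    values = np.asarray(values, dtype=float)
    dens, edges = np.histogram(values, bins=bins, density=True)
    if np.count_nonzero(dens) < 5:
        raise ValueError("fewer than 5 occupied histogram bins; fit refused")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [0.0, 1.0, 2.0 * values.std(), float(values.mean())]
    popt, _ = optimize.curve_fit(_gauss_form, centers, dens, p0=p0, maxfev=20000)
    popt[2] = abs(popt[2])
    resid = float(np.sqrt(np.mean((_gauss_form(centers, *popt) - dens) ** 2)))
    return GaussianFitParams(y0=float(popt[0]), a=float(popt[1]), w=float(popt[2]),
                             xc=float(popt[3]), rms_residual=resid)


@dataclass
class BoltzmannParams:
    v_half: float
    slope: float
    amp: float
    rms_residual: float = 0.0
    monotonic: bool = True


def _boltz(v, amp, v_half, slope):
    return amp / (1.0 + np.exp((v_half - v) / slope))


def fit_boltzmann(iv_points: Sequence[tuple[float, float]]) -> BoltzmannParams:
    """Least-squares Boltzmann fit of normalized activation vs voltage;
    activation increases with depolarization (slope > 0)."""
    pts = np.asarray(iv_points, dtype=float)
    v, i = pts[:, 0], pts[:, 1]
    order = np.argsort(v)
    mono = bool(np.all(np.diff(i[order]) >= -0.05 * max(np.ptp(i), 1e-12)))
    p0 = [float(i.max()), float(np.median(v)), 7.0]
    popt, _ = optimize.curve_fit(_boltz, v, i, p0=p0, maxfev=20000)
    amp, v_half, slope = popt
    resid = float(np.sqrt(np.mean((_boltz(v, *popt) - i) ** 2)))
    return BoltzmannParams(v_half=float(v_half), slope=float(slope), amp=float(amp),
                           rms_residual=resid, monotonic=mono)
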