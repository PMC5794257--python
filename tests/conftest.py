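import numpy as np
import pytest

from ribbonsyn.cmtrack import CmTrace, track_cm
from ribbonsyn.synth import (
    cell_from_preset,
    exo_from_preset,
    protocol_from_preset,
    simulate_voltage_clamp,
)

BASELINE = (0.05, 0.45)


def make_cm_trace(dcm_ff, period=2e-4, step_onset=0.5, step_duration=1.0,
                  ica_pa=None, qca_pc=None, cm_base_pf=10.0):
    """Assemble a CmTrace directly from a ΔCm array (analysis-side fixture)."""
    dcm_ff = np.asarray(dcm_ff, dtype=float)
    n = dcm_ff.size
    t = (np.arange(n) + 0.5) * period
    ica = np.zeros(n) if ica_pa is None else np.asarray(ica_pa, dtype=float)
    if qca_pc is None:
        in_step = (t >= step_onset) & (t < step_onset + step_duration)
        qca = np.cumsum(np.where(in_step, np.abs(ica) * period, 0.0))
    else:
        qca = np.asarray(qca_pc, dtype=float)
    return CmTrace(
        t=t, cm_pf=cm_base_pf + dcm_ff * 1e-3, rs_mohm=np.full(n, 10.0),
        rm_mohm=np.full(n, 500.0), dcm_ff=dcm_ff, ica_pa=ica, qca_pc=qca,
        valid=np.ones(n, dtype=bool), step_onset=step_onset,
        step_duration=step_duration, baseline_window=(0.05, step_onset - 0.05),
        period=period,
    )


@pytest.fixture(scope="session")
def wt_sweep():
    """Noiseless WT-preset sweep (1 s step, 0.7 s tail)."""
    return simulate_voltage_clamp(
        cell_from_preset("wt"),
        protocol_from_preset("wt", total_duration=2.2),
        exo=exo_from_preset("wt"),
    )


@pytest.fixture(scope="session")
def wt_trace(wt_sweep):
    return track_cm(wt_sweep, baseline_window=BASELINE)


@pytest.fixture(scope="session")
def ko_trace():
    sweep = simulate_voltage_clamp(
        cell_from_preset("ko"),
        protocol_from_preset("ko", total_duration=2.2),
        exo=exo_from_preset("ko"),
    )
    return track_cm(sweep, baseline_window=BASELINE)
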