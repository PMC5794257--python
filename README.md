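# ribbonsyn

Analysis toolkit for hair-cell **ribbon-synapse electrophysiology**: dual-sine
whole-cell capacitance tracking, exocytosis component/kinetics analysis,
postsynaptic EPSC event statistics, and ABR/DPOAE audiometry — together with
synthetic-data generators that produce every input with known ground truth.

## Who it is for

Auditory and synaptic physiologists who record from inner hair cells (IHCs)
and afferent boutons and need a reproducible, scriptable version of the
standard analysis chain:

- **Cm tracking (two-sine method).** A dual sinusoid at f1 and f2 = 2·f1
  rides on the command step; per f1 period the complex admittances
  Y(ω) = I(ω)/V(ω) at both frequencies determine the three-element model
  Y(ω) = 1/(Rs + Rm/(1 + jωRmCm)) in closed form, yielding Cm, Rs and Rm at
  the time resolution of one f1 period (0.16–0.32 ms).
- **Exocytosis kinetics.** Release latency (baseline + 3 SD threshold with a
  hold rule), linear and superlinear release components (two-segment
  piecewise-linear fit with exhaustive changepoint search and an F-test),
  Ca²⁺ efficiency ΔCm/ΔQ_Ca (fF/pC), endocytosis τ (single-exponential
  decay), plus Cm–V, Gaussian-histogram and Boltzmann population fits.
- **EPSC analysis.** Matched-filter detection with per-event template
  refinement; amplitude/rise/decay/duration metrics; 1 s / 100 ms sliding
  rate profiles with onset (+2 SD), sustained/transient classification
  (20 s horizon), time-to-peak (+3 SD in two overlapping 200 ms windows) and
  50 s integrals; two-component amplitude mixtures (small Gaussian peak +
  Gaussian-or-gamma body, BIC-selected) with the small-peak area percentage;
  Kolmogorov–Smirnov distribution comparisons.
- **Audiometry.** ABR trial averaging (300–3000 Hz zero-phase band-pass),
  wave-1 p1–n1 metrics, threshold as the interpolated level where the growth
  function reaches 5× the noise floor (80 dB SPL default when absent), and
  DPOAE extraction of the cubic distortion product at 2f1−f2 with a 20-bin
  noise floor and a mean + 3 SD threshold.

No raw recordings ship with the package; `ribbonsyn.synth` emulates them at
the parameter values of the study conditions (presets `wt` and `ko`), so
every estimator can be validated against ground truth.

## Worked example

```python
from ribbonsyn.synth import (cell_from_preset, protocol_from_preset,
                             exo_from_preset, simulate_voltage_clamp)
from ribbonsyn.cmtrack import track_cm
from ribbonsyn.exo import segment_components, compute_efficiency, fit_endocytosis

cell  = cell_from_preset("wt")            # 10 pF, 10 MOhm, Boltzmann Ca current
proto = protocol_from_preset("wt", total_duration=22.0)  # 1 s step to -39 mV
sweep = simulate_voltage_clamp(cell, proto, exo=exo_from_preset("wt"))
trace = track_cm(sweep, baseline_window=(0.05, 0.45))
comp  = segment_components(trace)
print(f"baseline Cm {trace.meta['cm_base_pf']:.2f} pF")
print(f"linear {comp.linear_mag:.1f} fF @ {comp.linear_rate:.0f} fF/s, "
      f"superlinear {comp.super_mag:.1f} fF")
print(f"efficiency {compute_efficiency(trace, (comp.latency, comp.super_onset_t)):.3f} fF/pC")
print(f"endocytosis tau {fit_endocytosis(trace)[0]:.2f} s")
```

prints

```
baseline Cm 10.00 pF
linear 52.0 fF @ 101 fF/s, superlinear 222.8 fF
efficiency 0.904 fF/pC
endocytosis tau 6.00 s
```

i.e. the estimator chain recovers the programmed resting capacitance, the
two release components (52 fF readily releasable pool released at
101 fF/s, then the 223 fF superlinear component), the stimulus–secretion
coupling of 0.9 fF of membrane per pC of Ca²⁺ charge, and the 6 s
endocytotic retrieval — all from the raw simulated current sweep.

The same chain is available from a shell:

```sh
ribbonsyn simulate --preset wt --out sweep.h5
ribbonsyn cm-track --sweep sweep.h5 --baseline 0.05:0.45 --out cmtrace.csv
ribbonsyn exo-analyze --cmtrace cmtrace.csv --step-onset 0.5 --step-duration 1.0 --out components.json
```

with further subcommands `epsc-detect`, `epsc-stats`, `epsc-compare`,
`abr-threshold`, `dpoae-threshold` and `run` (full configured pipeline with
a reproducibility manifest).

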