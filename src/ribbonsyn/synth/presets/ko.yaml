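# Ribbonless (RIBEYE knockout) study conditions for the synthetic generators.
genotype: KO

cell:
  cm_base: 10.0        # pF
  rs: 10.0             # MOhm
  rm: 500.0            # MOhm
  e_rev_ca: 30.0       # mV
  # g_max_ca sets the linear-component Ca efficiency to 0.93 fF/pC at the
  # -44 mV step: g = linear_rate / (0.93 * m_inf(-44) * |V - E|)
  g_max_ca: 5.6397     # nS
  v_half_ca: -34.0     # mV
  slope_ca: 7.0        # mV

protocol:
  f1: 5000.0           # Hz
  sine_amplitude: 40.0 # mV summed (20 mV per frequency)
  holding_v: -84.0     # mV
  step_v: -44.0        # mV, small depolarization (delayed-release regime)
  step_onset: 0.5      # s
  step_duration: 1.0   # s
  sample_rate: 200000.0  # Hz

exo:
  latency: 0.204         # s, prolonged release latency at -44 mV
  linear_rate: 75.0      # fF/s
  linear_capacity: 42.0  # fF
  superlinear_onset: 0.5 # s (unused: no superlinear phase at this weak step)
  superlinear_rate: 0.0  # fF/s
  superlinear_capacity: 0.0
  endo_tau: 7.0          # s

epsc:
  baseline_rate: 1.0     # events/s
  peak_rate: 44.0        # events/s
  time_to_peak: 9.0      # s
  decay_mode: sustained  # 7/11 fibers sustained; override for transient runs
  rate_decay_tau: 20.0   # s (transient runs use 4.0 with sustain_frac 0)
  sustain_frac: 0.5
  k_onset: 10.0          # s
  small_frac: 0.055      # enlarged small-event peak
  small_mean: 50.0       # pA
  small_sd: 12.0         # pA
  main_dist: gamma
  main_params: [6.0, 38.0]  # shape/scale; mixture median ~212 pA, ~8% > 350 pA
  rise_tau: 0.15         # ms
  decay_tau_main: 0.45   # ms
  small_slow_frac: 0.019 # enlarged small-slow subpopulation
  decay_tau_slow: 1.5    # ms
  noise_sd: 5.0          # pA

abr:
  levels: [10, 20, 30, 40, 50, 60, 70, 80]
  growth_slope: 0.04     # uV/dB, smaller wave-1 growth
  threshold_level_true: 40.0  # dB SPL, ~10 dB shift re WT
  wave_latencies: [1.5]
  noise_rms: 5.0
  n_trials: 260
  sample_rate: 10000.0
  freq_khz: 23.0

dpoae:
  f1: 10000.0
  levels: [20, 30, 40, 50, 60, 70, 80]
  dp_gain: -20.0         # outer-hair-cell function unaffected
  noise_floor_rms: 0.0036   # per-FFT-bin floor ~ -5 dB SPL over a 1 s record
  duration: 1.0
  sample_rate: 200000.0
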