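# Wild-type study conditions for the synthetic generators.
genotype: WT

cell:
  cm_base: 10.0        # pF, resting inner-hair-cell capacitance
  rs: 10.0             # MOhm, uncompensated series resistance
  rm: 500.0            # MOhm, membrane resistance
  e_rev_ca: 30.0       # mV, Ca current reversal
  # g_max_ca sets the linear-component Ca efficiency to 0.9 fF/pC at the
  # -39 mV step: g = linear_rate / (0.9 * m_inf(-39) * |V - E|)
  g_max_ca: 4.9487     # nS
  v_half_ca: -34.0     # mV, half-activation of the Ca conductance
  slope_ca: 7.0        # mV, Boltzmann slope

protocol:
  f1: 5000.0           # Hz; Cm time resolution = 1/f1 = 0.2 ms
  sine_amplitude: 40.0 # mV summed dual-sine budget (20 mV per frequency)
  holding_v: -84.0     # mV
  step_v: -39.0        # mV, strong 1 s depolarization
  step_onset: 0.5      # s
  step_duration: 1.0   # s
  sample_rate: 200000.0  # Hz

exo:
  latency: 0.102         # s, release latency at this step
  linear_rate: 101.0     # fF/s, first (linear) component rate
  linear_capacity: 52.0  # fF, first component magnitude
  # the superlinear ramp is placed where the linear component saturates
  # (latency + 52/101) and its rate is set so the full 223 fF magnitude
  # fits inside the 1 s step: 223 / (1 - 0.6168515)
  superlinear_onset: 0.6168515   # s
  superlinear_rate: 582.0        # fF/s (observed post-changepoint slope)
  superlinear_capacity: 223.0    # fF, second component magnitude
  endo_tau: 6.0          # s, endocytosis time constant

epsc:
  baseline_rate: 1.0     # events/s, spontaneous
  peak_rate: 57.0        # events/s, evoked peak
  time_to_peak: 21.0     # s from the high-K+ switch
  decay_mode: sustained
  rate_decay_tau: 20.0   # s, relaxation from peak toward the plateau
  sustain_frac: 0.5      # plateau as fraction of peak
  k_onset: 10.0          # s, high-K+ switch time
  small_frac: 0.01       # weight of the small-amplitude Gaussian peak
  small_mean: 50.0       # pA
  small_sd: 12.0         # pA
  main_dist: gaussian
  main_params: [173.5, 45.0]  # pA mean/sd; mixture median ~173 pA
  rise_tau: 0.15         # ms
  decay_tau_main: 0.45   # ms
  small_slow_frac: 0.0044  # overall fraction of small-and-slow events
  decay_tau_slow: 1.5    # ms
  noise_sd: 5.0          # pA recording noise

abr:
  levels: [10, 20, 30, 40, 50, 60, 70, 80]  # dB SPL
  growth_slope: 0.05     # uV p1-n1 per dB above threshold
  threshold_level_true: 30.0  # dB SPL
  wave_latencies: [1.5]  # ms
  noise_rms: 5.0         # uV per trial
  n_trials: 260
  sample_rate: 10000.0   # Hz
  freq_khz: 23.0

dpoae:
  f1: 10000.0            # Hz (f2 = 1.2 f1 = 12 kHz, DP at 8 kHz)
  levels: [20, 30, 40, 50, 60, 70, 80]
  dp_gain: -20.0         # dB re primaries
  noise_floor_rms: 0.0036   # Pa; per-FFT-bin floor ~ -5 dB SPL over a 1 s record
  duration: 1.0          # s
  sample_rate: 200000.0  # Hz
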