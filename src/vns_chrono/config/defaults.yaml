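# Default stimulation-parameter ranges per innervation condition and
# default processing constants.  Units: intensity mA, pulse_width us,
# frequency Hz, num_pulses count, delay ms.
conditions:
  intact:
    n_default: 75
    ranges:
      intensity: [0.2, 1.0]
      pulse_width: [50.0, 200.0]
      frequency: [21.3, 42.7]
      num_pulses: [1, 4]
      delay: [16.0, 156.2]
  vagotomy:
    n_default: 75
    ranges:
      intensity: [0.2, 2.0]
      pulse_width: [50.0, 200.0]
      frequency: [10.0, 40.0]
      num_pulses: [1, 6]
      delay: [0.0, 298.8]
  isolated:
    n_default: 100
    ranges:
      intensity: [6.0, 9.7]
      pulse_width: [25.0, 1000.0]
      frequency: [25.0, 38.5]
      num_pulses: [5, 14]
      delay: [0.0, 382.0]

protocol:
  stim_s: 30.0
  pause_s: 30.0

# Cardiac-cycle budget used by the burst-fit check (warning only).
cycle_budget_ms: 400.0

detector:
  bandpass_hz: [5.0, 15.0]
  integrate_ms: 150.0
  refractory_ms: 200.0
  match_window_ms: 50.0

trigger:
  theta: 0.6
  decay_tau_s: 2.0
  refractory_s: 0.2
  floor_mv: 0.05
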