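# Sonication parameter sets used in the boiling-histotripsy characterization
# experiments: four one-factor sweeps (acoustic power, cycles/pulse, total
# sonication time, PRF) around the base setting 600 W / 15,000 cycles / 1 Hz
# on a 3x3x3 focal grid with 1 mm spacing. frequency_hz is the transducer
# operating frequency; total_time_s is the nominal printed duration.
frequency_hz: 1.2e6
pattern:
  grid_shape: [3, 3, 3]
  spacing_mm: 1.0
sweeps:
  acoustic_power:
    - {power_W: 500, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 902}
    - {power_W: 550, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 902}
    - {power_W: 600, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 902}
    - {power_W: 650, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 902}
  cycles_per_pulse:
    - {power_W: 600, cycles_per_pulse: 10000, prf_hz: 1.0, total_time_s: 902, pulse_length_ms_printed: 8.3}
    - {power_W: 600, cycles_per_pulse: 12000, prf_hz: 1.0, total_time_s: 902, pulse_length_ms_printed: 10.0}
    - {power_W: 600, cycles_per_pulse: 14000, prf_hz: 1.0, total_time_s: 902, pulse_length_ms_printed: 11.6}
    - {power_W: 600, cycles_per_pulse: 16000, prf_hz: 1.0, total_time_s: 902, pulse_length_ms_printed: 13.3}
    - {power_W: 600, cycles_per_pulse: 18000, prf_hz: 1.0, total_time_s: 902, pulse_length_ms_printed: 15.0}
    - {power_W: 600, cycles_per_pulse: 20000, prf_hz: 1.0, total_time_s: 902, pulse_length_ms_printed: 16.6}
  total_sonication_time:
    - {power_W: 600, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 137, repeats: 5}
    - {power_W: 600, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 274, repeats: 10}
    - {power_W: 600, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 410, repeats: 15}
    - {power_W: 600, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 574, repeats: 20}
    - {power_W: 600, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 684, repeats: 25}
    - {power_W: 600, cycles_per_pulse: 15000, prf_hz: 1.0, total_time_s: 820, repeats: 30}
  prf:
    - {power_W: 600, cycles_per_pulse: 16000, prf_hz: 0.5, total_time_s: 800, duty_cycle_pct_printed: 0.66, repeats: 15}
    - {power_W: 600, cycles_per_pulse: 16000, prf_hz: 1.0, total_time_s: 400, duty_cycle_pct_printed: 1.33, repeats: 15}
    - {power_W: 600, cycles_per_pulse: 16000, prf_hz: 2.0, total_time_s: 200, duty_cycle_pct_printed: 2.66, repeats: 15}
    - {power_W: 600, cycles_per_pulse: 16000, prf_hz: 3.0, total_time_s: 133, duty_cycle_pct_printed: 4.00, repeats: 15}
    - {power_W: 600, cycles_per_pulse: 16000, prf_hz: 4.0, total_time_s: 100, duty_cycle_pct_printed: 5.33, repeats: 15}
    - {power_W: 600, cycles_per_pulse: 16000, prf_hz: 5.0, total_time_s: 80, duty_cycle_pct_printed: 6.66, repeats: 15}
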