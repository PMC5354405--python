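# Reduced PRF sweep: 600 W, 16,000 cycles/pulse, 3x3x3 pattern, varying PRF.
# Grid and repeat counts are scaled down from the physical experiment so the
# sweep completes in seconds; raise `repeats` to 15 for the full schedule.
runs:
  - {name: prf0p5, power_w: 600, cycles_per_pulse: 16000, prf_hz: 0.5, repeats: 3}
  - {name: prf1, power_w: 600, cycles_per_pulse: 16000, prf_hz: 1.0, repeats: 3}
  - {name: prf2, power_w: 600, cycles_per_pulse: 16000, prf_hz: 2.0, repeats: 3}
  - {name: prf5, power_w: 600, cycles_per_pulse: 16000, prf_hz: 5.0, repeats: 3}
grid_shape: [35, 35, 35]
voxel_mm: 0.65
noise_sd_celsius: 0.5
cooldown_s: 10.0
seed: 1
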