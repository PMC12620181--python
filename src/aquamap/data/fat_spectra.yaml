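# Multi-peak fat spectrum presets.
#
# Peak positions are chemical shifts in ppm on the scale where water sits at
# 4.70 ppm; amplitudes are relative proton-density fractions (normalized to
# sum to 1 at load time).  The numbers are transcribed from published liver /
# vegetable-oil MR spectroscopy triglyceride models and are editable here.
# water_shift_ppm moves the water resonance (temperature correction for
# room-temperature phantom scans).
in_vivo_9peak:
  peak_ppm: [0.90, 1.30, 1.60, 2.02, 2.24, 2.75, 4.20, 5.19, 5.29]
  amplitude: [0.088, 0.642, 0.058, 0.062, 0.058, 0.006, 0.039, 0.010, 0.037]
  water_ppm: 4.70
  water_shift_ppm: 0.0
peanut_oil_9peak:
  peak_ppm: [0.90, 1.30, 1.60, 2.02, 2.24, 2.75, 4.20, 5.19, 5.29]
  amplitude: [0.080, 0.630, 0.072, 0.070, 0.050, 0.012, 0.046, 0.012, 0.028]
  water_ppm: 4.70
  water_shift_ppm: 0.14
single_peak_test:
  peak_ppm: [1.30]
  amplitude: [1.0]
  water_ppm: 4.70
  water_shift_ppm: 0.0
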