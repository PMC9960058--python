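# Reference run: model constants reported at E0 = 0.25 mg/L, with
# observations simulated over the enzyme grid used for k2 fitting.
rates:
  k1E0: 0.0066   # s^-1 at the reference E0
  k2: 0.0015     # s^-1, enzyme-independent rearrangement rate
  k3E0: 0.0002   # s^-1 at the reference E0
enzyme:
  E0: [0.25, 0.125, 0.5, 1.0]   # mg/L; first entry is the reference
grid:
  t_end_s: 20000
  n_points: 2001
seed: 0
tmax_noise_sigma: 0.0
stages: [gen_tmax, simulate, tmax, fit_k2, predict_ss]
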