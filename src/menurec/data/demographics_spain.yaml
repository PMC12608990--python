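# National demographic specification (Spanish-like reference population).
# age_density: relative density at 5-year bin midpoints (piecewise-linear
# in between); shape approximates the national population pyramid.
name: spain
age_density:
  bin_width: 5
  weights: [4.2, 4.8, 5.5, 5.5, 5.3, 5.3, 5.6, 6.2, 7.5, 7.8, 7.5, 7.2, 6.5, 5.6, 4.9, 4.0, 3.0, 2.2, 1.4]
gender: {female: 0.51, male: 0.49}
region: {coastal: 0.58, inland: 0.42}
locality: {small: 0.20, medium: 0.30, large: 0.50}
reference:
  pct_omnivore: 87.0
  pct_veg_over15: 6.0
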