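## Demo run configuration: both experimental arms at desk scale.
seed: 0

# photoconversion arm
bleed_1000: 0.131        # planted green-to-red contamination at 1,000 nm
bleed_1040: 0.146        # and at 1,040 nm
pc_slope: 0.00079        # planted median-RGR per mJ/mm^2 (dose-response slope)
wavelength_ratio: 9.05   # planted 1,040/1,000 nm median-RGR ratio
n_pc_sessions: 8         # simulated single-mouse dose-response recordings
n_pc_cells: 100          # cells per simulated field of view
dprime: 2.26             # planted stimulated-vs-reference separation
n_dprime_cells: 2000     # cells per region

# dynamic (negative-GECI) arm
n_dyn_cells: 48
fraction_tuned: 0.125
response_amplitude: 0.105  # fractional dip at the preferred direction
dyn_noise_sd: 2.0          # a.u., on a ~100 a.u. baseline
bleach_half_life_s: 2000.0
gray_s: 8.0
anova_mode: pooled
p_tuned: 0.01
p_oriented: 0.01
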