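cov_max: 10.0
glcm_distances:
- 2
- 5
n_levels: 64
normality_alpha: 0.05
out_dir: out
population_n: 120
posthoc: bonferroni
r_threshold: 0.8
repeat_angle_jitter_deg: 5.0
repeat_n: 30
repeat_perturb_radius_px: 0.5
rsd_max: 30.0
sector_span_deg: 120.0
seed: 1
size_area_ratios:
- 0.6
- 1.0
- 1.5
size_n_per_group: 10
welch: false
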