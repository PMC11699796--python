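n_genes: 5000
subpopulations:
- Asia
- Americas
- Canada-trees
- Europe-Domestic-1
- Europe-Domestic-2
- Europe-Mix
group_sizes:
- 3
- 4
- 4
- 4
- 4
- 4
la_group_means:
- 1.0
- 3.5
- 3.5
- 3.5
- 7.5
- 7.5
la_within_sd: 0.6
log2_baseline_mean: 7.0
log2_baseline_sd: 1.8
dispersion: 0.05
size_factor_log_sd: 0.25
n_de_per_group: 60
de_lfc_range:
- 1.0
- 4.0
de_down_fraction: 0.7
qtt_fraction: 0.05
qtt_alpha: 1.0
n_focal_genes: 3
n_hidden_factors: 1
hf_loading_fraction: 0.3
hf_loading_sd: 0.5
hf_phenotype_corr: 0.0
lactic_glycerol_rho: -0.85
glycerol_ethanol_rho: 0.66
glycerol_mean: 6.0
glycerol_sd: 1.2
ethanol_mean: 8.0
ethanol_sd: 0.8
residual_sugars_mean: 25.0
residual_sugars_sd: 12.0
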