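# Small synthetic experiment exercising every pipeline stage end to end.
n_cells: 64
n_samples: 4
n_pcg: 500
n_lnc: 600
n_chromosomes: 5
n_rare_genes: 10
rare_cell_fraction: 0.17
rare_log_mean: 3.0
n_noise_lnc: 350
n_malignant: 52
cnv_region_length: 150
cnv_log2_shift: 1.0
n_stemlike: 10
stem_marker_count: 30
seed: 7
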