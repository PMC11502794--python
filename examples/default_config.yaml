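alpha: 0.05
flank: 2000
lfc_threshold: 1.0
min_coverage: 5
min_delta: 0.1
out_dir: epipattern_out
seed: 0
simulation:
  baseline_mu: 0.4
  bb_dispersion: 0.1
  ccgg_per_gene: 2
  chrom_lengths:
    chr1: 4000000
    chr2: 4000000
  cpgs_per_gene: 4
  frac_true: 0.1
  gene_gap: 8000
  gene_length: 2000
  mean_coverage: 30.0
  mean_log_sigma_rna: 1.0
  mean_log_sigma_tags: 0.5
  n_genes: 300
  nb_dispersion: 0.1
  planted_delta: 0.3
  planted_lfc: 2.0
  seed: 0
  tf_fraction: 0.3
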