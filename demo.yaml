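# Demo configuration for `bindexpr all` — a scaled-down planted study.
# Any SimulationConfig field may appear under `simulate`; the other
# sections override per-stage defaults (flags win over this file).
simulate:
  n_chroms: 2
  chrom_length: 4000000
  n_genes: 240
  n_target_genes_up: 30
  n_target_genes_down: 30
  n_focal_peaks: 150
  n_partner_peaks: 150
  baseline_step: 2000
classify:
  promoter_halfwidth: 1000
  min_overlap: 1
profile:
  flank: 5000
  bin_size: 50
  proximal_cutoff: 2000
beta:
  da: 60
  window: 100000
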