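# Demo run: two small fully heterozygous chromosomes, 60 F2 individuals.
# Usage: meioxo run --config examples/demo.yaml --out-dir demo_out
seed: 7
out_dir: demo_out
genome:
  chromosomes:
    - {name: chr1, length: 6000000, centromere: 3000000}
    - {name: chr2, length: 4000000, centromere: 2000000}
  snp_density:
    chr1: 6.7
    chr2: 6.7
  het_blocks:
    chr1: [[0, 6000000]]
    chr2: [[0, 4000000]]
pathway:
  classI_base_cM_per_Mb: 6.0
  classII_base_cM_per_Mb: 3.0
  classI_interference_shape: 5.0
simulator:
  n_individuals: 60
  mean_coverage: 8.0
  error_rate: 0.002
  sites_per_mb: 120
caller:
  smoothing_window: 9
  min_support: 3
landscape:
  window_bp: 300000
  density_window_bp: 100000
  group_size: 12
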