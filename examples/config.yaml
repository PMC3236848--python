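base_seed: 1
depths:
- 20000
- 60000
- 120000
filter:
  max_n_count: 2
  min_length_bp: 17
k: 31
n_replicates: 4
output_dir: seqsat_demo_run
sample: demo
simulation:
  abundance_mu: 0.0
  abundance_sigma: 1.8
  max_length_bp: 5000
  min_length_bp: 300
  n_genes: 2000
  n_injection_rate: 0.01
  n_reads: 200000
  read_length: 75
  seed: 1
  short_read_fraction: 0.01
  silent_fraction: 0.1
write_fastq: false
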