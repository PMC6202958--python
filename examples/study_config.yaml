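# A small end-to-end run: two seasons at one station, simulated from the
# default study community.  Run with:
#   rhodoscan run --config examples/study_config.yaml --outdir out/
seed: 42
divergence: 0.1
community:
  preset: study
  read_length: 150
  error_rate: 0.005
  background_fraction: 0.8
samples:
  - sample_id: CAT_october
    station: CAT
    season: October
    chl_a_ug_per_L: 0.23
    n_dna_reads: 20000
    n_rna_reads: 20000
    blue_fraction: 0.63   # true blue-PR fraction used by the simulator
  - sample_id: CAT_april
    station: CAT
    season: April
    chl_a_ug_per_L: 0.9
    n_dna_reads: 20000
    n_rna_reads: 20000
    blue_fraction: 0.30
recruit:
  k: 4
  target_fpr: 1.0e-3
  decoy_count: 20000
place:
  min_cols: 20
  min_margin: 0.01
tuning:
  chl_threshold: 0.25
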