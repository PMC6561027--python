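# Desk-scale synthetic screen configuration for `predfit simulate`.
seed: 11
genome_length: 150000
n_genes: 60
n_insertions: 600
read_depth: 200000
n_replicates: 2
conditions:          # condition name -> expansion factor d (output/input CFU)
  VCPL: 100.0
  ECPL: 100.0
landscape:           # counts of non-neutral genes in the simulated truth
  essential: 4
  defective: 4
  dead: 2
  improved: 2
pools:               # binary-sorting assays (attachment + rounding)
  depth: 100000
  replicates: 3
  mutants: 40
  controls: 5
  contamination: 0.02
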