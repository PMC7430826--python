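# Default spike-in study design: three plant read pools at 30% each plus
# three bacterial pools at 3.3% each (ratios renormalized to 100), with a
# nine-point dilution series of the target plastome spike.
background:
  - {label: plantA, proportion: 30.0}
  - {label: plantB, proportion: 30.0}
  - {label: plantC, proportion: 30.0}
  - {label: bactA, proportion: 3.3}
  - {label: bactB, proportion: 3.3}
  - {label: bactC, proportion: 3.3}
dilution_fractions: [5.0, 2.5, 1.25, 0.6, 0.3, 0.15, 0.07, 0.03, 0.01]
total_reads: 220000
replicates: 3
read_len: 125
error_rate: 0.002
k_id: 31
k_phylo: 8
detection:
  min_fraction: 0.5
  min_reads: 10
  min_unique_kmers: 100
  alpha: 1.0e-6
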