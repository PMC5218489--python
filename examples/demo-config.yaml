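# Demo pipeline configuration: co-amplified marker pair with polymerase
# errors and recombination. Run with:
#   pcr-fidelity run --config examples/demo-config.yaml --out demo-out
seed: 7

templates:
  kind: homolog-pair      # amplicon | homolog-pair | structured
  length: 1100
  marker_count: 9

simulation:
  sub_rate_per_doubling: 1.5e-4     # per base per doubling
  recomb_rate_per_doubling: 9.6e-5  # per base per doubling
  target_doublings: 10.7            # closed-form mode; use
                                    # efficiency_per_cycle for lineage mode
  n_cycles: 16
  n_reads: 5000
  read_pass_model: [15, 40]

filters:
  rates: {min_passes: 15}           # strict preset for error rates
  switching:                        # relaxed preset for switching scans
    min_passes: 3
    require_max_event_qv: false
    require_mapq: 0
    min_length_fraction: 0.0
    drop_chimeric: false

report:
  cycles: 16
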