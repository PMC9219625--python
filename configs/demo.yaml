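# Bundled demo scenario: three species, one recent horizontal transfer
# planted between the two most divergent lineages.  `tetrack run-all
# --config configs/demo.yaml` re-discovers exactly that event from
# sequence alone and writes a checksummed manifest.
out_dir: demo_out
seed: 1
n_species: 3
tree_height: 0.25
genome_length: 60000
copies_per_species: 8
copy_classes: [intact, intact, intact, intact, intact, intact, full, truncated]
copy_age_max: 0.04
ht_scenario: most_divergent
ht_time: 0.005
host_gene_length: 10000
secondary_gene_length: 3000
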