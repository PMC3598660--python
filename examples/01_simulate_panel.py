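"""Generate a synthetic reference-gene panel with known ground truth.

Builds the default benchmark: 12 candidate genes profiled in triplicate
across 25 samples in three biological subgroups, with three genes planted
as genuinely stable (biological noise SD 0.1 log2 units) and the rest
noisy or confounded with the subgroups.
"""

from refstab import simulate_cq_dataset, study_panel_config

config = study_panel_config(seed=42)
table, truth = simulate_cq_dataset(config)

print(f"observations: {len(table.observations)} "
      f"({len(config.gene_ids)} genes x {len(config.sample_ids)} samples"
      f" x {config.replicates} replicates)")
n_dropout = sum(1 for o in table.observations if o.cq is None)
print(f"non-detects (dropout at Cq > {config.dropout_cq}): {n_dropout}")
print(f"planted stable set: {sorted(truth.planted_stable_set)}")
print(f"largest sample loading shift: "
      f"{max(truth.sample_shifts.values()):+.2f} log2 units")

# The planted set is what a correct stability analysis should rank on top;
# the loading shifts are the sample-to-sample bias normalization must remove.
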