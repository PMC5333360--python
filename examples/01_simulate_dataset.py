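"""Generate a synthetic study: genome, planted binding sites, counts, truth.

The generator emulates a 2 sexes x 4 tissues x 2 treatments x 6 replicates
knockdown experiment with planted gene classes and >= 5 motif instances in
the upstream window of every true target gene.
"""

import pandas as pd

from dsxtargets import SimulationConfig, generate_genome, simulate_counts

cfg = SimulationConfig(seed=42, n_genes=400, n_chromosomes=2)
genome, genes, truth = generate_genome(cfg)
counts, design = simulate_counts(cfg, truth)

print(f"genome: {len(genome)} chromosomes, "
      f"{sum(len(s) for s in genome.values()):,} bp total")
print(f"genes: {len(genes)} ({sum(g.strand == '+' for g in genes)} on +)")
print("\nplanted gene classes (each target class carries "
      f"{cfg.planted_sites_per_target} upstream motif instances):")
print(truth.genes["gene_class"].value_counts().to_string())
print(f"\nplanted motif instances: {len(truth.plantings)}")
print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print("\nfirst design cells:")
print(design.head(3).to_string())
# The truth table is what downstream recovery is scored against: a gene is a
# true target for a sex x tissue when its class is modulated there and it
# carries >= 5 planted sites.
print(f"\ntrue male targets in brain: {len(truth.true_targets('M', 'brain'))}")
print(f"true female targets in head_horn: {len(truth.true_targets('F', 'head_horn'))}")
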