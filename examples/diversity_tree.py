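"""Neighbour-joining dendrogram of the structured diploid panel with
block-bootstrap node supports."""

import tetrasnp as t
from tetrasnp.diversity import block_bootstrap_support

cfg = t.SimulationConfig(seed=9, n_loci=1500, n_chromosomes=6,
                         chrom_length_bp=1_000_000, n_diversity_a=16,
                         n_groups_species_a=4, missing_rate=0.02)
model = t.simulate.simulate_genome_model(cfg)
pools, matrix, panel = t.simulate.simulate_progenitor_panels(model, cfg)
divA = matrix.subset_samples(
    [s for s in matrix.sample_ids if s.startswith("A_")])

res = block_bootstrap_support(divA, n_boot=100, block_snps=100,
                              seed=cfg.seed)
print("newick (supports label internal nodes):")
print(res.newick)
strong = sum(1 for v in res.supports.values() if v >= 95)
print(f"{strong} of {len(res.supports)} internal bipartitions have "
      ">=95% support - well-differentiated genetic groups resolve as "
      "strongly supported clades")
for split, sup in sorted(res.supports.items(), key=lambda kv: -kv[1])[:4]:
    groups = sorted({panel.loc[s, 'group'] for s in split})
    print(f"  support {sup:5.1f}%  {len(split)} samples from groups "
          f"{groups}")
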