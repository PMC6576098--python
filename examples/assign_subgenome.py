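"""Assign an allotetraploid's progenitor-derived subgenome to present-day
populations by haploid-downscaling IBS distances."""

import numpy as np

import tetrasnp as t
from tetrasnp.assignment import assign_subgenome

cfg = t.SimulationConfig(seed=13, n_loci=1500, n_chromosomes=6,
                         chrom_length_bp=1_000_000, n_groups_species_a=8,
                         n_diversity_a=24, missing_rate=0.0)
model = t.simulate.simulate_genome_model(cfg)
pools, matrix, panel = t.simulate.simulate_progenitor_panels(model, cfg)

true_group = "G5"
poolA = next(p for p in pools if p.group == true_group)
poolB = next(p for p in pools if p.species == "speciesB")
tet, dihaploid_id = t.simulate.simulate_allotetraploid(
    poolA, poolB, cfg.n_tetraploids, cfg.seed,
    locus_ids=matrix.locus_ids)

combined = t.GenotypeMatrix(
    np.column_stack([matrix.calls, tet.calls]), matrix.locus_ids,
    np.concatenate([matrix.sample_ids, tet.sample_ids]))
queries = [s for s in tet.sample_ids if s.startswith("T_")]
refs = {}
for s in matrix.sample_ids:
    if s.startswith("A_"):
        refs.setdefault(str(panel.loc[s, "group"]), []).append(s)

report = assign_subgenome(combined, queries, refs, n_runs=200,
                          seed=cfg.seed)
print(f"{report.n_loci} shared complete loci, {report.n_runs} haploid "
      f"draws per accession, {len(queries)} tetraploid queries")
print("\ngroup ranking (mean IBS over queries; smaller = closer):")
for _, row in report.per_group.iterrows():
    marker = "  <- true donor group" if row["group"] == true_group else ""
    print(f"  {row['rank']}. {row['group']}  {row['mean_ibs']:.4f}{marker}")
best = report.per_reference.iloc[0]
print(f"\nclosest individual: {best['reference']} (group {best['group']}, "
      f"IBS {best['mean_ibs']:.4f} +/- {best['sd_ibs']:.4f} across "
      "queries)")
print("The donor group attains the minimum mean IBS: the subgenome is "
      "assigned to the population it was actually drawn from.")
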