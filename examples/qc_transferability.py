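"""Cross-species QC accounting: call rates, the scorable/polymorphic
table and the dihaploid-based homeologous partition for the tetraploid."""

import numpy as np
import pandas as pd

import tetrasnp as t
from tetrasnp.qc import call_rate, classify_homeologous, summarize_species

cfg = t.SimulationConfig(seed=5, n_loci=2000, n_chromosomes=6,
                         chrom_length_bp=1_000_000)
model = t.simulate.simulate_genome_model(cfg)
catalog = t.simulate.simulate_loci(model, cfg)
pools, matrix, panel = t.simulate.simulate_progenitor_panels(model, cfg)
tet, dihaploid_id = t.simulate.simulate_allotetraploid(
    pools[0], pools[-1], cfg.n_tetraploids, cfg.seed,
    locus_ids=catalog.index.to_numpy())

combined = t.GenotypeMatrix(
    np.column_stack([matrix.calls, tet.calls]), catalog.index.to_numpy(),
    np.concatenate([matrix.sample_ids, tet.sample_ids]))
combined = t.simulate.inject_missingness(combined, cfg.missing_rate,
                                         cfg.seed)
tet_panel = pd.DataFrame(
    {"species": "allotetraploid",
     "role": ["dihaploid" if s == dihaploid_id else "diversity"
              for s in tet.sample_ids]},
    index=pd.Index(tet.sample_ids, name="sample_id"))
full_panel = pd.concat([panel, tet_panel])
catalog["source"] = "speciesA_derived"
catalog["genic_class"] = "coding"

rates = [call_rate(combined, s) for s in combined.sample_ids]
print(f"call rate across {combined.n_samples} samples: "
      f"{min(rates):.1f}-{max(rates):.1f}% (mean {np.mean(rates):.1f}%)")

sA = summarize_species(combined, full_panel, catalog, "speciesA")
row = sA.table.loc[("TOTAL", "TOTAL")]
print(f"species A: {int(row['scorable'])} scorable ({row['scorable_pct']}%), "
      f"{int(row['polymorphic'])} polymorphic ({row['polymorphic_pct']}%)")

sT = summarize_species(combined, full_panel, catalog, "allotetraploid",
                       dihaploid_id=dihaploid_id)
row = sT.table.loc[("TOTAL", "TOTAL")]
print(f"allotetraploid: {int(row['dihaploid_het'])} homeologous loci "
      f"({row['dihaploid_het_pct']}% of scorable; heterozygous in the "
      "dihaploid, i.e. fixed inter-subgenome differences)")
print(f"  allelic polymorphism within subgenomes: {int(row['polymorphic'])} "
      f"loci ({row['polymorphic_pct']}% of scorable) - the within-species "
      "diversity left after removing homeologs")
homeo = classify_homeologous(combined, dihaploid_id)
print("homeolog partition:",
      {k: int(v) for k, v in homeo.value_counts().items()})
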