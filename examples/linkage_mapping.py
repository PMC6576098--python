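"""Linkage statistics in an F2 progeny: segregation distortion, two-point
recombination with Kosambi distances, co-segregation bins and the map
summary."""

import numpy as np
import pandas as pd

import tetrasnp as t
from tetrasnp.linkage import (SEG_1_2_1, cluster_cosegregating,
                              distortion_scan, gap_fraction_below,
                              kosambi_cm, map_summary, two_point)
from tetrasnp.pipeline import _map_positions

cfg = t.SimulationConfig(seed=21, n_loci=1200, n_chromosomes=6,
                         chrom_length_bp=1_000_000, missing_rate=0.02)
model = t.simulate.simulate_genome_model(cfg)
catalog = t.simulate.simulate_loci(model, cfg)
pools, _, _ = t.simulate.simulate_progenitor_panels(model, cfg)
pos_cm, codes = _map_positions(catalog, model, cfg.map_length_cm)
gA = pools[0].haplotypes
progeny, _ = t.simulate.simulate_mapping_progeny(
    np.vstack([gA[0], gA[0]]), np.vstack([gA[1], gA[1]]), "F2_self",
    cfg.n_f2, pos_cm, codes, cfg.seed, locus_ids=catalog.index.to_numpy())
progeny = t.simulate.inject_missingness(progeny, cfg.missing_rate, cfg.seed)

parents = pd.DataFrame({"parent1": 2 * gA[0], "parent2": 2 * gA[1]},
                       index=catalog.index)
scan = distortion_scan(progeny, parents, "F2_self")
inf = scan[scan["seg_type"] == SEG_1_2_1]
print(f"{len(inf)} informative (founder-divergent) loci of "
      f"{len(scan)}; {100 * inf['distorted_p01'].mean():.1f}% distorted "
      "at p<0.01 (Mendelian simulation, so near the nominal 1%)")

first = inf.index[:2]
r, lod = two_point(progeny.subset_loci(np.asarray(first[:1])).calls[0],
                   progeny.subset_loci(np.asarray(first[1:2])).calls[0],
                   "F2_self")
d_true = abs(pos_cm[catalog.index.get_loc(first[0])]
             - pos_cm[catalog.index.get_loc(first[1])])
print(f"two-point between {first[0]} and {first[1]}: r = {r:.3f} "
      f"(LOD {lod:.1f}) -> {kosambi_cm(min(r, 0.499)):.1f} cM Kosambi; "
      f"simulated map distance {d_true:.1f} cM")

sub = progeny.subset_loci(np.asarray(inf.index[:40]))
bins = cluster_cosegregating(sub)
print(f"co-segregation: {sub.n_loci} markers fall on {len(bins)} unique "
      "positions (markers with zero observed recombinants merge)")

table = pd.DataFrame({
    "marker": inf.index,
    "lg": catalog.loc[inf.index, "chrom"].to_numpy(),
    "position_cm": pos_cm[[catalog.index.get_loc(m) for m in inf.index]],
    "from_array": True})
summary = map_summary(table)
print(f"map: {summary.loc['TOTAL', 'n_markers']} markers, "
      f"{summary.loc['TOTAL', 'coverage_cm']:.0f} cM total, mean "
      f"adjacent distance "
      f"{summary.loc['TOTAL', 'mean_distance_unique_cm']:.2f} cM; "
      f"{100 * gap_fraction_below(table, 2.0):.0f}% of gaps < 2 cM")
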