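"""One-config end-to-end run: simulate -> design -> qc -> ld -> tree ->
assign -> linkage.

`run_pipeline` wires the synthetic generator through every analysis stage
and writes the stage outputs (TSV/JSON/Newick/VCF) into one directory.
Everything is keyed by ``SimulationConfig.seed``, so two runs from the
same config produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment, design, diversity, io, linkage, qc, simulate
from .core import GenotypeMatrix
from .io import _NumpyEncoder

__all__ = ["run_pipeline"]


def _map_positions(catalog: pd.DataFrame, model, map_length_cm: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform bp -> cM conversion per chromosome."""
    pos_cm, codes = [], []
    chrom_code = {c: i for i, c in enumerate(model.chromosomes)}
    for chrom, pos in zip(catalog["chrom"], catalog["pos"]):
        pos_cm.append(pos / model.chrom_lengths[chrom] * map_length_cm)
        codes.append(chrom_code[chrom])
    return np.asarray(pos_cm), np.asarray(codes)


def run_pipeline(config: simulate.SimulationConfig, out_dir) -> dict:
    """Run the full synthetic study and write all stage outputs.

    Returns a summary dict (also written as ``pipeline_summary.json``)
    with the headline numbers of every stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ----- simulate ------------------------------------------------------
    model = simulate.simulate_genome_model(config)
    catalog = simulate.simulate_loci(model, config)
    pools, panel_matrix, panel = simulate.simulate_progenitor_panels(
        model, config)
    source_group = "G1"
    poolA = next(p for p in pools if p.group == source_group)
    poolB = next(p for p in pools if p.species == "speciesB")
    tetra, dihaploid_id = simulate.simulate_allotetraploid(
        poolA, poolB, config.n_tetraploids, config.seed,
        locus_ids=catalog.index.to_numpy())

    # mapping progenies: F1 from two species-A groups, F2 from selfing a
    # cross of two doubled haplotypes (one subgenome modelled as diploid)
    pos_cm, codes = _map_positions(catalog, model, config.map_length_cm)
    gA = pools[0].haplotypes
    gB2 = pools[1 % len(pools)].haplotypes
    f1_parent1 = np.vstack([gA[0], gA[1]])
    f1_parent2 = np.vstack([gB2[0], gB2[1]])
    f1_progeny, _ = simulate.simulate_mapping_progeny(
        f1_parent1, f1_parent2, "F1_pseudo_testcross", config.n_f1,
        pos_cm, codes, config.seed, locus_ids=catalog.index.to_numpy())
    f2_p1 = np.vstack([gA[2], gA[2]])
    f2_p2 = np.vstack([gA[3], gA[3]])
    f2_progeny, f2_truth = simulate.simulate_mapping_progeny(
        f2_p1, f2_p2, "F2_self", config.n_f2, pos_cm, codes,
        config.seed + 1, locus_ids=catalog.index.to_numpy())

    # assemble the combined diversity matrix: progenitor panels +
    # tetraploids + dihaploid, then inject missingness and write files
    combined = GenotypeMatrix(
        np.column_stack([panel_matrix.calls, tetra.calls]),
        catalog.index.to_numpy(),
        np.concatenate([panel_matrix.sample_ids, tetra.sample_ids]))
    tet_rows = pd.DataFrame(
        [(s, "allotetraploid",
          "dihaploid" if s == dihaploid_id else "diversity",
          "", "", False)
         for s in tetra.sample_ids],
        columns=["sample_id", "species", "role", "group", "replicate_of",
                 "admixed"]).set_index("sample_id")
    full_panel = pd.concat([panel, tet_rows])
    truth = {
        "tetraploid_source_group": source_group,
        "dihaploid_id": dihaploid_id,
        "locus_cm": {str(l): float(c)
                     for l, c in zip(catalog.index, pos_cm)},
    }
    paths = simulate.inject_missingness_and_write(
        combined, catalog, model, out, config.missing_rate, config.seed,
        panel=full_panel, truth=truth)
    catalog_read, observed = io.read_vcf(paths["vcf"])

    # ----- design --------------------------------------------------------
    sel_cfg = design.SelectionConfig(min_spacing_bp=10_000,
                                     lookahead_bp=5_000)
    genes = pd.DataFrame(model.gene_intervals,
                         columns=["chrom", "start", "end", "gene_id"])
    candidates = {g[3] for g in model.gene_intervals[::200]}
    qual_ok = design.basic_quality_filter(catalog, sel_cfg)
    annotated = design.annotate_genic(qual_ok, genes, candidates,
                                      known_chroms=set(model.chromosomes))
    speciesA_div = [s for s in observed.sample_ids if s.startswith("A_div")]
    recurrent = design.canephora_recurrence_filter(
        annotated, observed.subset_samples(speciesA_div), sel_cfg)
    manifest = design.spacing_selection(recurrent, sel_cfg)
    manifest.to_csv(out / "manifest.tsv", sep="\t")
    summary_design = design.design_summary(manifest, model.chrom_lengths)
    summary_design.to_csv(out / "design_summary.tsv", sep="\t")

    # ----- qc ------------------------------------------------------------
    cat_for_qc = catalog_read.copy()
    cat_for_qc["source"] = np.where(
        np.arange(len(cat_for_qc)) % 3 == 0, "speciesA_derived",
        "tetraploid_derived")
    cat_for_qc["genic_class"] = design.annotate_genic(
        catalog, genes, candidates)["genic_class"]
    qc_summary = qc.summarize_species(observed, full_panel, cat_for_qc,
                                      "speciesA")
    qc_tet = qc.summarize_species(observed, full_panel, cat_for_qc,
                                  "allotetraploid",
                                  dihaploid_id=dihaploid_id)
    qc_summary.table.to_csv(out / "qc_speciesA.tsv", sep="\t")
    qc_tet.table.to_csv(out / "qc_allotetraploid.tsv", sep="\t")
    call_rates = {str(s): qc.call_rate(observed, s)
                  for s in observed.sample_ids}

    # ----- ld ------------------------------------------------------------
    # LD decays with distance only where linkage generates it: use the F2
    # progeny (the diversity panel's loci are unlinked by construction)
    divA = observed.subset_samples(speciesA_div)
    f2_obs = simulate.inject_missingness(f2_progeny, config.missing_rate,
                                         config.seed + 2)
    ld_matrix = diversity.ld_filter(f2_obs, catalog)
    max_dist = config.chrom_length_bp // 4
    ld = diversity.pairwise_r2(ld_matrix, catalog, max_dist_bp=max_dist)
    ld = diversity.decay_curve(ld, bin_width_bp=max(1, max_dist // 25))
    ld.records.to_csv(out / "ld_pairs.tsv", sep="\t", index=False)
    ld.curve.to_csv(out / "ld_curve.tsv", sep="\t", index=False)

    # ----- tree ----------------------------------------------------------
    tree = diversity.block_bootstrap_support(
        divA, n_boot=100, block_snps=100, seed=config.seed)
    (out / "speciesA_nj.nwk").write_text(tree.newick + "\n")

    # ----- assign --------------------------------------------------------
    queries = [s for s in observed.sample_ids
               if s.startswith("T_")][:config.n_tetraploids]
    refs_by_group: dict[str, list[str]] = {}
    for s in speciesA_div:
        refs_by_group.setdefault(str(full_panel.loc[s, "group"]),
                                 []).append(s)
    report = assignment.assign_subgenome(
        observed, queries, refs_by_group, n_runs=200, seed=config.seed)
    report.per_reference.to_csv(out / "assignment_references.tsv",
                                sep="\t", index=False)
    report.per_group.to_csv(out / "assignment_groups.tsv", sep="\t",
                            index=False)

    # ----- linkage -------------------------------------------------------
    parent_calls = pd.DataFrame({"parent1": 2 * gA[2], "parent2": 2 * gA[3]},
                                index=catalog.index)
    distortion = linkage.distortion_scan(f2_obs, parent_calls, "F2_self")
    distortion.to_csv(out / "distortion.tsv", sep="\t")
    informative = distortion[distortion["seg_type"] == linkage.SEG_1_2_1]
    map_table = pd.DataFrame({
        "marker": informative.index,
        "lg": catalog.loc[informative.index, "chrom"].to_numpy(),
        "position_cm": [truth["locus_cm"][str(m)]
                        for m in informative.index],
        "from_array": True,
    })
    msum = linkage.map_summary(map_table)
    msum.to_csv(out / "map_summary.tsv", sep="\t")

    summary = {
        "n_loci": int(config.n_loci),
        "n_selected": int(len(manifest)),
        "genome_density_per_mb": float(
            summary_design.loc["GENOME", "density_per_mb"]),
        "mean_call_rate_pct": float(np.mean(list(call_rates.values()))),
        "speciesA_polymorphic_pct": float(
            qc_summary.table.loc[("TOTAL", "TOTAL"), "polymorphic_pct"]),
        "tetraploid_homeolog_pct": float(
            qc_tet.table.loc[("TOTAL", "TOTAL"), "dihaploid_het_pct"]),
        "ld_half_decay_bp": (float(ld.half_decay_bp)
                             if ld.half_decay_defined else None),
        "assigned_group": str(report.per_group.iloc[0]["group"]),
        "true_source_group": source_group,
        "f2_distorted_pct_p01": float(
            100 * informative["distorted_p01"].mean())
        if len(informative) else None,
        "map_total_coverage_cm": float(msum.loc["TOTAL", "coverage_cm"]),
    }
    with open(out / "pipeline_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, cls=_NumpyEncoder)
    return summary
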