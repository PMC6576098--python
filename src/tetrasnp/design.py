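"""The SNP-array selection workflow, from raw variant calls to a manifest.

Stages, in the order the array was designed:

1. basic quality — biallelic SNPs only, QUAL strictly above the threshold,
   and no other variant call within the probe flank (default 60 bp) on
   either side.
2. tetraploid allelic filter — drop loci heterozygous or missing in the
   dihaploid (those mark inter-subgenome divergence, not allelic
   variation) and require at least two accessions homozygous for
   different alleles.
3. diploid recurrence filter — the minor allele must be carried by at
   least ``min_recurrence`` distinct genotypes, screening out
   individual-specific alleles.
4. genic annotation — coding/non-coding by gene-interval membership
   (1-based inclusive), candidate-gene tagging.
5. spacing selection — greedy left-to-right pick honouring a minimum
   inter-SNP distance (default 40 kb), with candidate-gene loci exempt
   and an alternating genic/non-genic preference to approach parity.

Every stage takes and returns a catalog DataFrame, so stages compose and
are idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import MISSING, GenotypeMatrix, validate_catalog

__all__ = [
    "SelectionConfig", "basic_quality_filter", "arabica_subgenome_filter",
    "canephora_recurrence_filter", "annotate_genic", "spacing_selection",
    "design_summary",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds of the selection workflow (all comparisons strict where
    noted in the stage docstrings)."""

    qual_min: float = 40.0
    flank_bp: int = 60
    min_spacing_bp: int = 40_000
    min_recurrence: int = 2
    lookahead_bp: int = 10_000  # window for the genic-parity preference

    def __post_init__(self) -> None:
        if self.qual_min < 0 or self.flank_bp < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_spacing_bp <= 0 or self.min_recurrence < 1:
            raise ValueError("spacing and recurrence must be positive")


def _require_sorted(catalog: pd.DataFrame) -> None:
    for _, grp in catalog.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("catalog must be position-sorted per chromosome")


def basic_quality_filter(catalog: pd.DataFrame,
                         config: SelectionConfig = SelectionConfig()
                         ) -> pd.DataFrame:
    """Biallelic-SNP + QUAL + flanking filter.

    A locus survives when its REF and ALT are both single bases (one ALT
    allele), QUAL > ``qual_min`` strictly, and no *other input record* lies
    within ``flank_bp`` of it on the same chromosome — the probe flank must
    be free of variation. The flank test uses all input records, including
    ones that themselves fail the other criteria.
    """
    validate_catalog(catalog)
    _require_sorted(catalog)
    is_snp = (catalog["ref"].str.len() == 1) & \
             (catalog["alt"].str.len() == 1) & \
             (~catalog["alt"].str.contains(",", regex=False)) & \
             (catalog["alt"] != "*")
    qual_ok = catalog["qual"].astype(float) > config.qual_min
    flank_ok = pd.Series(True, index=catalog.index)
    for _, grp in catalog.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        near_prev = np.zeros(len(pos), dtype=bool)
        near_next = np.zeros(len(pos), dtype=bool)
        if len(pos) > 1:
            gaps = np.diff(pos)
            near_prev[1:] = gaps <= config.flank_bp
            near_next[:-1] = gaps <= config.flank_bp
        flank_ok.loc[grp.index] = ~(near_prev | near_next)
    return catalog.loc[is_snp & qual_ok & flank_ok].copy()


def arabica_subgenome_filter(catalog: pd.DataFrame, matrix: GenotypeMatrix,
                             dihaploid_id: str,
                             accession_ids: list[str]) -> pd.DataFrame:
    """Within-subgenome allelic filter for the tetraploid discovery set.

    Keeps loci where (i) the dihaploid call is homozygous — a heterozygous
    or missing dihaploid call marks polymorphism *between* the subgenomes —
    and (ii) at least two accessions are homozygous for different alleles,
    i.e. at least one hom-ref and one hom-alt among ``accession_ids``.
    """
    validate_catalog(catalog)
    dh = matrix.sample_calls(dihaploid_id)  # KeyError if absent
    acc = matrix.subset_samples(accession_ids).calls
    dh_hom = (dh == 0) | (dh == 2)
    hom_ref = (acc == 0).sum(axis=1)
    hom_alt = (acc == 2).sum(axis=1)
    keep_mask = dh_hom & (hom_ref >= 1) & (hom_alt >= 1)
    keep = pd.Series(keep_mask, index=matrix.locus_ids)
    in_cat = catalog.index[keep.reindex(catalog.index, fill_value=False)]
    return catalog.loc[in_cat].copy()


def canephora_recurrence_filter(catalog: pd.DataFrame,
                                matrix: GenotypeMatrix,
                                config: SelectionConfig = SelectionConfig()
                                ) -> pd.DataFrame:
    """Keep loci whose minor allele is carried by at least
    ``min_recurrence`` distinct genotypes (a carrier counts once whether
    het or hom), screening out rare individual-specific alleles."""
    validate_catalog(catalog)
    if matrix.n_samples == 0:
        raise ValueError("empty discovery panel")
    if matrix.n_samples < config.min_recurrence:
        raise ValueError("panel smaller than min_recurrence")
    calls = matrix.calls
    called = calls != MISSING
    alt_dose = np.where(called, calls, 0).sum(axis=1)
    total_dose = 2 * called.sum(axis=1)
    # minor allele: alt if alt dosage <= half of total; ties go to alt
    alt_minor = alt_dose * 2 <= total_dose
    carriers_alt = ((calls == 1) | (calls == 2)).sum(axis=1)
    carriers_ref = ((calls == 1) | (calls == 0)).sum(axis=1)
    carriers = np.where(alt_minor, carriers_alt, carriers_ref)
    keep = pd.Series(carriers >= config.min_recurrence,
                     index=matrix.locus_ids)
    in_cat = catalog.index[keep.reindex(catalog.index, fill_value=False)]
    return catalog.loc[in_cat].copy()


def annotate_genic(catalog: pd.DataFrame, genes: pd.DataFrame,
                   candidate_gene_ids: set[str] | None = None,
                   known_chroms: set[str] | None = None) -> pd.DataFrame:
    """Label each locus coding/non-coding by 1-based inclusive gene
    intervals, and tag loci falling in candidate genes.

    ``genes`` needs columns chrom/start/end/gene_id (as from
    :func:`tetrasnp.io.read_gff3`). When ``known_chroms`` is given, a gene
    on an unknown chromosome raises.
    """
    validate_catalog(catalog)
    if known_chroms is not None:
        unknown = set(genes["chrom"]) - set(known_chroms)
        if unknown:
            raise ValueError(f"GFF chromosomes not in the genome model: "
                             f"{sorted(unknown)}")
    candidate_gene_ids = candidate_gene_ids or set()
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in genes.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            # interval ends are exclusive in the tree; +1 keeps 1-based
            # inclusive GFF semantics
            (int(s), int(e) + 1, gid)
            for s, e, gid in zip(grp["start"], grp["end"], grp["gene_id"]))
    out = catalog.copy()
    genic_class, candidate = [], []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        hits = trees[chrom][int(pos)] if chrom in trees else set()
        if hits:
            genic_class.append("coding")
            cand = sorted(iv.data for iv in hits
                          if iv.data in candidate_gene_ids)
            candidate.append(cand[0] if cand else "")
        else:
            genic_class.append("non-coding")
            candidate.append("")
    out["genic_class"] = genic_class
    out["candidate_gene_id"] = candidate
    return out


def spacing_selection(catalog: pd.DataFrame,
                      config: SelectionConfig = SelectionConfig()
                      ) -> pd.DataFrame:
    """Greedy minimum-spacing pick producing the array manifest.

    Walks each chromosome left to right. Candidate-gene loci are always
    selected and exempt from spacing (they were force-included on the
    array). A non-candidate locus is eligible when it lies at least
    ``min_spacing_bp`` beyond the previously retained non-candidate locus;
    among eligible loci within ``lookahead_bp`` the first one matching the
    currently preferred genic class is taken (the preference alternates
    after every pick, approximating genic/intergenic parity). Ties break
    toward the lower coordinate, so the result is deterministic.
    """
    validate_catalog(catalog)
    _require_sorted(catalog)
    if catalog.empty:
        out = catalog.copy()
        out["selection_class"] = pd.Series(dtype=object)
        return out
    has_genic = "genic_class" in catalog.columns and \
        catalog["genic_class"].isin(["coding", "non-coding"]).all()
    selected: list = []
    selection_class: list[str] = []
    want = "coding"
    for _, grp in catalog.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        cand = (grp["candidate_gene_id"].fillna("") != "").to_numpy() \
            if "candidate_gene_id" in grp.columns \
            else np.zeros(len(grp), dtype=bool)
        genic = grp["genic_class"].to_numpy() if has_genic else None
        idx = grp.index.to_numpy()
        last = -np.inf
        i = 0
        while i < len(pos):
            if cand[i]:
                selected.append(idx[i])
                selection_class.append("candidate")
                i += 1
                continue
            if pos[i] - last < config.min_spacing_bp:
                i += 1
                continue
            pick = i
            if genic is not None and genic[i] != want:
                j = i + 1
                while j < len(pos) and pos[j] - pos[i] <= config.lookahead_bp:
                    if not cand[j] and genic[j] == want:
                        pick = j
                        break
                    j += 1
            # candidates skipped over are still force-included
            for k in range(i, pick):
                if cand[k]:
                    selected.append(idx[k])
                    selection_class.append("candidate")
            selected.append(idx[pick])
            selection_class.append("spaced")
            if genic is not None:
                want = "non-coding" if genic[pick] == "coding" else "coding"
            last = pos[pick]
            i = pick + 1
    manifest = catalog.loc[selected].copy()
    manifest["selection_class"] = selection_class
    return manifest


def design_summary(manifest: pd.DataFrame,
                   chrom_lengths: dict[str, int],
                   unanchored: str = "chr0") -> pd.DataFrame:
    """Per-chromosome marker count, density (SNPs/Mb) and mean adjacent
    inter-marker distance; the GENOME row excludes the unanchored
    pseudo-chromosome from its means."""
    if manifest.empty:
        raise ValueError("empty manifest")
    rows = []
    for chrom, grp in manifest.groupby("chrom", sort=False):
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        length = chrom_lengths[chrom]
        gaps = np.diff(pos)
        rows.append({
            "chrom": chrom,
            "n_markers": len(pos),
            "length_mb": length / 1e6,
            "density_per_mb": len(pos) / (length / 1e6),
            "mean_distance_bp": float(gaps.mean()) if gaps.size else np.nan,
        })
    out = pd.DataFrame(rows).set_index("chrom")
    anchored = out.index != unanchored
    sub = out.loc[anchored]
    genome_len = sub["length_mb"].sum()
    all_gaps = []
    for chrom in sub.index:
        pos = np.sort(manifest.loc[manifest["chrom"] == chrom,
                                   "pos"].to_numpy(dtype=np.int64))
        all_gaps.extend(np.diff(pos))
    out.loc["GENOME"] = {
        "n_markers": int(sub["n_markers"].sum()),
        "length_mb": genome_len,
        "density_per_mb": sub["n_markers"].sum() / genome_len,
        "mean_distance_bp": float(np.mean(all_gaps)) if all_gaps else np.nan,
    }
    return out
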