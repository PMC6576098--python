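"""Genotyping quality control and the cross-species transferability table.

Implements the array-evaluation accounting: call-score thresholds
(GenTrain-like per-locus and GenCall-like per-call scores), per-sample
call rates, per-panel scorable/polymorphic classification, the
dihaploid-based homeologous/allelic partition for the allotetraploid, the
species summary table (counts and percentages per SNP source x genic
class) and replicate concordance.

Percentages are rounded half-up to one decimal, matching how such tables
are printed; every percentage in a summary recomputes exactly from its
count pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (MISSING, GenotypeMatrix, percentage, samples_of,
                   validate_panel)

__all__ = [
    "apply_call_thresholds", "call_rate", "classify_panel_loci",
    "classify_homeologous", "summarize_species", "SpeciesSummary",
    "replicate_concordance",
]

HOMEOLOGOUS = "homeologous"
ALLELIC_CANDIDATE = "allelic_candidate"
UNUSABLE = "unusable"


def apply_call_thresholds(matrix: GenotypeMatrix,
                          locus_scores: pd.Series,
                          call_scores: pd.DataFrame,
                          gentrain_min: float = 0.6,
                          gencall_min: float = 0.2) -> GenotypeMatrix:
    """Set calls to missing when either quality score is below threshold.

    ``locus_scores`` is a per-locus (GenTrain-like) series; ``call_scores``
    a loci x samples (GenCall-like) frame. A call fails when its locus
    score < ``gentrain_min`` or its call score < ``gencall_min``; passing
    calls are untouched.
    """
    if not np.array_equal(locus_scores.index.to_numpy(), matrix.locus_ids):
        raise ValueError("locus_scores not aligned with the matrix loci")
    if (not np.array_equal(call_scores.index.to_numpy(), matrix.locus_ids)
            or not np.array_equal(call_scores.columns.to_numpy(),
                                  matrix.sample_ids)):
        raise ValueError("call_scores not aligned with the matrix")
    calls = matrix.calls.copy()
    bad = (locus_scores.to_numpy(dtype=float)[:, None] < gentrain_min) | \
          (call_scores.to_numpy(dtype=float) < gencall_min)
    calls[bad] = MISSING
    return GenotypeMatrix(calls, matrix.locus_ids.copy(),
                          matrix.sample_ids.copy())


def call_rate(matrix: GenotypeMatrix, sample_id: str) -> float:
    """Percentage of scorable (non-missing) loci for one sample, to one
    decimal, half-up."""
    calls = matrix.sample_calls(sample_id)
    return percentage(int((calls != MISSING).sum()), calls.size)


def classify_panel_loci(matrix: GenotypeMatrix, panel: pd.DataFrame,
                        species: str,
                        scorable_min_fraction: float = 0.75) -> pd.DataFrame:
    """Per-locus scorable/polymorphic flags within one species panel.

    A locus is *scorable* when its non-missing fraction across the
    species' samples is at least ``scorable_min_fraction``; a scorable
    locus is *polymorphic* when at least two dosage states occur among its
    called samples. Non-scorable loci are never polymorphic.
    """
    validate_panel(panel)
    samples = samples_of(panel, species=species)
    if not samples:
        raise ValueError(f"no samples of species {species!r}")
    sub = matrix.subset_samples(samples)
    called = sub.calls != MISSING
    scorable = called.mean(axis=1) >= scorable_min_fraction
    n_states = np.zeros(sub.n_loci, dtype=int)
    for state in (0, 1, 2):
        n_states += ((sub.calls == state) & called).any(axis=1)
    polymorphic = scorable & (n_states >= 2)
    return pd.DataFrame({"scorable": scorable, "polymorphic": polymorphic},
                        index=matrix.locus_ids)


def classify_homeologous(matrix: GenotypeMatrix,
                         dihaploid_id: str) -> pd.Series:
    """Partition loci by the dihaploid's call.

    The dihaploid carries one haplotype per subgenome, so a heterozygous
    call marks a fixed inter-subgenome difference (*homeologous*); a
    homozygous call leaves the locus as an *allelic candidate*; a missing
    call makes it *unusable* and it drops out of the allelic denominator.
    """
    dh = matrix.sample_calls(dihaploid_id)
    out = np.where(dh == 1, HOMEOLOGOUS,
                   np.where(dh == MISSING, UNUSABLE, ALLELIC_CANDIDATE))
    return pd.Series(out, index=matrix.locus_ids, name="homeolog_class")


@dataclass
class SpeciesSummary:
    """Transferability accounting for one species panel.

    ``table`` is indexed by (source, genic_class) with the TOTAL rows
    included; counts are integers, percentages are printed-style floats
    (scorable% over synthesized, polymorphic% over scorable).
    """

    species: str
    table: pd.DataFrame
    scorable_min_fraction: float
    dihaploid_id: str | None = None

    def audit(self) -> None:
        """Re-derive every percentage from its count pair; raises on any
        mismatch (self-consistency check for reports)."""
        for _, row in self.table.iterrows():
            if row["synthesized"] and not pd.isna(row["scorable_pct"]):
                assert row["scorable_pct"] == percentage(
                    int(row["scorable"]), int(row["synthesized"]))
            if row["scorable"] and not pd.isna(row["polymorphic_pct"]):
                assert row["polymorphic_pct"] == percentage(
                    int(row["polymorphic"]), int(row["scorable"]))
            if self.dihaploid_id and row["scorable"] \
                    and not pd.isna(row.get("dihaploid_het_pct", np.nan)):
                assert row["dihaploid_het_pct"] == percentage(
                    int(row["dihaploid_het"]), int(row["scorable"]))


def summarize_species(matrix: GenotypeMatrix, panel: pd.DataFrame,
                      catalog: pd.DataFrame, species: str,
                      dihaploid_id: str | None = None,
                      scorable_min_fraction: float = 0.75) -> SpeciesSummary:
    """Species block of the transferability table.

    Rows are SNP source x genic class plus per-source and grand TOTALs.
    Scorable% uses the synthesized count as denominator and polymorphic%
    the scorable count. For the allotetraploid (``dihaploid_id`` given)
    the dihaploid-heterozygous (homeologous) count is reported against the
    scorable denominator, and polymorphism is counted only over allelic
    candidate loci — heterozygosity shared by every individual is
    subgenome divergence, not diversity.
    """
    flags = classify_panel_loci(matrix, panel, species,
                                scorable_min_fraction)
    if dihaploid_id is not None:
        homeo = classify_homeologous(matrix, dihaploid_id)
        is_homeo = (homeo == HOMEOLOGOUS).to_numpy()
        is_allelic = (homeo == ALLELIC_CANDIDATE).to_numpy()
    cat = catalog.loc[matrix.locus_ids]
    scorable = flags["scorable"].to_numpy()
    polymorphic = flags["polymorphic"].to_numpy()
    if dihaploid_id is not None:
        polymorphic = polymorphic & is_allelic

    def _row(mask: np.ndarray) -> dict:
        n_syn = int(mask.sum())
        n_sco = int((mask & scorable).sum())
        n_pol = int((mask & polymorphic).sum())
        row = {
            "synthesized": n_syn,
            "scorable": n_sco,
            "scorable_pct": percentage(n_sco, n_syn) if n_syn else np.nan,
            "polymorphic": n_pol,
            "polymorphic_pct": (percentage(n_pol, n_sco)
                                if n_sco else np.nan),
        }
        if dihaploid_id is not None:
            n_het = int((mask & scorable & is_homeo).sum())
            row["dihaploid_het"] = n_het
            row["dihaploid_het_pct"] = (percentage(n_het, n_sco)
                                        if n_sco else np.nan)
        return row

    sources = list(dict.fromkeys(cat["source"]))
    classes = ["coding", "non-coding"]
    rows, index = [], []
    for source in sources:
        src_mask = (cat["source"] == source).to_numpy()
        rows.append(_row(src_mask))
        index.append((source, "TOTAL"))
        for gc in classes:
            rows.append(_row(src_mask &
                             (cat["genic_class"] == gc).to_numpy()))
            index.append((source, gc))
    all_mask = np.ones(len(cat), dtype=bool)
    rows.append(_row(all_mask))
    index.append(("TOTAL", "TOTAL"))
    for gc in classes:
        rows.append(_row((cat["genic_class"] == gc).to_numpy()))
        index.append(("TOTAL", gc))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["source", "genic_class"]))
    summary = SpeciesSummary(species, table, scorable_min_fraction,
                             dihaploid_id)
    summary.audit()
    return summary


def replicate_concordance(matrix: GenotypeMatrix,
                          panel: pd.DataFrame) -> pd.DataFrame:
    """Concordance between each declared replicate pair.

    For samples with a non-empty ``replicate_of``: percentage of identical
    calls over the loci called in both members of the pair. Returns an
    empty frame when no pairs are declared.
    """
    validate_panel(panel, matrix)
    rows = []
    if "replicate_of" in panel.columns:
        pairs = panel[(panel["replicate_of"].notna())
                      & (panel["replicate_of"] != "")]
        for rep_id, row in pairs.iterrows():
            a = matrix.sample_calls(str(rep_id))
            b = matrix.sample_calls(str(row["replicate_of"]))
            joint = (a != MISSING) & (b != MISSING)
            n = int(joint.sum())
            conc = percentage(int((a[joint] == b[joint]).sum()), n) \
                if n else np.nan
            rows.append((rep_id, row["replicate_of"], n, conc))
    return pd.DataFrame(rows, columns=["replicate", "original",
                                       "n_joint_called", "concordance_pct"])
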