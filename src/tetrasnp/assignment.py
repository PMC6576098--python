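"""Haploid-downscaling IBS assignment of allotetraploid subgenomes.

The allotetraploid's collapsed genotype calls confound allelic and
homeologous heterozygosity, so a direct diploid distance to candidate
progenitor individuals is biased. The mitigation implemented here is
*haploid downscaling*: at every heterozygous call one allele is drawn at
random (Bernoulli 1/2), producing a haploid genotype; identity-by-state
(IBS) distances — the fraction of loci with differing alleles — are
computed between each query (tetraploid) and each reference (progenitor
individual) haplotype, and the draw/measure cycle is repeated over many
runs and averaged. Reference individuals flagged as admixed are excluded.
The report ranks reference individuals and their genetic groups by the
mean IBS over queries, with the standard deviation across queries.

The random stream is keyed by (seed, run, sample id), so adding samples to
an analysis does not perturb the draws of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "AssignmentReport", "shared_complete_loci", "draw_haploid",
    "ibs_distance", "assign_subgenome",
]


@dataclass
class AssignmentReport:
    """Ranked IBS assignment of a query set against grouped references."""

    per_pair: pd.DataFrame       # index (query, reference); mean_ibs
    per_reference: pd.DataFrame  # reference, group, mean, sd, rank
    per_group: pd.DataFrame      # group, mean, rank
    n_runs: int
    n_loci: int


def shared_complete_loci(matrix: GenotypeMatrix, query_ids: list[str],
                         reference_ids: list[str]) -> np.ndarray:
    """Locus ids called in every query and every reference sample."""
    if not query_ids or not reference_ids:
        raise ValueError("query and reference sets must be non-empty")
    sub = matrix.subset_samples(list(query_ids) + list(reference_ids))
    complete = (sub.calls != MISSING).all(axis=1)
    if not complete.any():
        raise ValueError("no shared loci without missing data")
    return matrix.locus_ids[complete]


def _sample_rng(seed: int, run: int, sample_id: str) -> np.random.Generator:
    key = zlib.crc32(str(sample_id).encode())
    return np.random.default_rng(np.random.SeedSequence(
        seed, spawn_key=(11, run, key)))


def draw_haploid(genotypes: np.ndarray, seed: int, run: int,
                 sample_id: str = "") -> np.ndarray:
    """One haploid draw from a dosage vector without missing values.

    Homozygous calls are deterministic (0 -> allele 0, 2 -> allele 1);
    heterozygous calls are fair Bernoulli draws. Reproducible given
    (seed, run, sample_id).
    """
    g = np.asarray(genotypes)
    if np.any(g == MISSING):
        raise ValueError("haploid draw requires complete genotypes")
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("dosages must be 0/1/2")
    rng = _sample_rng(seed, run, sample_id)
    hap = (g == 2).astype(np.int8)
    het = g == 1
    hap[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return hap


def ibs_distance(haploid_a: np.ndarray, haploid_b: np.ndarray) -> float:
    """Fraction of loci at which two haploid genotypes differ."""
    a = np.asarray(haploid_a)
    b = np.asarray(haploid_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("haploids must be non-empty and equal-length")
    return float((a != b).mean())


def assign_subgenome(matrix: GenotypeMatrix, query_ids: list[str],
                     references_by_group: dict[str, list[str]],
                     exclude_admixed: set[str] | None = None,
                     n_runs: int = 200, seed: int = 0,
                     downscale_references: bool = True) -> AssignmentReport:
    """Rank candidate progenitor individuals and groups by haploid IBS.

    For each run, haploid genotypes are drawn for every query and (by
    default) every reference; IBS is computed per (query, reference) over
    the shared complete loci and averaged over runs, then summarized as
    mean +/- SD across queries per reference. References listed in
    ``exclude_admixed`` are dropped before any computation. Groups are
    ranked by the unweighted mean of their members' means. Lower mean IBS
    = closer relative.

    ``downscale_references=False`` keeps reference heterozygotes drawn
    once per run disabled — references must then be fully homozygous.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    exclude_admixed = exclude_admixed or set()
    groups = {g: [r for r in refs if r not in exclude_admixed]
              for g, refs in references_by_group.items()}
    groups = {g: refs for g, refs in groups.items() if refs}
    ref_ids = [r for refs in groups.values() for r in refs]
    if not ref_ids:
        raise ValueError("no references left after admixture exclusion")
    loci = shared_complete_loci(matrix, list(query_ids), ref_ids)
    sub = matrix.subset_loci(loci)
    q = sub.subset_samples(list(query_ids)).calls
    r = sub.subset_samples(ref_ids).calls
    if not downscale_references and np.any(r == 1):
        raise ValueError("references are heterozygous; enable "
                         "downscale_references")

    n_loci = len(loci)
    acc = np.zeros((len(query_ids), len(ref_ids)))
    for run in range(n_runs):
        hq = np.column_stack([
            draw_haploid(q[:, i], seed, run, s)
            for i, s in enumerate(query_ids)]).astype(np.int8)
        if downscale_references:
            hr = np.column_stack([
                draw_haploid(r[:, j], seed, run, s)
                for j, s in enumerate(ref_ids)]).astype(np.int8)
        else:
            hr = (r == 2).astype(np.int8)
        # mismatch counts via two rank-1 products
        mism = hq.T.astype(np.int32) @ (1 - hr).astype(np.int32) + \
            (1 - hq).T.astype(np.int32) @ hr.astype(np.int32)
        acc += mism / n_loci
    mean_ibs = acc / n_runs

    per_pair = pd.DataFrame(mean_ibs, index=pd.Index(query_ids, name="query"),
                            columns=ref_ids).stack()
    per_pair = per_pair.rename("mean_ibs").to_frame()
    per_pair.index.names = ["query", "reference"]

    group_of = {ref: g for g, refs in groups.items() for ref in refs}
    ref_mean = mean_ibs.mean(axis=0)
    ref_sd = mean_ibs.std(axis=0, ddof=1) if len(query_ids) > 1 \
        else np.zeros(len(ref_ids))
    per_reference = pd.DataFrame({
        "reference": ref_ids,
        "group": [group_of[ref] for ref in ref_ids],
        "mean_ibs": ref_mean,
        "sd_ibs": ref_sd,
    }).sort_values(["mean_ibs", "reference"]).reset_index(drop=True)
    per_reference["rank"] = np.arange(1, len(per_reference) + 1)

    per_group = (per_reference.groupby("group")["mean_ibs"].mean()
                 .sort_values().rename("mean_ibs").reset_index())
    per_group["rank"] = np.arange(1, len(per_group) + 1)

    return AssignmentReport(per_pair, per_reference, per_group,
                            n_runs, n_loci)
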