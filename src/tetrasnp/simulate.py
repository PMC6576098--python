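"""Synthetic genomes, panels and progenies for the array pipeline.

The generator emulates the study system end to end so every downstream
stage is testable without any sequence download:

* species A — a structured, outcrossing diploid with several
  well-differentiated genetic groups (a Robusta-like species). Group
  allele frequencies follow a hierarchical Balding–Nichols model: an
  ancestral frequency per locus, group frequencies Beta-distributed
  around it with dispersion set by an Fst-like parameter.
* species B — a second diploid with much lower diversity (an
  eugenioides-like species): most loci are fixed, a small configurable
  fraction segregates.
* an allotetraploid formed from one haplotype pool of each species. Its
  genotype calls are collapsed to diploid-style dosages {0, het, 1}, as a
  cluster-calling array platform reports them, so loci divergently fixed
  between the two pools show *fixed heterozygosity* in every individual.
* a dihaploid carrying exactly one haplotype per subgenome — heterozygous
  precisely where its two subgenome haplotypes differ, which is what makes
  it the homeolog detector downstream.
* F1 pseudo-testcross and selfed-F2 mapping progenies with crossovers
  placed without interference on the centimorgan scale, converted through
  the inverse Kosambi function.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence`` children, so one config yields byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .linkage import kosambi_inverse_r

__all__ = [
    "GenomeModel", "SimulationConfig", "HaplotypePool",
    "simulate_genome_model", "simulate_loci", "simulate_progenitor_panels",
    "simulate_allotetraploid", "simulate_mapping_progeny",
    "inject_missingness_and_write",
]

#: Spacing of one gene "slot" along a chromosome; a gene occupies
#: ``genic_fraction`` of its slot, so the genic fraction is exact.
_GENE_SLOT_BP = 10_000


@dataclass(frozen=True)
class GenomeModel:
    """Reference-genome skeleton: chromosome sizes plus gene intervals
    (1-based inclusive, GFF convention)."""

    n_chromosomes: int
    chrom_lengths: dict[str, int]
    gene_intervals: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        ids = [g[3] for g in self.gene_intervals]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        for chrom, start, end, _ in self.gene_intervals:
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValueError(f"gene interval out of bounds on {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def genic_fraction(self) -> float:
        genic = sum(e - s + 1 for _, s, e, _ in self.gene_intervals)
        return genic / self.total_bp


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the array study's panels: 8 genetic groups in the
    structured diploid, a 27-accession diversity panel for it, 6 accessions
    of the low-diversity diploid, 16 allotetraploids plus one dihaploid,
    and mapping progenies of 93 (F1 pseudo-testcross) and 138 (selfed F2)
    individuals. Chromosome count follows the reference genome's 11
    pseudo-chromosomes; physical lengths are scaled down so a full run
    stays interactive.
    """

    seed: int = 0
    n_chromosomes: int = 11
    chrom_length_bp: int = 2_000_000
    genic_fraction: float = 0.4
    n_loci: int = 3000
    n_groups_species_a: int = 8
    fst_species_a: float = 0.2
    diversity_species_b: float = 0.05
    n_diversity_a: int = 27
    n_discovery_a: int = 12
    n_species_b: int = 6
    n_tetraploids: int = 16
    missing_rate: float = 0.08
    map_length_cm: float = 125.0
    n_f1: int = 93
    n_f2: int = 138
    pool_haplotypes: int = 40

    def __post_init__(self) -> None:
        for name in ("genic_fraction", "fst_species_a",
                     "diversity_species_b", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if not (0.0 < self.fst_species_a < 1.0):
            raise ValueError("fst_species_a must lie strictly in (0,1)")
        for name in ("n_chromosomes", "chrom_length_bp", "n_loci",
                     "n_groups_species_a", "n_diversity_a", "n_species_b",
                     "n_tetraploids", "n_f1", "n_f2", "pool_haplotypes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.map_length_cm <= 0:
            raise ValueError("map_length_cm must be positive")

    def rng(self, *key: int) -> np.random.Generator:
        """Child generator keyed by integers; stable under config reuse."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(key)))


@dataclass
class HaplotypePool:
    """Binary haplotypes (rows) over the shared locus list, for one
    genetic group of one species."""

    species: str
    group: str
    haplotypes: np.ndarray  # (n_haplotypes, n_loci), values in {0,1}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.size == 0:
            raise ValueError("haplotype pool must be non-empty 2-D")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1")

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]


# ---------------------------------------------------------------------------
# genome & loci


def simulate_genome_model(config: SimulationConfig) -> GenomeModel:
    """Build chromosome lengths and non-overlapping gene intervals.

    Genes are laid out one per 10 kb slot, each occupying a
    ``genic_fraction`` share of its slot at a random offset, so the
    realized genic fraction equals the configured one and intervals never
    overlap.
    """
    rng = config.rng(0)
    lengths = {f"chr{i + 1}": config.chrom_length_bp
               for i in range(config.n_chromosomes)}
    genes: list[tuple[str, int, int, str]] = []
    if config.genic_fraction > 0:
        for chrom, length in lengths.items():
            n_slots = length // _GENE_SLOT_BP
            gene_len = max(1, int(round(_GENE_SLOT_BP * config.genic_fraction)))
            offsets = rng.integers(0, _GENE_SLOT_BP - gene_len + 1,
                                   size=n_slots)
            for k in range(n_slots):
                start = k * _GENE_SLOT_BP + int(offsets[k]) + 1
                end = start + gene_len - 1
                genes.append((chrom, start, end, f"{chrom}_g{k + 1:05d}"))
    return GenomeModel(config.n_chromosomes, lengths, genes)


def simulate_loci(model: GenomeModel, config: SimulationConfig
                  ) -> pd.DataFrame:
    """Place ``n_loci`` biallelic SNP positions uniformly over the genome.

    Returns a variant catalog indexed by locus id, position-sorted, with
    random ref/alt bases and a QUAL score drawn uniformly on [20, 100) so
    that the quality filter downstream has something to reject.
    """
    rng = config.rng(1)
    chroms = model.chromosomes
    lengths = np.array([model.chrom_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(config.n_loci, lengths / lengths.sum())
    rows = []
    bases = np.array(list("ACGT"))
    for chrom, n in zip(chroms, counts):
        if n == 0:
            continue
        pos = np.sort(rng.choice(model.chrom_lengths[chrom], size=n,
                                 replace=False)) + 1
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append((chrom, int(p), bases[ref], bases[alt],
                         float(np.round(rng.uniform(20, 100), 1))))
    cat = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    cat.index = pd.Index(
        [f"snp_{c}_{p}" for c, p in zip(cat["chrom"], cat["pos"])],
        name="locus_id")
    cat["source"] = ""
    cat["genic_class"] = ""
    cat["candidate_gene_id"] = ""
    return cat


# ---------------------------------------------------------------------------
# progenitor panels


def _group_frequencies(p_anc: np.ndarray, fst: float,
                       n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw: group frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    scale = (1.0 - fst) / fst
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale,
                    size=(n_groups, p_anc.size))


def _diploids_from_freq(freq: np.ndarray, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """n diploid dosage columns from per-locus allele frequencies."""
    return (rng.random((freq.size, n)) < freq[:, None]).astype(np.int8) + \
           (rng.random((freq.size, n)) < freq[:, None]).astype(np.int8)


def simulate_progenitor_panels(model: GenomeModel, config: SimulationConfig
                               ) -> tuple[list[HaplotypePool],
                                          GenotypeMatrix, pd.DataFrame]:
    """Diversity panels for both progenitor species.

    Species A individuals are assigned round-robin to the
    ``n_groups_species_a`` groups; each group also receives a pool of
    ``pool_haplotypes`` haplotypes (used later to found allotetraploids).
    Species B is a single low-diversity pool. Returns ``(pools, matrix,
    panel)`` where ``panel`` maps every sample to species/group/role.
    """
    if config.n_groups_species_a < 1:
        raise ValueError("need at least one species-A group")
    rng = config.rng(2)
    n_loci = config.n_loci
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    group_freq = _group_frequencies(p_anc, config.fst_species_a,
                                    config.n_groups_species_a, rng)

    # species B: mostly fixed, divergent from A at about half the fixed loci
    segregating = rng.random(n_loci) < config.diversity_species_b
    fixed_allele = (rng.random(n_loci) < 0.5).astype(float)
    freq_b = np.where(segregating, rng.uniform(0.2, 0.8, size=n_loci),
                      fixed_allele)

    pools = [HaplotypePool(
        "speciesA", f"G{g + 1}",
        (rng.random((config.pool_haplotypes, n_loci))
         < group_freq[g][None, :]).astype(np.int8))
        for g in range(config.n_groups_species_a)]
    pools.append(HaplotypePool(
        "speciesB", "B",
        (rng.random((config.pool_haplotypes, n_loci))
         < freq_b[None, :]).astype(np.int8)))

    columns, sample_ids, panel_rows = [], [], []
    for i in range(config.n_diversity_a):
        g = i % config.n_groups_species_a
        columns.append(_diploids_from_freq(group_freq[g], 1, rng)[:, 0])
        sid = f"A_div{i + 1:02d}"
        sample_ids.append(sid)
        panel_rows.append((sid, "speciesA", "diversity", f"G{g + 1}", "", False))
    for i in range(config.n_species_b):
        columns.append(_diploids_from_freq(freq_b, 1, rng)[:, 0])
        sid = f"B_div{i + 1:02d}"
        sample_ids.append(sid)
        panel_rows.append((sid, "speciesB", "diversity", "B", "", False))

    matrix = GenotypeMatrix(np.column_stack(columns),
                            simulate_loci(model, config).index.to_numpy(),
                            np.asarray(sample_ids, dtype=object))
    panel = pd.DataFrame(
        panel_rows,
        columns=["sample_id", "species", "role", "group",
                 "replicate_of", "admixed"]).set_index("sample_id")
    return pools, matrix, panel


# ---------------------------------------------------------------------------
# allotetraploid


def _collapse_tetraploid(hapsA: np.ndarray, hapsB: np.ndarray) -> np.ndarray:
    """Collapse 4 haplotypes to an array-style diploid call: het whenever
    both alleles are present across the four doses."""
    total = hapsA.sum(axis=0) + hapsB.sum(axis=0)
    out = np.full(total.shape, 1, dtype=np.int8)
    out[total == 0] = 0
    out[total == hapsA.shape[0] + hapsB.shape[0]] = 2
    return out


def simulate_allotetraploid(poolA: HaplotypePool, poolB: HaplotypePool,
                            n_individuals: int, seed: int,
                            locus_ids: np.ndarray | None = None
                            ) -> tuple[GenotypeMatrix, str]:
    """Allotetraploids with two haplotypes from each progenitor pool, plus
    one dihaploid carrying a single haplotype per subgenome.

    Calls are collapsed dosages: a locus divergently fixed between the two
    pools is heterozygous in every tetraploid and in the dihaploid (fixed
    heterozygosity). Returns the matrix (tetraploids then the dihaploid)
    and the dihaploid's sample id.
    """
    if poolA.n_loci != poolB.n_loci:
        raise ValueError("pools must share the locus list")
    if n_individuals < 1:
        raise ValueError("need at least one tetraploid")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    cols, ids = [], []
    for i in range(n_individuals):
        ia = rng.choice(poolA.haplotypes.shape[0], size=2, replace=False)
        ib = rng.choice(poolB.haplotypes.shape[0], size=2, replace=False)
        cols.append(_collapse_tetraploid(poolA.haplotypes[ia],
                                         poolB.haplotypes[ib]))
        ids.append(f"T_{i + 1:02d}")
    ia = rng.integers(poolA.haplotypes.shape[0])
    ib = rng.integers(poolB.haplotypes.shape[0])
    cols.append((poolA.haplotypes[ia] + poolB.haplotypes[ib]).astype(np.int8))
    dihaploid_id = "DH_1"
    ids.append(dihaploid_id)
    loci = (np.asarray(locus_ids, dtype=object) if locus_ids is not None
            else np.asarray([f"L{j}" for j in range(poolA.n_loci)],
                            dtype=object))
    return GenotypeMatrix(np.column_stack(cols), loci,
                          np.asarray(ids, dtype=object)), dihaploid_id


# ---------------------------------------------------------------------------
# mapping progenies


def _gametes(phased: np.ndarray, rec: np.ndarray, chrom_codes: np.ndarray,
             n: int, rng: np.random.Generator) -> np.ndarray:
    """Recombinant gametes from a phased diploid.

    ``phased`` is (2, n_loci); ``rec`` holds the recombination fraction
    between locus i-1 and i (entries at chromosome starts are ignored:
    a fresh haplotype is drawn there). Returns (n_loci, n) alleles.
    """
    n_loci = phased.shape[1]
    new_chrom = np.empty(n_loci, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom_codes[1:] != chrom_codes[:-1]
    switch = rng.random((n_loci, n)) < rec[:, None]
    switch[new_chrom] = rng.random((new_chrom.sum(), n)) < 0.5
    # phase index = cumulative XOR of switches, reset at chromosome starts
    phase = np.zeros((n_loci, n), dtype=np.int8)
    current = np.zeros(n, dtype=np.int8)
    for i in range(n_loci):
        if new_chrom[i]:
            current = switch[i].astype(np.int8)
        else:
            current = current ^ switch[i].astype(np.int8)
        phase[i] = current
    return np.where(phase == 0, phased[0][:, None], phased[1][:, None])


def recombination_fractions(positions_cm: np.ndarray,
                            chrom_codes: np.ndarray) -> np.ndarray:
    """Adjacent-locus recombination fractions via the inverse Kosambi map."""
    rec = np.zeros(len(positions_cm))
    d = np.diff(positions_cm)
    same = chrom_codes[1:] == chrom_codes[:-1]
    rec[1:][same] = kosambi_inverse_r(np.abs(d[same]))
    return rec


def simulate_mapping_progeny(parent1: np.ndarray, parent2: np.ndarray,
                             design: str, n_offspring: int,
                             positions_cm: np.ndarray,
                             chrom_codes: np.ndarray, seed: int,
                             locus_ids: np.ndarray | None = None
                             ) -> tuple[GenotypeMatrix, dict]:
    """Progeny dosages for an F1 pseudo-testcross or a selfed F2.

    Parents are phased diploids of shape (2, n_loci). For the F1 design
    each offspring unites one recombinant gamete per parent. For the F2
    design a single F1 individual is first formed from one gamete of each
    parent, then selfed: each offspring unites two independent recombinant
    gametes of that F1. Crossovers follow a no-interference Markov walk
    along loci with adjacent fractions from the inverse Kosambi function.

    Returns the progeny matrix and a truth dict (the F1 phase for the F2
    design, empty otherwise).
    """
    for p in (parent1, parent2):
        p = np.asarray(p)
        if p.ndim != 2 or p.shape[0] != 2:
            raise ValueError("parents must be phased (2, n_loci) arrays")
    if design not in ("F1_pseudo_testcross", "F2_self"):
        raise ValueError(f"unknown design {design!r}")
    if n_offspring < 1:
        raise ValueError("n_offspring must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    rec = recombination_fractions(np.asarray(positions_cm, dtype=float),
                                  np.asarray(chrom_codes))
    truth: dict = {}
    if design == "F1_pseudo_testcross":
        g1 = _gametes(np.asarray(parent1), rec, chrom_codes, n_offspring, rng)
        g2 = _gametes(np.asarray(parent2), rec, chrom_codes, n_offspring, rng)
        calls = (g1 + g2).astype(np.int8)
    else:
        f1 = np.vstack([
            _gametes(np.asarray(parent1), rec, chrom_codes, 1, rng)[:, 0],
            _gametes(np.asarray(parent2), rec, chrom_codes, 1, rng)[:, 0]])
        truth["f1_phase"] = f1
        g1 = _gametes(f1, rec, chrom_codes, n_offspring, rng)
        g2 = _gametes(f1, rec, chrom_codes, n_offspring, rng)
        calls = (g1 + g2).astype(np.int8)
    loci = (np.asarray(locus_ids, dtype=object) if locus_ids is not None
            else np.asarray([f"L{j}" for j in range(calls.shape[0])],
                            dtype=object))
    ids = np.asarray([f"P_{j + 1:03d}" for j in range(n_offspring)],
                     dtype=object)
    return GenotypeMatrix(calls, loci, ids), truth


# ---------------------------------------------------------------------------
# missingness & file output


def inject_missingness(matrix: GenotypeMatrix, missing_rate: float,
                       seed: int) -> GenotypeMatrix:
    """Set each call to MISSING independently with probability
    ``missing_rate`` (uniform at random; no platform failure modes)."""
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    calls = matrix.calls.copy()
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    return GenotypeMatrix(calls, matrix.locus_ids.copy(),
                          matrix.sample_ids.copy())


def inject_missingness_and_write(matrix: GenotypeMatrix,
                                 catalog: pd.DataFrame,
                                 model: GenomeModel,
                                 out_dir, missing_rate: float, seed: int,
                                 panel: pd.DataFrame | None = None,
                                 truth: dict | None = None) -> dict:
    """Apply missingness and write the full synthetic file set.

    Emits ``genotypes.vcf`` (VCF 4.2, 1-based, QUAL column), ``genome.fa``,
    ``annotation.gff3``, ``panel.tsv`` (when a panel is given) and
    ``truth.json`` (when truth is given). Returns a name -> path dict.
    """
    from . import io as _io
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    noisy = inject_missingness(matrix, missing_rate, seed)
    paths = {
        "vcf": _io.write_vcf(catalog, noisy, out / "genotypes.vcf"),
        "fasta": _io.write_fasta(model, out / "genome.fa", seed=seed),
        "gff3": _io.write_gff3(model, out / "annotation.gff3"),
    }
    if panel is not None:
        paths["panel"] = _io.write_panel(panel, out / "panel.tsv")
    if truth is not None:
        paths["truth"] = _io.write_truth(truth, out / "truth.json")
    return paths
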