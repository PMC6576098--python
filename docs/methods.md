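# Methods

## The system being modelled

An allotetraploid species (genome C·E, 2n = 4x) formed by hybridization of
two diploids: species A, outcrossing and strongly structured into discrete
genetic groups, and species B, with much lower standing diversity. Array
genotyping reports cluster-based calls, so a tetraploid genotype is
collapsed to {hom-ref, het, hom-alt}: a site where the two subgenomes carry
different fixed alleles is heterozygous in *every* individual ("fixed
heterozygosity"). A dihaploid individual — one haplotype per subgenome —
is the key instrument: it is heterozygous exactly at those homeologous
sites, which drives both the array-design filter and the QC partition.

## Synthetic-data generator

The generator defines the study conditions; every analysis is validated
against it.

- **Genome.** 11 chromosomes by default (matching the reference genome's
  pseudo-chromosome count), 2 Mb each. Physical lengths are scaled down by
  roughly an order of magnitude relative to a real ~700 Mb genome so that a
  full run of every stage stays interactive; all downstream statistics are
  functions of marker density and map length, not absolute genome size.
  Genes occupy a fixed fraction (default 0.40, the array's genic share) of
  each 10 kb slot at a random offset, giving an exact genic fraction and
  non-overlapping intervals.
- **Allele frequencies.** Hierarchical Balding–Nichols model: per locus an
  ancestral frequency p ~ U(0.05, 0.95); each species-A group draws its
  frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with F = `fst_species_a`
  (default 0.2 — strong, well-differentiated groups). Expected Hudson-type
  Fst between two groups equals F, which the tests verify. Species B is
  fixed at a random allele per locus except for a `diversity_species_b`
  fraction (default 0.05) of segregating loci; about half of its fixed loci
  are therefore divergent from species A's prevailing allele, generating
  fixed heterozygosity in the tetraploid.
- **Panels.** Defaults mirror the study panels: 27 species-A diversity
  accessions round-robin over 8 groups, 6 species-B accessions, 16
  tetraploids plus one dihaploid, F1 pseudo-testcross progeny of 93 and
  selfed-F2 progeny of 138.
- **Meiosis.** Gametes follow a no-interference Markov walk along each
  chromosome: adjacent-locus recombination fractions come from the inverse
  Kosambi function r = ½·tanh(d/50) of the cM gap (uniform bp→cM map,
  default 125 cM per chromosome). The F2 design forms a single F1 from one
  gamete of each founder and selfs it — one subgenome of the tetraploid is
  treated as an ordinary diploid, consistent with disomic inheritance;
  tetraploid meiosis is not modelled.
- **Missingness** is i.i.d. per call (default rate 0.08, matching observed
  ~92% mean call rates); platform-specific cluster-failure modes are not
  emulated.
- **Determinism.** All randomness flows from `SimulationConfig.seed`
  through `numpy.random.SeedSequence` children with fixed spawn keys; a
  config reproduces its output files byte for byte.

What the generator does *not* emulate — coalescent linkage disequilibrium
within populations, selection, mutation-rate heterogeneity, genotype-
intensity artefacts — bounds what passing tests show: they validate the
statistical machinery and its contracts, not platform-specific behaviour
on real intensity data. In particular the diversity panels have no
physical LD (loci are independent given group frequencies), so LD-decay
analyses are exercised on mapping progenies, where recombination generates
genuine distance-dependent correlation.

## Design choices that were genuinely open

- **"No variation in the flank"** is implemented as *no other variant call
  within 60 bp* (the design was filtered from VCFs); reference k-mer
  uniqueness screening is out of scope.
- **Spacing selection** is greedy left-to-right per chromosome with a
  40 kb default minimum. Candidate-gene loci are always selected and
  exempt from spacing (they were force-included on the array). Genic
  parity is approximated, not enforced: when the next eligible locus is
  not of the currently preferred class, a small look-ahead window (10 kb
  default) may substitute the first locus of the preferred class; the
  preference alternates after each pick. The achieved balance is reported.
- **QUAL** comparison is strict (> 40); a locus at exactly the threshold
  is rejected. The MAF (> 0.10) and missingness (< 10%) filters for LD are
  likewise strict.
- **"Scorable"** has no quantitative definition in a per-panel setting;
  the default requires a non-missing fraction ≥ 0.75 within the panel,
  configurable and recorded in the summary object.
- **Percentages** are rounded half-up to one decimal (integer for the
  map-table ratio), and every summary audits that its percentages
  recompute exactly from their count pairs.
- **r²** is composite LD — squared Pearson correlation of unphased dosage
  vectors over jointly called samples — not haplotype-EM r². The
  half-decay distance is taken on the binned means (default 1 kb bins in
  the API; pipeline bins scale with the distance cap), interpolated
  linearly between the straddling bins, and flagged undefined when the
  curve never reaches half its maximum.
- **NJ** is delegated to scikit-bio's Saitou–Nei implementation with
  negative branch lengths clamped to zero; ids are sorted before
  agglomeration so input order cannot change the topology. Bootstrap
  blocks are consecutive runs of 100 SNPs, trailing partial block kept;
  supports are the percentage of replicate trees containing each internal
  bipartition of the reference tree.
- **Haploid downscaling** applies to both query and reference
  heterozygotes (a homozygous-reference-only mode exists). The random
  stream is keyed by (seed, run, sample id) so enlarging the sample set
  never perturbs existing draws. Group scores are unweighted means of the
  member individuals' means; per-individual output is primary.
- **Two-point F2 EM** starts at r = 0.25, tolerance 1e-8, at most 500
  iterations, r clamped to [1e-9, 0.5]; coupling/repulsion is resolved by
  refitting with one locus recoded and keeping the higher likelihood. The
  χ² distortion test uses no continuity correction; the null-calibration
  check simulates progenies of 500 so the asymptotics are clean.
- **Co-segregation bins** merge markers whose jointly called progeny
  patterns are identical up to allele relabelling, closed transitively, so
  bins are genuine equivalence classes under missing data.
- **Multipoint ordering is out of scope.** Map summaries consume given
  (marker, LG, position) tables; `greedy_seriation` is a labelled
  convenience, not an ordering algorithm. Both the all-marker and the
  unique-position mean adjacent distances are reported; the
  unique-position figure is primary.

## Problem sizes

Tests and the acceptance script run the generator at 800–3000 loci,
6–11 chromosomes of 0.6–2 Mb, the default panel sizes, 50 recovery
replicates at 1000 loci / 200 runs, 10⁴ loci for the null-distortion
calibration, and 100 bootstrap replicates — sizes chosen so each
statistical check has comfortable resolving power while a full suite run
stays in the tens of seconds.

## Known limitations

- Tetraploid genotypes are collapsed calls; allele dosage (0–4) is never
  modelled, so dosage-aware methods cannot be validated here.
- The admixture flag on references is an input, not an inference; ancestry
  estimation (sNMF/ADMIXTURE-style) is intentionally not implemented.
- The LD half-decay of a structured multi-group panel depends on
  population history the generator does not model; only planted decay
  curves and progeny LD are quantitative targets.
- The F2 two-point EM assumes codominant biallelic markers; dominant
  markers and mixed-phase multi-locus likelihoods are not supported.
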