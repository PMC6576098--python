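"""Array-design filters against brute-force oracles and edge cases."""

import numpy as np
import pandas as pd
import pytest

from tetrasnp.core import MISSING, GenotypeMatrix
from tetrasnp.design import (SelectionConfig, annotate_genic,
                             arabica_subgenome_filter, basic_quality_filter,
                             canephora_recurrence_filter, design_summary,
                             spacing_selection)


def make_catalog(rows):
    """rows: (chrom, pos, ref, alt, qual[, genic_class, candidate])."""
    recs = []
    for r in rows:
        chrom, pos, ref, alt, qual = r[:5]
        genic = r[5] if len(r) > 5 else ""
        cand = r[6] if len(r) > 6 else ""
        recs.append((chrom, pos, ref, alt, qual, genic, cand))
    cat = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "qual",
                                      "genic_class", "candidate_gene_id"])
    cat.index = pd.Index([f"L{i}" for i in range(len(cat))],
                         name="locus_id")
    return cat


def random_catalog(rng, n=1000, chroms=("chr1", "chr2"), span=2_000_000):
    rows = []
    for chrom in chroms:
        pos = np.sort(rng.choice(span, size=n // len(chroms),
                                 replace=False)) + 1
        for p in pos:
            alt = rng.choice(["A", "C", "G,T"])  # some multi-allelic
            rows.append((chrom, int(p), "T", alt,
                         float(rng.uniform(10, 90))))
    return make_catalog(rows)


class TestBasicQualityFilter:
    def test_triallelic_removed(self):
        cat = make_catalog([("chr1", 100, "A", "C,G", 60.0)])
        assert basic_quality_filter(cat).empty

    def test_qual_threshold_is_strict(self):
        cat = make_catalog([("chr1", 100, "A", "C", 39.0),
                            ("chr1", 5000, "A", "C", 40.0),
                            ("chr1", 9000, "A", "C", 40.01)])
        kept = basic_quality_filter(cat)
        assert list(kept["pos"]) == [9000]

    def test_close_pair_removed_by_flanking_rule(self):
        cat = make_catalog([("chr1", 100, "A", "C", 60.0),
                            ("chr1", 150, "A", "C", 60.0)])
        assert basic_quality_filter(cat).empty

    def test_low_qual_neighbour_still_spoils_the_flank(self):
        cat = make_catalog([("chr1", 100, "A", "C", 10.0),
                            ("chr1", 130, "A", "C", 60.0)])
        assert basic_quality_filter(cat).empty

    def test_unsorted_input_rejected(self):
        cat = make_catalog([("chr1", 500, "A", "C", 60.0),
                            ("chr1", 100, "A", "C", 60.0)])
        with pytest.raises(ValueError):
            basic_quality_filter(cat)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        cat = random_catalog(rng)
        cfg = SelectionConfig()
        kept = basic_quality_filter(cat, cfg)
        expected = []
        for locus, row in cat.iterrows():
            if "," in row["alt"] or len(row["alt"]) != 1:
                continue
            if not row["qual"] > cfg.qual_min:
                continue
            near = cat[(cat["chrom"] == row["chrom"])
                       & (cat.index != locus)
                       & ((cat["pos"] - row["pos"]).abs() <= cfg.flank_bp)]
            if len(near) == 0:
                expected.append(locus)
        assert list(kept.index) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        cat = random_catalog(rng)
        once = basic_quality_filter(cat)
        twice = basic_quality_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_qual_monotonicity(self):
        rng = np.random.default_rng(3)
        cat = random_catalog(rng)
        counts = [len(basic_quality_filter(
            cat, SelectionConfig(qual_min=q))) for q in (20, 40, 60, 80)]
        assert counts == sorted(counts, reverse=True)


class TestArabicaSubgenomeFilter:
    def _matrix(self, dihaploid, accessions):
        calls = np.array([[dihaploid] + accessions], dtype=np.int8).T
        calls = calls.reshape(1, -1)
        return GenotypeMatrix(calls, np.array(["L0"], dtype=object),
                              np.array(["DH"] + [f"A{i}" for i in
                                                 range(len(accessions))],
                                       dtype=object))

    def _kept(self, dihaploid, accessions):
        m = self._matrix(dihaploid, accessions)
        cat = make_catalog([("chr1", 100, "A", "C", 60.0)])
        cat.index = pd.Index(["L0"], name="locus_id")
        out = arabica_subgenome_filter(
            cat, m, "DH", [f"A{i}" for i in range(len(accessions))])
        return len(out) == 1

    def test_heterozygous_dihaploid_removed(self):
        assert not self._kept(1, [0, 2, 0, 2, 0])

    def test_homref_dihaploid_with_divergent_homs_kept(self):
        assert self._kept(0, [0, 2, 0, 0, 0])

    def test_single_het_accession_not_enough(self):
        assert not self._kept(0, [0, 0, 0, 0, 1])

    def test_enumeration_oracle_five_accessions(self):
        """All 4^5 genotype configurations of 5 accessions, for each
        dihaploid state: the filter equals 'dihaploid homozygous AND at
        least one hom-ref and one hom-alt accession'."""
        states = (0, 1, 2, MISSING)
        for dh in states:
            for cfg_id in range(4 ** 5):
                acc = [states[(cfg_id // 4 ** k) % 4] for k in range(5)]
                expected = dh in (0, 2) and \
                    any(a == 0 for a in acc) and any(a == 2 for a in acc)
                assert self._kept(dh, acc) == expected

    def test_missing_dihaploid_sample_errors(self):
        m = self._matrix(0, [0, 2])
        cat = make_catalog([("chr1", 100, "A", "C", 60.0)])
        cat.index = pd.Index(["L0"], name="locus_id")
        with pytest.raises(KeyError):
            arabica_subgenome_filter(cat, m, "NOPE", ["A0", "A1"])


class TestRecurrenceFilter:
    def _run(self, calls):
        calls = np.asarray(calls, dtype=np.int8)
        m = GenotypeMatrix(
            calls, np.array([f"L{i}" for i in range(calls.shape[0])],
                            dtype=object),
            np.array([f"S{j}" for j in range(calls.shape[1])], dtype=object))
        cat = make_catalog([("chr1", 100 * (i + 1) + 1000 * i, "A", "C", 60.0)
                            for i in range(calls.shape[0])])
        cat.index = pd.Index([f"L{i}" for i in range(calls.shape[0])],
                             name="locus_id")
        return canephora_recurrence_filter(cat, m)

    def test_singleton_removed(self):
        assert self._run([[1] + [0] * 11]).empty

    def test_two_het_carriers_retained(self):
        assert len(self._run([[1, 1] + [0] * 10])) == 1

    def test_matches_carrier_count_oracle(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(50, 12)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        kept = self._run(calls)
        expected = []
        for i in range(50):
            row = calls[i][calls[i] != MISSING]
            alt_dose = int((row).sum())
            tot = 2 * len(row)
            minor_is_alt = alt_dose * 2 <= tot
            if minor_is_alt:
                carriers = int(((calls[i] == 1) | (calls[i] == 2)).sum())
            else:
                carriers = int(((calls[i] == 1) | (calls[i] == 0)).sum())
            if carriers >= 2:
                expected.append(f"L{i}")
        assert list(kept.index) == expected

    def test_empty_panel_errors(self):
        m = GenotypeMatrix(np.zeros((1, 0), dtype=np.int8),
                           np.array(["L0"], dtype=object),
                           np.array([], dtype=object))
        cat = make_catalog([("chr1", 100, "A", "C", 60.0)])
        cat.index = pd.Index(["L0"], name="locus_id")
        with pytest.raises(ValueError):
            canephora_recurrence_filter(cat, m)


class TestAnnotateGenic:
    GENES = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "start": [1000, 5000],
        "end": [1999, 5999],
        "gene_id": ["g1", "g2"],
    })

    def test_inside_interval_is_coding(self):
        cat = make_catalog([("chr1", 1500, "A", "C", 60.0)])
        out = annotate_genic(cat, self.GENES)
        assert out["genic_class"].iloc[0] == "coding"

    def test_interval_bounds_inclusive(self):
        cat = make_catalog([("chr1", 1000, "A", "C", 60.0),
                            ("chr1", 1999, "A", "C", 60.0),
                            ("chr1", 2000, "A", "C", 60.0)])
        out = annotate_genic(cat, self.GENES)
        assert list(out["genic_class"]) == ["coding", "coding",
                                            "non-coding"]

    def test_candidate_tagging(self):
        cat = make_catalog([("chr1", 5500, "A", "C", 60.0)])
        out = annotate_genic(cat, self.GENES, candidate_gene_ids={"g2"})
        assert out["candidate_gene_id"].iloc[0] == "g2"

    def test_matches_linear_scan_oracle(self, sim):
        rng = np.random.default_rng(5)
        genes = pd.DataFrame(sim["model"].gene_intervals,
                             columns=["chrom", "start", "end", "gene_id"])
        chroms = sim["model"].chromosomes
        rows = []
        for chrom in chroms:
            pos = np.sort(rng.choice(sim["model"].chrom_lengths[chrom],
                                     size=340, replace=False)) + 1
            rows += [(chrom, int(p), "A", "C", 60.0) for p in pos]
        cat = make_catalog(rows)
        out = annotate_genic(cat, genes)
        for locus, row in out.iterrows():
            hit = ((genes["chrom"] == row["chrom"])
                   & (genes["start"] <= row["pos"])
                   & (genes["end"] >= row["pos"])).any()
            assert (row["genic_class"] == "coding") == hit

    def test_unknown_chromosome_errors(self):
        cat = make_catalog([("chr1", 1500, "A", "C", 60.0)])
        with pytest.raises(ValueError):
            annotate_genic(cat, self.GENES, known_chroms={"chrX"})


class TestSpacingSelection:
    def test_greedy_pick_is_maximal(self):
        cat = make_catalog([("chr1", 100, "A", "C", 60.0),
                            ("chr1", 30_000, "A", "C", 60.0),
                            ("chr1", 50_000, "A", "C", 60.0)])
        out = spacing_selection(cat)
        assert list(out["pos"]) == [100, 50_000]

    def test_single_locus_retained(self):
        cat = make_catalog([("chr1", 100, "A", "C", 60.0)])
        assert len(spacing_selection(cat)) == 1

    def test_candidate_exempt_from_spacing(self):
        cat = make_catalog([("chr1", 100, "A", "C", 60.0, "coding", ""),
                            ("chr1", 10_100, "A", "C", 60.0, "coding", "g9"),
                            ("chr1", 60_000, "A", "C", 60.0, "coding", "")])
        out = spacing_selection(cat)
        assert set(out["pos"]) == {100, 10_100, 60_000}
        assert (out.loc[out["pos"] == 10_100,
                        "selection_class"] == "candidate").all()

    def test_greedy_matches_exhaustive_maximum(self):
        """Greedy cardinality equals the best over all spacing-valid
        subsets (exhaustive on 12 loci)."""
        from itertools import combinations
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(200_000, size=12, replace=False)) + 1
        cat = make_catalog([("chr1", int(p), "A", "C", 60.0) for p in pos])
        got = len(spacing_selection(cat))
        best = 0
        for k in range(len(pos), 0, -1):
            for sub in combinations(pos, k):
                if all(b - a >= 40_000 for a, b in zip(sub, sub[1:])):
                    best = k
                    break
            if best:
                break
        assert got == best

    def test_spacing_invariant_on_random_catalogs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            cat = random_catalog(rng, n=200, span=1_000_000)
            out = spacing_selection(cat)
            noncand = out[out["selection_class"] != "candidate"]
            for _, grp in noncand.groupby("chrom"):
                assert (np.diff(np.sort(grp["pos"])) >= 40_000).all()

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(8)
        cat = random_catalog(rng, n=300, span=3_000_000)
        once = spacing_selection(cat)
        twice = spacing_selection(once)
        pd.testing.assert_frame_equal(once, twice)
        shuffled = cat.sample(frac=1, random_state=1).sort_values(
            ["chrom", "pos"])
        again = spacing_selection(shuffled)
        assert set(once.index) == set(again.index)

    def test_empty_catalog_gives_empty_manifest(self):
        cat = make_catalog([])
        assert spacing_selection(cat).empty


class TestDesignSummary:
    def test_density_arithmetic(self):
        cat = make_catalog([("chr1", int(p), "A", "C", 60.0)
                            for p in np.linspace(1, 999_000, 10)])
        out = design_summary(cat, {"chr1": 1_000_000})
        assert out.loc["chr1", "density_per_mb"] == pytest.approx(10.0)

    def test_mean_adjacent_distance(self):
        cat = make_catalog([("chr1", 1, "A", "C", 60.0),
                            ("chr1", 100_001, "A", "C", 60.0),
                            ("chr1", 300_001, "A", "C", 60.0)])
        out = design_summary(cat, {"chr1": 1_000_000})
        assert out.loc["chr1", "mean_distance_bp"] == pytest.approx(150_000)

    def test_unanchored_excluded_from_genome_row(self):
        cat = make_catalog([("chr0", 100, "A", "C", 60.0),
                            ("chr1", 100, "A", "C", 60.0),
                            ("chr1", 500_000, "A", "C", 60.0)])
        out = design_summary(cat, {"chr0": 1_000_000, "chr1": 1_000_000})
        assert out.loc["GENOME", "n_markers"] == 2
        assert out.loc["GENOME", "density_per_mb"] == pytest.approx(2.0)
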