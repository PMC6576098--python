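"""LD machinery and NJ trees: formula oracles, planted curves and trees."""

import numpy as np
import pandas as pd
import pytest

from tetrasnp.core import MISSING, GenotypeMatrix
from tetrasnp.diversity import (LDResult, block_bootstrap_support,
                                decay_curve, euclidean_distance_matrix,
                                ld_filter, nj_tree, pairwise_r2)


def matrix_from(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        calls,
        np.asarray([f"L{i}" for i in range(calls.shape[0])], dtype=object),
        np.asarray([f"S{j}" for j in range(calls.shape[1])], dtype=object))


def catalog_for(m, chrom="chr1", spacing=100):
    return pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, m.n_loci + 1) * spacing},
        index=pd.Index(m.locus_ids, name="locus_id"))


class TestLdFilter:
    def test_maf_threshold_strict(self):
        # 10 samples: one het => MAF 0.05; five het => 0.25; two hom-alt
        # and ... MAF exactly 0.10 = 2 alt alleles /20
        rows = [
            [1] + [0] * 9,        # MAF 0.05 -> drop
            [1, 1] + [0] * 8,     # MAF 0.10 exactly -> drop (strict)
            [1, 1, 1] + [0] * 7,  # MAF 0.15 -> keep
        ]
        m = matrix_from(rows)
        out = ld_filter(m, catalog_for(m))
        assert list(out.locus_ids) == ["L2"]

    def test_missing_threshold_strict(self):
        base = [0, 2] * 5
        exact = list(base)
        exact[0] = MISSING  # 1/10 = 10% missing exactly -> drop
        m = matrix_from([base, exact])
        out = ld_filter(m, catalog_for(m))
        assert list(out.locus_ids) == ["L0"]

    def test_unanchored_chromosome_removed(self):
        m = matrix_from([[0, 2] * 5, [0, 2] * 5])
        cat = catalog_for(m)
        cat.loc["L1", "chrom"] = "chr0"
        out = ld_filter(m, cat)
        assert list(out.locus_ids) == ["L0"]


class TestPairwiseR2:
    def test_identical_columns_r2_one(self):
        m = matrix_from([[0, 1, 2, 0, 1], [0, 1, 2, 0, 1]])
        res = pairwise_r2(m, catalog_for(m), max_dist_bp=1000)
        assert res.records["r2"].iloc[0] == pytest.approx(1.0)

    def test_complement_r2_one(self):
        a = [0, 1, 2, 0, 1]
        m = matrix_from([a, [2 - x for x in a]])
        res = pairwise_r2(m, catalog_for(m), max_dist_bp=1000)
        assert res.records["r2"].iloc[0] == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(21)
        calls = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        m = matrix_from(calls)
        cat = catalog_for(m, spacing=10)
        res = pairwise_r2(m, cat, max_dist_bp=10 * 50)
        pos = cat["pos"].to_numpy()
        k = 0
        for i in range(50):
            for j in range(i + 1, 50):
                ok = (calls[i] != MISSING) & (calls[j] != MISSING)
                if ok.sum() < 2:
                    continue
                x, y = calls[i][ok].astype(float), calls[j][ok].astype(float)
                if x.var() == 0 or y.var() == 0:
                    continue
                r2 = (np.mean((x - x.mean()) * (y - y.mean())) ** 2
                      / (x.var() * y.var()))
                row = res.records.iloc[k]
                assert row["distance_bp"] == pos[j] - pos[i]
                assert abs(row["r2"] - r2) < 1e-10
                k += 1
        assert k == len(res.records)

    def test_r2_bounded_and_relabel_invariant(self):
        rng = np.random.default_rng(22)
        calls = rng.integers(0, 3, size=(20, 15)).astype(np.int8)
        m = matrix_from(calls)
        res = pairwise_r2(m, catalog_for(m), max_dist_bp=100000)
        assert ((res.records["r2"] >= 0) & (res.records["r2"] <= 1)).all()
        flipped = matrix_from(2 - calls)
        res2 = pairwise_r2(flipped, catalog_for(flipped),
                           max_dist_bp=100000)
        np.testing.assert_allclose(res.records["r2"], res2.records["r2"],
                                   atol=1e-12)


class TestDecayCurve:
    def test_planted_exponential_half_decay(self):
        """r²(d)=exp(-d/c) sampled densely: half-decay ~ c·ln2 within one
        bin width."""
        c, bin_w = 5000.0, 1000
        d = np.arange(50, 30_000, 50)
        res = LDResult(pd.DataFrame({"distance_bp": d,
                                     "r2": np.exp(-d / c)}))
        res = decay_curve(res, bin_width_bp=bin_w)
        assert res.half_decay_defined
        assert abs(res.half_decay_bp - c * np.log(2)) <= bin_w

    def test_curve_never_crossing_flagged(self):
        d = np.arange(100, 5000, 100)
        res = LDResult(pd.DataFrame({"distance_bp": d,
                                     "r2": 0.9 - 1e-6 * d}))
        res = decay_curve(res, bin_width_bp=1000)
        assert not res.half_decay_defined

    def test_flat_curve_flagged(self):
        d = np.arange(100, 5000, 100)
        res = LDResult(pd.DataFrame({"distance_bp": d, "r2": 0.5}))
        res = decay_curve(res, bin_width_bp=1000)
        assert not res.half_decay_defined

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            decay_curve(LDResult(pd.DataFrame({"distance_bp": [],
                                               "r2": []})))


class TestEuclideanDistance:
    def test_identical_samples_zero(self):
        m = matrix_from([[1, 1], [2, 2]])
        d = euclidean_distance_matrix(m)
        assert d.iloc[0, 1] == 0.0

    def test_hand_example(self):
        m = matrix_from([[0, 2], [0, 2]])
        d = euclidean_distance_matrix(m)
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(8))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(23)
        calls = rng.integers(0, 3, size=(20, 5)).astype(np.int8)
        m = matrix_from(calls)
        d = euclidean_distance_matrix(m)
        for i in range(5):
            for j in range(5):
                expect = np.sqrt(((calls[:, i] - calls[:, j]) ** 2).sum())
                assert d.iloc[i, j] == pytest.approx(expect)

    def test_complete_loci_only(self):
        calls = np.array([[0, 2], [MISSING, 2], [2, 0]], dtype=np.int8)
        d = euclidean_distance_matrix(matrix_from(calls))
        # locus 1 dropped -> distance over loci 0 and 2
        assert d.iloc[0, 1] == pytest.approx(np.sqrt(4 + 4))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(24)
        m = matrix_from(rng.integers(0, 3, size=(30, 6)).astype(np.int8))
        d = euclidean_distance_matrix(m).to_numpy()
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def random_additive_tree(rng, n_taxa):
    """Random binary tree with branch lengths; returns (newick-free)
    pairwise path-length distances and the set of non-trivial splits."""
    import itertools
    nodes = [frozenset([i]) for i in range(n_taxa)]
    children = {}
    lengths = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = a | b
        children[parent] = (a, b)
        lengths[a] = rng.uniform(0.5, 2.0)
        lengths[b] = rng.uniform(0.5, 2.0)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    # distances by path lengths
    dist = np.zeros((n_taxa, n_taxa))

    def leaf_depths(node, acc):
        if node in children:
            out = {}
            for ch in children[node]:
                for leaf, d in leaf_depths(ch, acc).items():
                    out[leaf] = d + lengths[ch]
            return out
        return {next(iter(node)): 0.0}

    def fill(node):
        if node not in children:
            return
        a, b = children[node]
        da = {l: d + lengths[a] for l, d in leaf_depths(a, 0).items()}
        db = {l: d + lengths[b] for l, d in leaf_depths(b, 0).items()}
        for la, va in da.items():
            for lb, vb in db.items():
                dist[la, lb] = dist[lb, la] = va + vb
        fill(a)
        fill(b)

    fill(root)
    taxa = frozenset(f"t{i}" for i in range(n_taxa))
    splits = set()
    for node in children:
        side = frozenset(f"t{i}" for i in node)
        if "t0" in side:
            side = taxa - side
        if 1 < len(side) < n_taxa - 1:
            splits.add(side)
    return dist, splits


def tree_splits(tree, taxa):
    anchor = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            parts.add(side)
    return parts


class TestNjTree:
    def test_additive_four_taxa_exact(self):
        """NJ on additive distances reproduces both the topology and the
        path-length distances exactly."""
        rng = np.random.default_rng(31)
        dist, splits = random_additive_tree(rng, 4)
        ids = [f"t{i}" for i in range(4)]
        frame = pd.DataFrame(dist, index=ids, columns=ids)
        res = nj_tree(frame)
        taxa = frozenset(ids)
        assert tree_splits(res.tree, taxa) == splits
        tt = res.tree.tip_tip_distances()
        for ii, a in enumerate(ids):
            for jj, b in enumerate(ids):
                assert tt[a, b] == pytest.approx(dist[ii, jj], abs=1e-9)

    def test_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = nj_tree(d)
        tt = res.tree.tip_tip_distances()
        for a in "abc":
            for b in "abc":
                assert tt[a, b] == pytest.approx(d.loc[a, b], abs=1e-9)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(32)
        dist, _ = random_additive_tree(rng, 6)
        ids = [f"t{i}" for i in range(6)]
        frame = pd.DataFrame(dist, index=ids, columns=ids)
        perm = list(np.random.default_rng(1).permutation(6))
        shuffled = frame.iloc[perm, perm]
        taxa = frozenset(ids)
        assert tree_splits(nj_tree(frame).tree, taxa) == \
            tree_splits(nj_tree(shuffled).tree, taxa)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d)


def two_group_matrix(rng, n_loci=600, n_per_group=6, delta=0.8):
    """Two clearly separated groups: allele frequencies differ by delta."""
    p = np.full(n_loci, 0.1)
    q = p + delta
    cols = []
    for _ in range(n_per_group):
        cols.append(((rng.random(n_loci) < p).astype(np.int8)
                     + (rng.random(n_loci) < p).astype(np.int8)))
    for _ in range(n_per_group):
        cols.append(((rng.random(n_loci) < q).astype(np.int8)
                     + (rng.random(n_loci) < q).astype(np.int8)))
    calls = np.column_stack(cols)
    ids = [f"g1_{i}" for i in range(n_per_group)] + \
          [f"g2_{i}" for i in range(n_per_group)]
    return GenotypeMatrix(
        calls, np.asarray([f"L{i}" for i in range(n_loci)], dtype=object),
        np.asarray(ids, dtype=object))


class TestBlockBootstrap:
    def test_planted_split_high_support(self):
        rng = np.random.default_rng(33)
        m = two_group_matrix(rng)
        res = block_bootstrap_support(m, n_boot=100, block_snps=100, seed=5)
        split = frozenset(s for s in m.sample_ids if s.startswith("g2"))
        assert res.supports[split] >= 95

    def test_zero_bootstraps_reference_only(self):
        rng = np.random.default_rng(34)
        m = two_group_matrix(rng, n_loci=150)
        res = block_bootstrap_support(m, n_boot=0, block_snps=100, seed=5)
        assert res.supports is None

    def test_same_seed_same_supports(self):
        rng = np.random.default_rng(35)
        m = two_group_matrix(rng, n_loci=300)
        a = block_bootstrap_support(m, n_boot=20, block_snps=100, seed=7)
        b = block_bootstrap_support(m, n_boot=20, block_snps=100, seed=7)
        assert a.supports == b.supports

    def test_fewer_loci_than_block_errors(self):
        rng = np.random.default_rng(36)
        m = two_group_matrix(rng, n_loci=50)
        with pytest.raises(ValueError):
            block_bootstrap_support(m, n_boot=10, block_snps=100, seed=1)
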