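"""Linkage-disequilibrium decay and distance-based trees.

LD is measured as composite r² — the squared Pearson correlation of
unphased dosage vectors over jointly called samples — for same-chromosome
pairs within a distance cap, then binned by physical distance; the
half-decay distance is where the binned mean first falls to half its
maximum (linear interpolation between the straddling bins). Trees are
neighbour-joining on Euclidean dosage distances over complete loci, with
node supports from a block bootstrap that resamples consecutive SNP
blocks, respecting the correlation structure along the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .core import MISSING, UNANCHORED, GenotypeMatrix

__all__ = [
    "LDResult", "TreeResult", "ld_filter", "pairwise_r2", "decay_curve",
    "euclidean_distance_matrix", "nj_tree", "block_bootstrap_support",
]


@dataclass
class LDResult:
    """Pairwise r² records plus the binned decay curve."""

    records: pd.DataFrame              # columns: distance_bp, r2
    curve: pd.DataFrame | None = None  # columns: bin_mid_bp, mean_r2, n
    half_decay_bp: float | None = None
    half_decay_defined: bool = True


@dataclass
class TreeResult:
    """A Newick tree with optional bootstrap supports per bipartition."""

    newick: str
    tree: TreeNode
    supports: dict[frozenset, float] | None = None


# ---------------------------------------------------------------------------
# LD


def maf(calls: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per locus over called samples (rows loci)."""
    called = calls != MISSING
    alt = np.where(called, calls, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / tot, np.nan)
    return np.minimum(p, 1 - p)


def ld_filter(matrix: GenotypeMatrix, catalog: pd.DataFrame,
              maf_min: float = 0.10, max_missing: float = 0.10,
              unanchored: str = UNANCHORED) -> GenotypeMatrix:
    """Retain loci with MAF strictly above ``maf_min``, missing fraction
    strictly below ``max_missing``, and not on the unanchored
    pseudo-chromosome. Both comparisons are strict."""
    cat = catalog.loc[matrix.locus_ids]
    miss = (matrix.calls == MISSING).mean(axis=1)
    freq = maf(matrix.calls)
    keep = (freq > maf_min) & (miss < max_missing) & \
           (cat["chrom"] != unanchored).to_numpy()
    return matrix.subset_loci(keep)


def _r2_pair(a: np.ndarray, b: np.ndarray) -> float | None:
    """Squared Pearson correlation over jointly called samples; None for
    a pair with zero variance (monomorphic in the joint set)."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return None
    x = a[ok].astype(float)
    y = b[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return None
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def pairwise_r2(matrix: GenotypeMatrix, catalog: pd.DataFrame,
                max_dist_bp: int) -> LDResult:
    """r² for every same-chromosome locus pair within ``max_dist_bp``.

    Loci must be position-sorted within each chromosome. Pairs in which
    either locus has zero dosage variance over the joint samples are
    skipped.
    """
    cat = catalog.loc[matrix.locus_ids]
    dists, r2s = [], []
    for _, grp in cat.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if not np.all(np.diff(pos) >= 0):
            raise ValueError("loci must be position-sorted per chromosome")
        rows = matrix.subset_loci(grp.index.to_numpy()).calls
        for i in range(len(pos)):
            j = i + 1
            while j < len(pos) and pos[j] - pos[i] <= max_dist_bp:
                r2 = _r2_pair(rows[i], rows[j])
                if r2 is not None:
                    dists.append(int(pos[j] - pos[i]))
                    r2s.append(r2)
                j += 1
    return LDResult(pd.DataFrame({"distance_bp": dists, "r2": r2s}))


def decay_curve(result: LDResult, bin_width_bp: int = 1000) -> LDResult:
    """Bin the pairwise records and locate the half-decay distance.

    The half-decay distance is where the binned mean r² first reaches half
    of the *maximum binned mean*, linearly interpolated between the two
    straddling bin midpoints. When the curve never crosses half-maximum
    the distance is undefined and flagged.
    """
    rec = result.records
    if rec.empty:
        raise ValueError("no pairwise records to bin")
    bin_idx = rec["distance_bp"] // bin_width_bp
    grouped = rec.groupby(bin_idx)["r2"].agg(["mean", "size"])
    curve = pd.DataFrame({
        "bin_mid_bp": (grouped.index.to_numpy() + 0.5) * bin_width_bp,
        "mean_r2": grouped["mean"].to_numpy(),
        "n": grouped["size"].to_numpy(),
    }).reset_index(drop=True)
    result.curve = curve
    target = curve["mean_r2"].max() / 2.0
    mids = curve["bin_mid_bp"].to_numpy()
    means = curve["mean_r2"].to_numpy()
    start = int(np.argmax(means))
    half = None
    for k in range(start, len(means)):
        if means[k] <= target:
            if k == 0:
                half = float(mids[0])
            else:
                x0, x1 = mids[k - 1], mids[k]
                y0, y1 = means[k - 1], means[k]
                half = float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0)) \
                    if y0 != y1 else float(x1)
            break
    result.half_decay_bp = half
    result.half_decay_defined = half is not None
    return result


# ---------------------------------------------------------------------------
# distances & trees


def euclidean_distance_matrix(matrix: GenotypeMatrix,
                              complete_loci_only: bool = True
                              ) -> pd.DataFrame:
    """Euclidean distance between sample dosage vectors.

    With ``complete_loci_only`` (the default) only loci called in every
    sample enter the computation, so all pairs share the same locus set.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = matrix.calls
    if complete_loci_only:
        complete = (calls != MISSING).all(axis=1)
        if not complete.any():
            raise ValueError("no loci without missing data")
        calls = calls[complete]
    d = squareform(pdist(calls.T.astype(float), metric="euclidean"))
    return pd.DataFrame(d, index=matrix.sample_ids,
                        columns=matrix.sample_ids)


def nj_tree(distance: pd.DataFrame) -> TreeResult:
    """Neighbour joining (Saitou–Nei) on a symmetric distance matrix.

    Ids are sorted before agglomeration so the topology does not depend on
    input row order; negative branch lengths are clamped to zero by the
    solver.
    """
    d = distance.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if d.shape[0] < 3:
        raise ValueError("neighbour joining needs at least three samples")
    order = np.argsort(np.asarray(distance.index, dtype=object))
    ids = [str(distance.index[i]) for i in order]
    dm = DistanceMatrix(d[np.ix_(order, order)], ids)
    tree = nj(dm, neg_as_zero=True)
    return TreeResult(str(tree).strip(), tree)


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions, each encoded as the side not containing
    the lexicographically smallest taxon (a canonical form)."""
    anchor = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if 1 < len(side) < len(taxa) - 1:
            parts.add(side)
    return parts


def block_bootstrap_support(matrix: GenotypeMatrix, n_boot: int = 100,
                            block_snps: int = 100, seed: int = 0,
                            complete_loci_only: bool = True) -> TreeResult:
    """NJ tree with supports from a block bootstrap over consecutive SNPs.

    Loci (assumed to be in genome order) are cut into consecutive blocks
    of ``block_snps`` (trailing partial block kept); each replicate
    resamples blocks with replacement up to the original block count,
    rebuilds the tree, and each internal bipartition of the reference tree
    is scored by the percentage of replicate trees containing it.
    ``n_boot=0`` returns the reference tree with no supports.
    """
    if matrix.n_loci < block_snps:
        raise ValueError("fewer loci than one bootstrap block")
    ref_dist = euclidean_distance_matrix(matrix, complete_loci_only)
    ref = nj_tree(ref_dist)
    if n_boot == 0:
        return ref
    taxa = frozenset(str(s) for s in matrix.sample_ids)
    ref_parts = _bipartitions(ref.tree, taxa)
    counts = {p: 0 for p in ref_parts}
    n_blocks = int(np.ceil(matrix.n_loci / block_snps))
    blocks = [np.arange(i * block_snps,
                        min((i + 1) * block_snps, matrix.n_loci))
              for i in range(n_blocks)]
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    for _ in range(n_boot):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        idx = np.concatenate([blocks[c] for c in chosen])
        boot = GenotypeMatrix(matrix.calls[idx],
                              np.asarray([f"b{k}" for k in range(len(idx))],
                                         dtype=object),
                              matrix.sample_ids.copy())
        try:
            bt = nj_tree(euclidean_distance_matrix(boot, complete_loci_only))
        except ValueError:  # replicate without complete loci: no votes
            continue
        parts = _bipartitions(bt.tree, taxa)
        for p in ref_parts:
            if p in parts:
                counts[p] += 1
    supports = {p: 100.0 * c / n_boot for p, c in counts.items()}
    ref.supports = supports
    _label_supports(ref.tree, taxa, supports)
    ref.newick = str(ref.tree).strip()
    return ref


def _label_supports(tree: TreeNode, taxa: frozenset,
                    supports: dict[frozenset, float]) -> None:
    anchor = min(taxa)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = taxa - side
        if side in supports:
            node.name = f"{supports[side]:.0f}"
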