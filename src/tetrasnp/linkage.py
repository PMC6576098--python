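"""Segregation classification, distortion tests and two-point linkage.

Covers the statistics a biparental mapping experiment needs before
multipoint ordering: classifying each locus's segregation type from the
parental calls, Pearson chi-square tests against the Mendelian expectation
(flagged at p < 0.01 and p < 0.001), maximum-likelihood two-point
recombination fractions (direct counting for fully informative F1
configurations, EM over the ambiguous double-heterozygote class for F2
codominant data), the Kosambi map function, co-segregation binning and
per-linkage-group map summaries. Multipoint ordering itself is out of
scope; `greedy_seriation` is a convenience only and makes no optimality
claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix, round_half_up

__all__ = [
    "LinkageObservation", "classify_segregation", "distortion_test",
    "two_point", "kosambi_cm", "kosambi_inverse_r", "cluster_cosegregating",
    "map_summary", "greedy_seriation",
]

SEG_1_1 = "1:1"      # het x hom (either direction), F1 pseudo-testcross
SEG_1_2_1 = "1:2:1"  # het x het (F1) or founder-divergent F2 codominant
NON_SEGREGATING = "non_segregating"
UNUSABLE = "unusable"


@dataclass
class LinkageObservation:
    """Per-locus progeny segregation record with its test result."""

    locus_id: str
    seg_type: str
    counts: dict[str, int]
    chi2: float | None = None
    p_value: float | None = None
    distorted_p01: bool = False
    distorted_p001: bool = False


# ---------------------------------------------------------------------------
# classification


def classify_segregation(parent1_call: int, parent2_call: int,
                         design: str) -> str:
    """Segregation type implied by the two parental dosage calls.

    F1 pseudo-testcross: het x hom and hom x het segregate 1:1,
    het x het segregates 1:2:1 (codominant), hom x hom does not segregate.
    F2 (selfed F1 of a biparental cross): only loci where the founders are
    homozygous for different alleles are informative (the F1 is then
    heterozygous, progeny 1:2:1). A missing parental call makes the locus
    unusable.
    """
    p1, p2 = parent1_call, parent2_call
    if p1 == MISSING or p2 == MISSING:
        return UNUSABLE
    if design == "F1_pseudo_testcross":
        het1, het2 = p1 == 1, p2 == 1
        if het1 and het2:
            return SEG_1_2_1
        if het1 or het2:
            return SEG_1_1
        return NON_SEGREGATING
    if design == "F2_self":
        if {p1, p2} == {0, 2}:
            return SEG_1_2_1
        return NON_SEGREGATING
    raise ValueError(f"unknown design {design!r}")


def segregation_counts(progeny_calls: np.ndarray, seg_type: str
                       ) -> dict[str, int]:
    """Tally progeny dosage classes for one locus (missing excluded)."""
    called = progeny_calls[progeny_calls != MISSING]
    counts = {int(k): int(v) for k, v in
              zip(*np.unique(called, return_counts=True))}
    if seg_type == SEG_1_1:
        # het x hom-ref yields {0,1}; het x hom-alt yields {1,2}
        keys = sorted(set(counts) | {1})
        return {str(k): counts.get(k, 0) for k in keys}
    return {str(k): counts.get(k, 0) for k in (0, 1, 2)}


# ---------------------------------------------------------------------------
# distortion


_EXPECTED = {SEG_1_1: np.array([0.5, 0.5]),
             SEG_1_2_1: np.array([0.25, 0.5, 0.25])}


def distortion_test(obs: LinkageObservation) -> LinkageObservation:
    """Pearson chi-square of the observed counts against the Mendelian
    ratio for the locus's segregation type (no continuity correction).

    df = number of genotype classes - 1. Flags are set at p < 0.01 and
    p < 0.001. The observation is updated in place and returned.
    """
    if obs.seg_type not in _EXPECTED:
        raise ValueError(f"no Mendelian expectation for {obs.seg_type!r}")
    expected = _EXPECTED[obs.seg_type]
    observed = np.array(list(obs.counts.values()), dtype=float)
    if observed.size != expected.size:
        raise ValueError(
            f"{obs.seg_type} needs {expected.size} classes, got "
            f"{observed.size}")
    total = observed.sum()
    if total == 0:
        raise ValueError("zero progeny counted")
    chi2, p = stats.chisquare(observed, f_exp=expected * total)
    obs.chi2, obs.p_value = float(chi2), float(p)
    obs.distorted_p01 = p < 0.01
    obs.distorted_p001 = p < 0.001
    return obs


def distortion_scan(progeny: GenotypeMatrix, parent_calls: pd.DataFrame,
                    design: str) -> pd.DataFrame:
    """Classify and test every locus; returns a tidy per-locus table."""
    rows = []
    for i, locus in enumerate(progeny.locus_ids):
        p1, p2 = parent_calls.loc[locus, ["parent1", "parent2"]]
        seg = classify_segregation(int(p1), int(p2), design)
        if seg in (NON_SEGREGATING, UNUSABLE):
            rows.append((locus, seg, np.nan, np.nan, False, False))
            continue
        obs = LinkageObservation(locus, seg,
                                 segregation_counts(progeny.calls[i], seg))
        distortion_test(obs)
        rows.append((locus, seg, obs.chi2, obs.p_value,
                     obs.distorted_p01, obs.distorted_p001))
    return pd.DataFrame(rows, columns=[
        "locus_id", "seg_type", "chi2", "p_value",
        "distorted_p01", "distorted_p001"]).set_index("locus_id")


# ---------------------------------------------------------------------------
# two-point estimation


def _f1_recombination(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Direct-count r-hat for two 1:1 loci scored in the same parent.

    Progeny calls at a het x hom locus take two dosage states; each state
    tags the transmitted parental allele. Phase is unknown, so the minor
    mismatch fraction is taken (r <= 0.5 by construction).
    """
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    ga = (a == a.max()).astype(int)
    gb = (b == b.max()).astype(int)
    n = a.size
    k = int((ga != gb).sum())
    k = min(k, n - k)  # pick the phase with fewer recombinants
    return k / n, _backcross_lod(k, n), n


def _backcross_lod(k: int, n: int) -> float:
    r = max(k / n, 1e-12)
    if k == 0:
        return n * np.log10(2.0)
    return float(k * np.log10(2 * r) + (n - k) * np.log10(2 * (1 - r)))


_GAMETES = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (allele at A, allele at B)


def _f2_class_probs(r: float) -> np.ndarray:
    """9-class (dosage_a, dosage_b) probabilities for coupling-phase F2."""
    g = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
    probs = np.zeros((3, 3))
    for i, (a1, b1) in enumerate(_GAMETES):
        for j, (a2, b2) in enumerate(_GAMETES):
            probs[a1 + a2, b1 + b2] += g[i] * g[j]
    return probs


def _f2_em(counts: np.ndarray, r0: float = 0.25, tol: float = 1e-8,
           max_iter: int = 500) -> float:
    """EM for the F2 two-point recombination fraction.

    ``counts`` is the 3x3 table of progeny (dosage_a, dosage_b) classes in
    coupling phase. The double heterozygote (1,1) mixes parental x parental
    and recombinant x recombinant gamete pairs and is handled by the
    E-step; every other class determines its gamete pair up to order.
    """
    n = counts.sum()
    r = r0
    for _ in range(max_iter):
        g = np.array([(1 - r) / 2, r / 2, r / 2, (1 - r) / 2])
        exp_rec = 0.0
        for (i, j), c in np.ndenumerate(counts):
            if c == 0:
                continue
            num, den = 0.0, 0.0
            for ii, (a1, b1) in enumerate(_GAMETES):
                for jj, (a2, b2) in enumerate(_GAMETES):
                    if a1 + a2 == i and b1 + b2 == j:
                        p = g[ii] * g[jj]
                        den += p
                        num += p * ((a1 != b1) + (a2 != b2))
            exp_rec += c * num / den
        r_new = min(max(exp_rec / (2 * n), 1e-9), 0.5)
        if abs(r_new - r) < tol:
            return r_new
        r = r_new
    return r


def _f2_loglik(counts: np.ndarray, r: float) -> float:
    probs = np.clip(_f2_class_probs(r), 1e-300, None)
    return float((counts * np.log(probs)).sum())


def two_point(calls_a: np.ndarray, calls_b: np.ndarray, design: str,
              min_informative: int = 10) -> tuple[float, float]:
    """Two-point recombination fraction and LOD for a pair of loci.

    F1 pseudo-testcross: direct counting on jointly called progeny (both
    loci must segregate through the same parent for this estimate to be
    meaningful). F2 codominant: EM over the 3x3 dosage table with the
    coupling/repulsion phase resolved by likelihood; LOD compares r-hat to
    free recombination (r = 0.5).
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    ok = (a != MISSING) & (b != MISSING)
    if int(ok.sum()) < min_informative:
        raise ValueError(
            f"only {int(ok.sum())} jointly informative progeny "
            f"(< {min_informative})")
    if design == "F1_pseudo_testcross":
        r, lod, _ = _f1_recombination(a, b)
        return r, lod
    if design == "F2_self":
        counts = np.zeros((3, 3))
        for i, j in zip(a[ok], b[ok]):
            counts[i, j] += 1
        # try both phases: repulsion is coupling with one locus recoded
        best = None
        for tab in (counts, counts[:, ::-1]):
            r = _f2_em(tab)
            ll = _f2_loglik(tab, r)
            if best is None or ll > best[1]:
                best = (r, ll, tab)
        r, ll, tab = best
        lod = (ll - _f2_loglik(tab, 0.5)) / np.log(10)
        return float(r), float(lod)
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# map function


def kosambi_cm(r):
    """Kosambi map distance d = 25·ln((1+2r)/(1-2r)), in centimorgans."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_inverse_r(d_cm):
    """Inverse Kosambi: r = 0.5·tanh(d/50) for a map distance in cM."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    out = 0.5 * np.tanh(d / 50.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# co-segregation & map summaries


def cluster_cosegregating(progeny: GenotypeMatrix) -> list[list[str]]:
    """Group markers showing zero observed recombination.

    Two markers fall in the same bin when their jointly called progeny
    patterns are identical up to phase (allele relabelling). The relation
    is closed transitively (union-find), so bins are genuine equivalence
    classes even with missing data.
    """
    n = progeny.n_loci
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    calls = progeny.calls
    for i in range(n):
        for j in range(i + 1, n):
            ok = (calls[i] != MISSING) & (calls[j] != MISSING)
            if not ok.any():
                continue
            a, b = calls[i][ok], calls[j][ok]
            if np.array_equal(a, b) or np.array_equal(a, 2 - b):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    bins: dict[int, list[str]] = {}
    for i in range(n):
        bins.setdefault(find(i), []).append(str(progeny.locus_ids[i]))
    return list(bins.values())


def map_summary(map_table: pd.DataFrame,
                array_flag: str | None = "from_array") -> pd.DataFrame:
    """Per-linkage-group summary of a genetic map.

    ``map_table`` needs columns ``marker``, ``lg`` and ``position_cm``
    (and optionally a boolean *array_flag* column marking array-derived
    markers). Reports marker count, array-SNP count and percentage,
    coverage (max - min position), mean adjacent distance over all markers
    and over unique positions (the unique-position mean is the primary
    figure), unique-position count and the largest gap. A TOTAL row sums
    counts and coverage; its mean distances pool the per-group adjacent
    gaps.
    """
    req = {"marker", "lg", "position_cm"}
    if not req <= set(map_table.columns):
        raise ValueError(f"map table needs columns {sorted(req)}")
    rows = []
    all_gaps, all_gaps_unique = [], []
    for lg, grp in map_table.groupby("lg", sort=True):
        pos = np.sort(grp["position_cm"].to_numpy(dtype=float))
        unique_pos = np.unique(pos)
        coverage = float(pos.max() - pos.min()) if len(pos) else 0.0
        gaps = np.diff(pos)
        gaps_u = np.diff(unique_pos)
        all_gaps.extend(gaps)
        all_gaps_unique.extend(gaps_u)
        n_array = int(grp[array_flag].sum()) if array_flag in grp else 0
        rows.append({
            "lg": lg,
            "n_markers": len(grp),
            "n_array_snps": n_array,
            "array_pct": (round_half_up(100 * n_array / len(grp), 0)
                          if len(grp) else np.nan),
            "coverage_cm": coverage,
            "mean_distance_cm": float(gaps.mean()) if gaps.size else np.nan,
            "mean_distance_unique_cm": (float(gaps_u.mean())
                                        if gaps_u.size else np.nan),
            "n_unique_positions": len(unique_pos),
            "largest_gap_cm": float(gaps_u.max()) if gaps_u.size else 0.0,
        })
    out = pd.DataFrame(rows).set_index("lg")
    total_array = int(out["n_array_snps"].sum())
    total_markers = int(out["n_markers"].sum())
    total = {
        "n_markers": total_markers,
        "n_array_snps": total_array,
        "array_pct": (round_half_up(100 * total_array / total_markers, 0)
                      if total_markers else np.nan),
        "coverage_cm": float(out["coverage_cm"].sum()),
        "mean_distance_cm": (float(np.mean(all_gaps))
                             if all_gaps else np.nan),
        "mean_distance_unique_cm": (float(np.mean(all_gaps_unique))
                                    if all_gaps_unique else np.nan),
        "n_unique_positions": int(out["n_unique_positions"].sum()),
        "largest_gap_cm": (float(np.max(all_gaps_unique))
                           if all_gaps_unique else 0.0),
    }
    out.loc["TOTAL"] = total
    return out


def gap_fraction_below(map_table: pd.DataFrame, threshold_cm: float) -> float:
    """Fraction of adjacent unique-position gaps smaller than a threshold."""
    gaps = []
    for _, grp in map_table.groupby("lg"):
        pos = np.unique(grp["position_cm"].to_numpy(dtype=float))
        gaps.extend(np.diff(pos))
    if not gaps:
        raise ValueError("no gaps: need at least two positions in some LG")
    gaps = np.asarray(gaps)
    return float((gaps < threshold_cm).mean())


def greedy_seriation(distance: pd.DataFrame) -> list[str]:
    """Nearest-neighbour ordering of markers by two-point distance.

    Convenience only — not a multipoint ordering algorithm. Starts from
    the pair with the largest distance's endpoint and repeatedly appends
    the closest unplaced marker.
    """
    d = distance.to_numpy(dtype=float)
    ids = list(distance.index)
    if len(ids) < 2:
        return ids
    start = int(np.nanargmax(np.nansum(d, axis=1)))
    order = [start]
    remaining = set(range(len(ids))) - {start}
    while remaining:
        last = order[-1]
        nxt = min(remaining, key=lambda j: (d[last, j], ids[j]))
        order.append(nxt)
        remaining.discard(nxt)
    return [ids[i] for i in order]
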