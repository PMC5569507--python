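"""Descriptive and comparative statistics for small-RNA surveys.

Covers read size distributions and 24/21-nt ratios with a rank-sum
comparison, 5'-nucleotide composition with a chi-square test, per-family
consensus and nucleotide-variation summaries, and clustering of the
family-by-species expression matrix into conservation classes I-V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .preprocess import ReadSet

SIZE_RANGE = (16, 26)
EXACT_WILCOXON_MAX_N = 12
DETECTION_SPECIES_MIN = 15   # conserved when detected in more than 15 species
ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class SizeDistribution:
    library_id: str
    counts: dict[int, int]        # length -> read count
    proportions: dict[int, float]


def size_distribution(readset: ReadSet,
                      size_range: tuple[int, int] = SIZE_RANGE) -> SizeDistribution:
    """Read counts and proportions per length over the retained window."""
    if not readset.counts:
        raise ValueError("empty readset")
    lo, hi = size_range
    counts = {length: 0 for length in range(lo, hi + 1)}
    for seq, c in readset.counts.items():
        if lo <= len(seq) <= hi:
            counts[len(seq)] += c
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no reads within the size range")
    proportions = {length: c / total for length, c in counts.items()}
    return SizeDistribution(readset.library_id, counts, proportions)


def ratio_24_21(readset: ReadSet) -> float | None:
    """count(24 nt) / count(21 nt); None when no 21-nt reads exist."""
    c21 = sum(c for s, c in readset.counts.items() if len(s) == 21)
    c24 = sum(c for s, c in readset.counts.items() if len(s) == 24)
    if c21 == 0:
        return None
    return c24 / c21


def wilcoxon_rank_sum(group_a, group_b,
                      exact_max_n: int = EXACT_WILCOXON_MAX_N) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact by enumeration of all rank assignments when both groups have at
    most ``exact_max_n`` observations (two-sided via distance of the
    rank sum from its permutation mean, which matches the classical
    doubled tail when there are no ties); otherwise a normal
    approximation with tie and continuity corrections.
    """
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    pooled = a + b
    if len(set(pooled)) == 1:
        return 1.0
    n, m = len(a), len(b)
    ranks = rankdata(pooled)
    w_obs = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2.0
    if n <= exact_max_n and m <= exact_max_n:
        d_obs = abs(w_obs - mu)
        total = 0
        hits = 0
        for idx in combinations(range(n + m), n):
            total += 1
            w = sum(ranks[i] for i in idx)
            if abs(w - mu) >= d_obs - 1e-12:
                hits += 1
        return hits / total
    # normal approximation with tie correction
    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    sigma = math.sqrt(sigma2)
    if sigma == 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / sigma
    return float(2 * _norm.sf(max(z, 0.0)))


def five_prime_composition(sequences, counts=None) -> dict[str, float]:
    """Fractions of A/C/G/U at the first position.

    ``counts`` optionally weights each sequence (e.g. by read count);
    the default weights each sequence once, as for candidate lists.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    if counts is None:
        counts = [1] * len(seqs)
    tally = {nt: 0.0 for nt in "ACGU"}
    for seq, w in zip(seqs, counts):
        tally[seq[0]] += w
    total = sum(tally.values())
    return {nt: v / total for nt, v in tally.items()}


def chi2_composition_test(counts_a: tuple[int, int],
                          counts_b: tuple[int, int]) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table
    of (5' U, non-U) counts for two groups.  Returns (chi2, p)."""
    table = np.array([counts_a, counts_b], dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row <= 0).any() or (col <= 0).any():
        raise ValueError("all marginals must be >= 1")
    expected = np.outer(row, col) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(_chi2_dist.sf(stat, df=1))


@dataclass
class FamilyVariation:
    consensus: str
    variations: list[float]  # per member: substitutions + |length difference|
    mean: float
    sd: float


def consensus_and_variation(members: list[str]) -> FamilyVariation:
    """Majority consensus of a family's top isoforms and per-member
    nucleotide variation against it.

    Consensus length is the modal member length (shorter wins ties);
    each column takes the majority base among members long enough to
    cover it, alphabetical tie-break.  Variation per member counts
    substitutions over the 5'-anchored overlap plus the length
    difference.
    """
    if len(members) < 2:
        raise ValueError("need at least two member sequences")
    lengths = [len(s) for s in members]
    modal = max(sorted(set(lengths)), key=lambda L: (lengths.count(L), -L))
    cols = []
    for j in range(modal):
        tally: dict[str, int] = {}
        for s in members:
            if j < len(s):
                tally[s[j]] = tally.get(s[j], 0) + 1
        cols.append(max(sorted(tally), key=lambda c: tally[c]))
    consensus = "".join(cols)
    variations = []
    for s in members:
        overlap = min(len(s), modal)
        subs = sum(s[i] != consensus[i] for i in range(overlap))
        variations.append(float(subs + abs(len(s) - modal)))
    arr = np.array(variations)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return FamilyVariation(consensus=consensus, variations=variations,
                           mean=float(arr.mean()), sd=sd)


@dataclass
class FamilyExpressionMatrix:
    """Family-by-species expression with detection summaries."""

    rpm: pd.DataFrame            # raw RPM values, families x species
    log2: pd.DataFrame           # log2(RPM + 1)
    detection: pd.Series         # number of species with RPM > 0 per family
    mean_rpm: pd.Series


def build_family_matrix(per_species_rpm: dict[str, dict[str, float]]) -> FamilyExpressionMatrix:
    """``{species: {family: RPM}}`` -> expression matrix (absent = 0)."""
    df = pd.DataFrame(per_species_rpm).fillna(0.0)
    df = df.sort_index().sort_index(axis=1)
    return FamilyExpressionMatrix(
        rpm=df,
        log2=np.log2(df + 1.0),
        detection=(df > 0).sum(axis=1),
        mean_rpm=df.mean(axis=1),
    )


def classify_conservation(matrix: FamilyExpressionMatrix, top: int = 50,
                          k: int = 5,
                          detection_min: int = DETECTION_SPECIES_MIN) -> pd.DataFrame:
    """Cluster the top families by mean RPM into conservation classes.

    The top ``top`` families by mean RPM (over all species, zeros
    included) are hierarchically clustered (average linkage, Euclidean
    distance on row-scaled log2(RPM+1)) and the tree is cut into ``k``
    groups.  Groups are labeled I..k by descending (mean detection
    breadth, mean expression).  Families detected in more than
    ``detection_min`` species are flagged conserved.
    """
    order = matrix.mean_rpm.sort_values(ascending=False, kind="stable")
    chosen = sorted(order.index[:top])
    if len(chosen) < k:
        raise ValueError(f"need at least {k} families, have {len(chosen)}")
    X = matrix.log2.loc[chosen].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    labels = fcluster(linkage(pdist(Z, metric="euclidean"), method="average"),
                      t=k, criterion="maxclust")
    n_species = matrix.rpm.shape[1]
    detect_frac = matrix.detection.loc[chosen].to_numpy() / n_species
    mean_expr = matrix.log2.loc[chosen].mean(axis=1).to_numpy()
    group_key = {}
    for g in np.unique(labels):
        mask = labels == g
        group_key[g] = (float(detect_frac[mask].mean()),
                        float(mean_expr[mask].mean()))
    ordered_groups = sorted(group_key, key=lambda g: group_key[g], reverse=True)
    roman_of = {g: ROMAN[i] for i, g in enumerate(ordered_groups)}
    return pd.DataFrame({
        "family": chosen,
        "conservation_class": [roman_of[g] for g in labels],
        "n_species_detected": matrix.detection.loc[chosen].to_numpy(),
        "mean_rpm": matrix.mean_rpm.loc[chosen].to_numpy(),
        "conserved": matrix.detection.loc[chosen].to_numpy() > detection_min,
    }).set_index("family")
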