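"""Cross-species abundance matrices and sequence-divergence statistics.

Implements the two abundance layers used in comparative repeatome figures
(within-genome proportion and cross-species relative share), the Kimura
2-parameter distance with pairwise deletion, average-linkage ordering for
heatmaps, and Tajima's relative-rate test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class AlignedPair:
    """Pairwise-deleted site counts of an aligned sequence pair."""

    n: int                  # compared (gapless, unambiguous) columns
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.n

    @property
    def Q(self) -> float:
        return self.transversions / self.n


@dataclass(frozen=True)
class RRTResult:
    m1: int
    m2: int
    chi2: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class AbundanceMatrix:
    """Two abundance layers over a repeats x species table.

    within_genome   reads of repeat r in species s / total analyzed reads of s
    relative_share  reads of r in s / total reads clustered for r (rows sum 1)
    """

    counts: pd.DataFrame
    within_genome: pd.DataFrame
    relative_share: pd.DataFrame


def count_site_patterns(seq_a: str, seq_b: str) -> AlignedPair:
    """Transition/transversion counts over pairwise-deleted columns."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must come from the same alignment (equal length)")
    n = ts = tv = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    return AlignedPair(n, ts, tv)


def k2p_from_pq(P: float, Q: float) -> float:
    """Closed-form Kimura 2-parameter distance from observed proportions."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("substitution saturation: K2P distance undefined")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(seq_a: str, seq_b: str, min_sites: int = 20) -> float:
    """K2P distance over pairwise-deleted columns of an aligned pair."""
    pair = count_site_patterns(seq_a, seq_b)
    if pair.n < min_sites:
        raise ValueError(f"only {pair.n} comparable columns (< {min_sites})")
    return k2p_from_pq(pair.P, pair.Q)


def p_distance(seq_a: str, seq_b: str) -> float:
    pair = count_site_patterns(seq_a, seq_b)
    return (pair.transitions + pair.transversions) / pair.n


def distance_matrix(seqs: Mapping[str, str]) -> tuple[pd.DataFrame, list[str]]:
    """Symmetric K2P matrix plus an average-linkage leaf ordering for heatmaps."""
    names = list(seqs)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    k = len(names)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = k2p_distance(seqs[names[i]], seqs[names[j]])
    df = pd.DataFrame(mat, index=names, columns=names)
    if k == 2:
        return df, names
    order = [names[i] for i in leaves_list(average(squareform(mat, checks=False)))]
    return df, order


def tajima_rrt(seq1: str, seq2: str, outgroup: str, min_sites: int = 20) -> RRTResult:
    """Tajima's relative-rate test of two ingroup lineages against an outgroup.

    m1 counts alignment columns where only seq1 differs (seq2 equals the
    outgroup), m2 the symmetric count; chi2 = (m1-m2)^2/(m1+m2) on 1 df.
    """
    if not (len(seq1) == len(seq2) == len(outgroup)):
        raise ValueError("the three sequences must come from one alignment")
    m1 = m2 = n = 0
    for a, b, o in zip(seq1.upper(), seq2.upper(), outgroup.upper()):
        if a not in _VALID or b not in _VALID or o not in _VALID:
            continue
        n += 1
        if a != b:
            if b == o:
                m1 += 1
            elif a == o:
                m2 += 1
    if n < min_sites:
        raise ValueError(f"only {n} comparable columns (< {min_sites})")
    if m1 + m2 == 0:
        return RRTResult(0, 0, 0.0, 1.0)
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    return RRTResult(m1, m2, chi2, float(chi2_dist.sf(chi2, 1)))


def abundance_matrix(cluster_counts: pd.DataFrame | Sequence[tuple[str, Mapping[str, int]]],
                     totals: Mapping[str, int]) -> AbundanceMatrix:
    """Build the two abundance layers from annotated cluster counts.

    ``cluster_counts`` is either a DataFrame with a ``repeat`` column plus one
    column per species, or an iterable of (repeat_name, {species: count}).
    Clusters of the same repeat are aggregated before division.
    """
    if isinstance(cluster_counts, pd.DataFrame):
        df = cluster_counts.copy()
    else:
        rows = [{"repeat": name, **counts} for name, counts in cluster_counts]
        df = pd.DataFrame(rows)
    missing = [s for s in df.columns if s != "repeat" and s not in totals]
    if missing:
        raise ValueError(f"species missing from totals: {missing}")
    counts = df.groupby("repeat").sum().fillna(0.0)
    counts = counts[[s for s in totals if s in counts.columns]]
    for s in totals:
        if s not in counts.columns:
            counts[s] = 0.0
    within = counts.div(pd.Series(totals), axis=1)
    row_sums = counts.sum(axis=1)
    share = counts.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    return AbundanceMatrix(counts, within, share)
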