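"""Shared pairwise-alignment primitives.

Local alignment is done with Bio.Align.PairwiseAligner (exact dynamic
programming); fast approximate searches (semi-global hit finding, identity
screens) use edlib.  Significance of a hit is an approximate Karlin-Altschul
E-value computed from an effective +1/-2 match/penalty score, documented in
docs/methods.md as a ranking/threshold device rather than a calibrated
BLAST E-value.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Karlin-Altschul parameters for +1/-2 nucleotide scoring (blastn-like) and
# ungapped BLOSUM80; approximate, used for ranking and thresholding only.
_NT_LAMBDA, _NT_K = 1.28, 0.46
_AA_LAMBDA, _AA_K = 0.343, 0.177

CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _make_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


# Default scoring tuned so that extending through <~75% identity is
# unprofitable: the optimal local alignment then hugs the genuinely shared
# block instead of drifting into random flanks.
_DEFAULT_ALIGNER = _make_aligner(1.0, -3.0, -5.0, -2.0)
_LENIENT_ALIGNER = _make_aligner(1.0, -1.0, -4.0, -1.0)

_BLOSUM80 = substitution_matrices.load("BLOSUM80")
_AA_ALIGNER = Align.PairwiseAligner()
_AA_ALIGNER.mode = "local"
_AA_ALIGNER.substitution_matrix = _BLOSUM80
_AA_ALIGNER.open_gap_score = -10.0
_AA_ALIGNER.extend_gap_score = -1.0


@dataclass(frozen=True)
class LocalHit:
    """Best-scoring local alignment between a query and a target."""

    score: float
    identity: float          # matches / alignment columns (gaps = mismatch)
    columns: int             # alignment span including gap columns
    matches: int
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str = "+"

    @property
    def nt_score(self) -> int:
        """Effective +1/-2 score used for E-values."""
        return self.matches - 2 * (self.columns - self.matches)


_EMPTY_HIT = LocalHit(0.0, 0.0, 0, 0, (0, 0), (0, 0))


def best_local(query: str, target: str, lenient: bool = False) -> LocalHit:
    """Best local alignment of query vs target (forward strand only)."""
    if not query or not target:
        return _EMPTY_HIT
    aligner = _LENIENT_ALIGNER if lenient else _DEFAULT_ALIGNER
    score = aligner.score(query, target)
    if score <= 0:
        return _EMPTY_HIT
    aln = next(iter(aligner.align(query, target)))
    counts = aln.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    qblocks, tblocks = aln.aligned
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    identity = matches / columns if columns else 0.0
    return LocalHit(float(score), identity, columns, matches, (q0, q1), (t0, t1))


def best_local_both_strands(query: str, target: str, lenient: bool = False) -> LocalHit:
    """Best local alignment over both strands of the target.

    Intervals of a minus-strand hit refer to the forward target coordinates.
    """
    fwd = best_local(query, target, lenient=lenient)
    rev = best_local(query, revcomp(target), lenient=lenient)
    if rev.score > fwd.score:
        t0, t1 = rev.target_interval
        n = len(target)
        return LocalHit(rev.score, rev.identity, rev.columns, rev.matches,
                        rev.query_interval, (n - t1, n - t0), "-")
    return fwd


def protein_local(query: str, target: str) -> LocalHit:
    """Best local alignment of two peptides under BLOSUM80."""
    if not query or not target:
        return _EMPTY_HIT
    score = _AA_ALIGNER.score(query, target)
    if score <= 0:
        return _EMPTY_HIT
    aln = next(iter(_AA_ALIGNER.align(query, target)))
    counts = aln.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    qblocks, tblocks = aln.aligned
    q0, q1 = int(qblocks[0][0]), int(qblocks[-1][1])
    t0, t1 = int(tblocks[0][0]), int(tblocks[-1][1])
    identity = matches / columns if columns else 0.0
    return LocalHit(float(score), identity, columns, matches, (q0, q1), (t0, t1))


def evalue_nt(nt_score: float, m: int, n: int) -> float:
    """Karlin-Altschul E-value for a +1/-2-scored nucleotide hit."""
    if nt_score <= 0:
        return float("inf")
    return _NT_K * max(m, 1) * max(n, 1) * math.exp(-_NT_LAMBDA * nt_score)


def evalue_protein(score: float, m: int, n: int) -> float:
    if score <= 0:
        return float("inf")
    return _AA_K * max(m, 1) * max(n, 1) * math.exp(-_AA_LAMBDA * score)


def global_identity(a: str, b: str) -> float:
    """Identity of the end-to-end alignment of two sequences (edit-distance based)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass(frozen=True)
class SemiGlobalHit:
    """One occurrence of a query inside a target (edlib HW search)."""

    start: int
    end: int
    strand: str
    edit_distance: int
    identity: float
    evalue: float


def _iter_hw_hits(query: str, target: str, max_edits: int) -> Iterator[tuple[int, int, int]]:
    """Yield non-overlapping (start, end, edits) occurrences, best first.

    Iteratively masks each found interval so that further, weaker occurrences
    surface on the next pass.
    """
    masked = list(target)
    for _ in range(500):
        res = edlib.align(query, "".join(masked), mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            return
        start, end = res["locations"][0]
        end += 1  # edlib end is inclusive
        yield start, end, res["editDistance"]
        for i in range(start, end):
            masked[i] = "#"


def find_occurrences(query: str, target: str, max_e: float = 1e-4,
                     max_divergence: float = 0.45) -> list[SemiGlobalHit]:
    """All significant occurrences of ``query`` on either strand of ``target``.

    Occurrences are found with a semi-global edit-distance search, scored
    with the effective +1/-2 scheme and filtered at ``max_e``.  Overlapping
    hits are merged keeping the more significant one.
    """
    if not query or not target:
        return []
    qlen = len(query)
    max_edits = int(max_divergence * qlen)
    hits: list[SemiGlobalHit] = []
    n = len(target)
    for strand, tseq in (("+", target), ("-", revcomp(target))):
        for start, end, edits in _iter_hw_hits(query, tseq, max_edits):
            matches = max(qlen, end - start) - edits
            score = matches - 2 * edits
            ev = evalue_nt(score, qlen, n)
            if ev > max_e:
                continue
            if strand == "-":
                start, end = n - end, n - start
            identity = matches / max(qlen, end - start)
            hits.append(SemiGlobalHit(start, end, strand, edits, identity, ev))
    # merge overlaps, most significant first
    hits.sort(key=lambda h: (h.evalue, h.edit_distance, h.start))
    kept: list[SemiGlobalHit] = []
    for h in hits:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in CIGAR_RE.findall(cigar)]


# ---------------------------------------------------------------------------
# k-mer machinery

def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def minimizers(seq: str, k: int = 13, w: int = 8) -> set[str]:
    """Set of (k, w) canonical minimizers of a sequence."""
    n = len(seq)
    if n < k:
        return set()
    kmers = [canonical(seq[i:i + k]) for i in range(n - k + 1)]
    hashes = [hash(km) for km in kmers]
    out: set[str] = set()
    nwin = len(kmers) - w + 1
    if nwin <= 0:
        out.add(kmers[hashes.index(min(hashes))])
        return out
    for i in range(nwin):
        j = min(range(i, i + w), key=lambda x: hashes[x])
        out.add(kmers[j])
    return out


class UnionFind:
    """Disjoint-set forest with path compression."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True
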