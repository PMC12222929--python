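"""5S rDNA reconstruction and tandem-array classification on long reads.

The 5S rDNA of plants is organized in tandem monomers, each a ~120-bp gene
followed by a non-transcribed spacer (NTS).  This module reconstructs the
gene from short reads mapped against a seed gene, derives the complete
monomer from the inter-gene periodicity on long reads, scans long reads for
monomer occurrences at a significance threshold (E <= 1e-4 by default), and
classifies each read's array organization:

regular              >= 5 monomers, no major gap, read longer than 6000 bp
potentially_regular  periodic but unconfirmable (short read, or only 2-4
                     monomers)
pseudogenic          >= 2 monomers with at least one major gap (sequence
                     between them fell below the detection threshold)
sparse               a single monomer

A "major gap" is operationalized as consecutive monomer starts more than
1.5 periods apart (gap_frac = 0.5 of the monomer length), configurable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from typing import Mapping, Sequence

import numpy as np

from ._alignment import SemiGlobalHit, best_local_both_strands, find_occurrences, minimizers
from .consensus import _mafft, majority_consensus
from .prep import ReadSet

# canonical plant 5S internal-promoter elements, 0-based half-open intervals
# on the gene; defaults, not measured values — override per study.
DEFAULT_CONTROL_REGIONS = {"A_box": (49, 60), "IE": (66, 72), "C_box": (79, 97)}

MonomerHit = SemiGlobalHit


@dataclass(frozen=True)
class Monomer5S:
    """A complete 5S rDNA monomer: gene + NTS, with gene-internal control
    regions (A-box, intermediate element, C-box)."""

    gene: str
    nts: str
    control_regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_REGIONS))

    def __post_init__(self) -> None:
        for name, (s, e) in self.control_regions.items():
            if not (0 <= s < e <= len(self.gene)):
                raise ValueError(f"control region {name} outside the gene")

    @property
    def sequence(self) -> str:
        return self.gene + self.nts

    def __len__(self) -> int:
        return len(self.gene) + len(self.nts)


@dataclass(frozen=True)
class ClassifyParams:
    min_monomers: int = 5
    min_read_len: int = 6000
    # A "major gap" marks sequence fallen below the detection threshold (one
    # missed monomer adds >= 1 monomer length) or an inserted spacer; NTS
    # elongations by internal duplication stay below ~2/3 of a monomer, so
    # 0.75 separates length variants from pseudogenic interruptions.
    gap_frac: float = 0.75     # major gap: > gap_frac * monomer_length


@dataclass(frozen=True)
class ArrayCall:
    read_id: str
    read_length: int
    monomer_count: int
    gaps: tuple[int, ...]           # inter-monomer gaps (period - monomer length)
    nts_lengths: tuple[int, ...]    # per-interval NTS length estimates
    label: str


def derive_label(read_length: int, monomer_count: int, gaps: Sequence[int],
                 monomer_length: int, params: ClassifyParams = ClassifyParams()) -> str:
    """The classification rule, exposed so every call is re-derivable."""
    if monomer_count < 1:
        raise ValueError("no monomers: no call")
    if monomer_count == 1:
        return "sparse"
    gap_max = params.gap_frac * monomer_length
    if any(g > gap_max for g in gaps):
        return "pseudogenic"
    if monomer_count >= params.min_monomers and read_length > params.min_read_len:
        return "regular"
    return "potentially_regular"


def scan_monomers(read: str, monomer: Monomer5S | str, max_e: float = 1e-4) -> list[MonomerHit]:
    """Significant occurrences of the 5S gene on a long read, both strands.

    Overlapping hits are merged keeping the more significant, so tandem
    junction artifacts are not double-counted.
    """
    gene = monomer.gene if isinstance(monomer, Monomer5S) else monomer
    if not gene:
        raise ValueError("monomer gene is undefined")
    if not read:
        return []
    return find_occurrences(gene, read, max_e=max_e)


def classify_array(read_id: str, read: str, hits: Sequence[MonomerHit],
                   monomer_length: int,
                   params: ClassifyParams = ClassifyParams()) -> ArrayCall | None:
    """Classify one read's array organization from its monomer hit geometry.

    Gaps are distances between consecutive hit starts minus the monomer
    length.  Returns None for reads without hits (no call)."""
    if not hits:
        return None
    starts = sorted(h.start for h in hits)
    periods = [b - a for a, b in zip(starts, starts[1:])]
    gaps = tuple(p - monomer_length for p in periods)
    label = derive_label(len(read), len(hits), gaps, monomer_length, params)
    # NTS length estimate per interval: period minus the gene span
    spans = sorted((h.start, h.end) for h in hits)
    nts_lengths = tuple(b_start - a_end for (_, a_end), (b_start, _) in zip(spans, spans[1:]))
    return ArrayCall(read_id, len(read), len(hits), gaps, nts_lengths, label)


def classify_reads(reads: ReadSet, monomer: Monomer5S, max_e: float = 1e-4,
                   params: ClassifyParams = ClassifyParams()) -> tuple[list[ArrayCall], int]:
    """Scan and classify every read; returns (calls, no-call read count)."""
    calls, no_call = [], 0
    for r in reads:
        hits = scan_monomers(r.sequence, monomer, max_e=max_e)
        call = classify_array(r.id, r.sequence, hits, len(monomer), params)
        if call is None:
            no_call += 1
        else:
            calls.append(call)
    return calls, no_call


# ---------------------------------------------------------------------------
# reconstruction


def reconstruct_gene(short_reads: ReadSet, seed_gene: str,
                     min_identity: float = 0.75, min_span_frac: float = 0.5,
                     k: int = 11) -> tuple[str, float]:
    """Majority consensus of short reads mapped to a seed 5S gene.

    Identity is relaxed to 75% so diverged genes still recruit reads; the
    mapped read fraction doubles as a genome-abundance proxy.  With no
    mapped reads the seed is returned unchanged with fraction 0.
    """
    if not (80 <= len(seed_gene) <= 200):
        raise ValueError("seed gene should be 80-200 bp")
    seed_kmers = minimizers(seed_gene, k=k, w=1)
    counts = np.zeros((4, len(seed_gene)), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    mapped = 0
    for read in short_reads:
        if not (minimizers(read.sequence, k=k, w=1) & seed_kmers):
            continue
        hit = best_local_both_strands(read.sequence, seed_gene, lenient=True)
        if hit.identity < min_identity or hit.columns < min_span_frac * min(
                len(read.sequence), len(seed_gene)):
            continue
        mapped += 1
        q0, q1 = hit.query_interval
        t0, t1 = hit.target_interval
        seq = read.sequence
        if hit.strand == "-":
            # hit intervals refer to forward seed coordinates; orient the read
            from ._alignment import revcomp
            seq = revcomp(seq)
            q0, q1 = len(seq) - q1, len(seq) - q0
        span = min(q1 - q0, t1 - t0)
        for i in range(span):
            b = base_idx.get(seq[q0 + i])
            if b is not None:
                counts[b, t0 + i] += 1
    if mapped == 0:
        return seed_gene, 0.0
    consensus = "".join(
        "ACGT"[int(np.argmax(counts[:, j]))] if counts[:, j].sum() > 0 else seed_gene[j]
        for j in range(len(seed_gene)))
    return consensus, mapped / len(short_reads)


def build_monomer(long_reads: ReadSet, gene: str, max_e: float = 1e-4,
                  period_tolerance: float = 0.2,
                  control_regions: Mapping[str, tuple[int, int]] | None = None,
                  ) -> tuple[Monomer5S, int, int]:
    """Reconstruct the complete monomer from inter-gene periodicity.

    On reads carrying >= 2 gene hits, each gene-to-next-gene interval is a
    monomer candidate; candidates near the modal period are aligned and
    majority-called.  Returns (monomer, reads used, monomers extracted).
    """
    candidates: list[str] = []
    used_reads = 0
    for read in long_reads:
        hits = [h for h in scan_monomers(read.sequence, gene, max_e=max_e)]
        by_strand: dict[str, list[MonomerHit]] = {}
        for h in hits:
            by_strand.setdefault(h.strand, []).append(h)
        found = False
        for strand, shits in by_strand.items():
            if len(shits) < 2:
                continue
            shits.sort(key=lambda h: h.start)
            for a, b in zip(shits, shits[1:]):
                if strand == "-":
                    # the array runs right-to-left: the unit spans from this
                    # gene's monomer-space start (forward coord b.end) to the
                    # next gene's start (forward coord a.end)
                    from ._alignment import revcomp
                    seq = revcomp(read.sequence[a.end:b.end])
                else:
                    seq = read.sequence[a.start:b.start]
                if len(seq) > len(gene):
                    candidates.append(seq)
                    found = True
        if found:
            used_reads += 1
    if not candidates:
        raise ValueError("no regular periodicity: no read carries two detectable genes")
    lengths = [len(c) for c in candidates]
    modal = _modal_length(lengths)
    keep = [c for c in candidates if abs(len(c) - modal) <= period_tolerance * modal]
    if len(keep) < 2:
        raise ValueError("no regular periodicity: monomer candidates have no modal length")
    consensus = majority_consensus(_mafft(keep)) if len(set(keep)) > 1 else keep[0]
    glen = min(len(gene), len(consensus))
    monomer = Monomer5S(consensus[:glen], consensus[glen:],
                        dict(control_regions) if control_regions else {
                            n: (s, e) for n, (s, e) in DEFAULT_CONTROL_REGIONS.items()
                            if e <= glen})
    return monomer, used_reads, len(keep)


def _modal_length(lengths: Sequence[int], bin_width: int = 20) -> int:
    binned = Counter(round(x / bin_width) for x in lengths)
    top_bin = max(binned, key=lambda b: (binned[b], -b))
    members = [x for x in lengths if round(x / bin_width) == top_bin]
    return int(np.median(members))


# ---------------------------------------------------------------------------
# variant reporting and divergence


@dataclass(frozen=True)
class NtsVariant:
    read_id: str
    interval_index: int
    nts_length: int
    kind: str                 # "elongated" | "shortened"
    internal_repetition: bool | None


def nts_variants(calls: Sequence[ArrayCall], reads: ReadSet | None = None,
                 monomer: Monomer5S | str | None = None,
                 dev_frac: float = 0.2, word: int = 10, max_e: float = 1e-4) -> list[NtsVariant]:
    """Flag NTS length variants across regular / potentially regular calls.

    Periods deviating more than ``dev_frac`` from the modal period are
    flagged elongated or shortened.  When ``reads`` and ``monomer`` are
    supplied, elongated spacers are extracted from the read and checked for
    internal repetition (word-match diagonals, word size 10) — the dotplot
    signature of a tandem-duplicated NTS segment.
    """
    eligible = [c for c in calls if c.label in ("regular", "potentially_regular")]
    if not eligible:
        raise ValueError("no regular or potentially regular calls")
    all_nts = [n for c in eligible for n in c.nts_lengths]
    if not all_nts:
        return []
    modal = _modal_length(all_nts)
    by_id = reads.by_id() if reads is not None else {}
    variants: list[NtsVariant] = []
    for call in eligible:
        spacer_intervals: list[tuple[int, int]] | None = None
        for idx, nts_len in enumerate(call.nts_lengths):
            if abs(nts_len - modal) <= dev_frac * modal:
                continue
            kind = "elongated" if nts_len > modal else "shortened"
            repetition: bool | None = None
            if kind == "elongated" and call.read_id in by_id and monomer is not None:
                read = by_id[call.read_id].sequence
                if spacer_intervals is None:
                    hits = scan_monomers(read, monomer, max_e=max_e)
                    spans = sorted((h.start, h.end) for h in hits)
                    spacer_intervals = [(a_end, b_start)
                                        for (_, a_end), (b_start, _) in zip(spans, spans[1:])]
                if idx < len(spacer_intervals):
                    s, e = spacer_intervals[idx]
                    repetition = has_internal_repetition(read[s:e], word=word)
            variants.append(NtsVariant(call.read_id, idx, nts_len, kind, repetition))
    return variants


def has_internal_repetition(spacer: str, word: int = 10, min_run: int = 3) -> bool:
    """True when a spacer shows off-diagonal word-match runs (tandem
    self-similarity), the dotplot signature of an internally duplicated NTS."""
    n = len(spacer)
    if n < 2 * word:
        return False
    positions: dict[str, list[int]] = {}
    for i in range(n - word + 1):
        positions.setdefault(spacer[i:i + word], []).append(i)
    diagonals: Counter = Counter()
    for pos in positions.values():
        for i in pos:
            for j in pos:
                if j > i:
                    diagonals[j - i] += 1
    return any(count >= min_run for off, count in diagonals.items() if off >= word)


def region_divergence(aligned: Sequence[str], regions: Mapping[str, tuple[int, int]],
                      ref_index: int = 0) -> dict[str, float]:
    """Per-region proportion of variable alignment columns.

    ``regions`` are intervals in the coordinates of the (ungapped) reference
    row; all remaining reference positions form the "remainder" entry.
    """
    ref = aligned[ref_index]
    col_of: dict[int, int] = {}
    rpos = 0
    for col, c in enumerate(ref):
        if c != "-":
            col_of[rpos] = col
            rpos += 1
    out: dict[str, float] = {}
    covered: set[int] = set()
    for name, (s, e) in regions.items():
        cols = [col_of[p] for p in range(s, e) if p in col_of]
        covered.update(range(s, e))
        out[name] = _variable_fraction(aligned, cols)
    rest = [col_of[p] for p in range(rpos) if p not in covered]
    out["remainder"] = _variable_fraction(aligned, rest)
    return out


def _variable_fraction(aligned: Sequence[str], cols: Sequence[int]) -> float:
    if not cols:
        return float("nan")
    variable = 0
    for col in cols:
        bases = {s[col] for s in aligned if s[col] in "ACGT"}
        if len(bases) > 1:
            variable += 1
    return variable / len(cols)


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("no unambiguous bases")
    return gc / denom


def monomer_read_share(n_monomer_reads: int, total_reads: int) -> dict[str, float | str]:
    """Percentage of long reads bearing at least one monomer, as printed in a
    report: exact value, 4 significant digits, and the 3-decimal
    round-half-even form."""
    pct = 100.0 * n_monomer_reads / total_reads
    rounded = Decimal(repr(pct)).quantize(Decimal("0.001"), rounding=ROUND_HALF_EVEN)
    return {
        "percent": pct,
        "percent_4sig": float(f"{pct:.4g}"),
        "percent_rounded": float(rounded),
    }
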