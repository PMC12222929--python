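"""Reference repeat reconstruction from long reads.

A cluster contig seeds a search of the long-read pool; the 20 best-matching
reads are mined for full or fragmented element copies by extending each hit
to the element boundaries (cross-read alignment takes the role of the
dotplot inspection used in manual reconstruction); the copies are aligned
and majority-called into a consensus, which is then polished by iterative
short-read mapping.  Terminal repeats and protein domains (translated
search, BLOSUM80) annotate the result.

Long-read searching and copy-boundary detection run on minimap2; the E-value
layer ranking its hits is computed here (approximate Karlin-Altschul on an
effective +1/-2 score), since hit ranking by significance is part of the
reconstruction contract while the aligner itself is interchangeable.
"""

from __future__ import annotations

import logging
import math
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

from ._alignment import best_local, evalue_nt, evalue_protein, parse_cigar, protein_local, revcomp
from .prep import ReadSet

logger = logging.getLogger(__name__)

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class LongReadHit:
    read_id: str
    query: str                    # name of the searched contig
    score: int
    evalue: float
    interval: tuple[int, int]     # on the read, forward coordinates
    strand: str


@dataclass(frozen=True)
class ElementCopy:
    read_id: str
    sequence: str                 # oriented to match the anchor copy
    interval: tuple[int, int]
    strand: str
    full: bool


@dataclass(frozen=True)
class DomainHit:
    name: str
    frame: int                    # 1..3 forward, -1..-3 reverse
    start: int
    end: int
    score: float
    evalue: float

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass
class RepeatConsensus:
    name: str
    sequence: str
    repeat_class: str = "unclassified"
    terminal_repeats: tuple[tuple[int, int], tuple[int, int]] | None = None
    terminal_repeat_kind: str | None = None     # "LTR" | "TIR" | None
    domains: list[DomainHit] = field(default_factory=list)
    source_copy_count: int = 0


# ---------------------------------------------------------------------------
# minimap2 plumbing


@dataclass(frozen=True)
class _Paf:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    blocklen: int


def _minimap2(target: Mapping[str, str], queries: Mapping[str, str],
              preset: str = "map-ont") -> list[_Paf]:
    with tempfile.TemporaryDirectory() as tmp:
        tpath, qpath = Path(tmp, "t.fa"), Path(tmp, "q.fa")
        for path, seqs in ((tpath, target), (qpath, queries)):
            with open(path, "w") as fh:
                for name, seq in seqs.items():
                    fh.write(f">{name}\n{seq}\n")
        proc = subprocess.run(
            ["minimap2", "-x", preset, "-c", "--secondary=no", "-p", "0.3",
             str(tpath), str(qpath)],
            capture_output=True, text=True, check=True)
    records = []
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        records.append(_Paf(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                            f[5], int(f[6]), int(f[7]), int(f[8]),
                            int(f[9]), int(f[10])))
    return records


# ---------------------------------------------------------------------------


def search_long_reads(contig: str, long_reads: ReadSet, top: int = 20,
                      max_e: float = 1e-5, contig_name: str = "contig") -> list[LongReadHit]:
    """The ``top`` best-matching long reads for a contig, ranked by ascending
    significance then descending score; ties broken by read id."""
    if len(contig) < 100:
        raise ValueError("search contig must be >= 100 bp")
    total = sum(len(r.sequence) for r in long_reads)
    # reads are the queries so that every read gets its own primary alignment
    paf = _minimap2({contig_name: contig}, {r.id: r.sequence for r in long_reads})
    best: dict[str, LongReadHit] = {}
    for rec in paf:
        score = rec.matches - 2 * (rec.blocklen - rec.matches)
        ev = evalue_nt(score, len(contig), total)
        if ev > max_e:
            continue
        hit = LongReadHit(rec.qname, contig_name, score, ev,
                          (rec.qstart, rec.qend), rec.strand)
        old = best.get(rec.qname)
        if old is None or (hit.evalue, -hit.score) < (old.evalue, -old.score):
            best[rec.qname] = hit
    ranked = sorted(best.values(), key=lambda h: (h.evalue, -h.score, h.read_id))
    return ranked[:top]


def detect_copies(hits: Sequence[LongReadHit], long_reads: ReadSet, contig: str,
                  extend: int = 15_000, join_gap: int = 500,
                  full_frac: float = 0.9) -> list[ElementCopy]:
    """Extend each hit to the element boundaries and emit one copy per read.

    Boundaries come from aligning every hit read's neighbourhood against the
    longest-hit ("anchor") neighbourhood: because element flanks differ
    between genomic copies, alignments end at the element boundaries.  A copy
    shorter than ``full_frac`` of the modal length is flagged fragmented.
    With a single hit no cross-read structure exists and the hit interval is
    returned unchanged.
    """
    if not hits:
        raise ValueError("no long-read hits: reconstruction aborted")
    by_id = long_reads.by_id()
    segments: dict[str, tuple[int, str]] = {}
    for h in hits:
        read = by_id[h.read_id].sequence
        s = max(0, h.interval[0] - extend)
        e = min(len(read), h.interval[1] + extend)
        segments[h.read_id] = (s, read[s:e])

    if len(hits) == 1:
        h = hits[0]
        read = by_id[h.read_id].sequence
        seq = read[h.interval[0]:h.interval[1]]
        if h.strand == "-":
            seq = revcomp(seq)
        return [ElementCopy(h.read_id, seq, h.interval, h.strand, True)]

    anchor = max(hits, key=lambda h: (h.interval[1] - h.interval[0], h.read_id))
    a_off, a_seg = segments[anchor.read_id]
    paf = _minimap2({"anchor": a_seg},
                    {h.read_id: segments[h.read_id][1] for h in hits
                     if h.read_id != anchor.read_id})

    def merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
        merged: list[list[int]] = []
        for s, e in sorted(intervals):
            if merged and s - merged[-1][1] <= join_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]

    copies: list[ElementCopy] = []
    anchor_t: list[tuple[int, int]] = []
    per_read: dict[str, list[_Paf]] = {}
    for rec in paf:
        per_read.setdefault(rec.qname, []).append(rec)
        anchor_t.append((rec.tstart, rec.tend))

    for h in hits:
        if h.read_id == anchor.read_id:
            continue
        recs = per_read.get(h.read_id)
        off, seg = segments[h.read_id]
        hit_iv = (h.interval[0] - off, h.interval[1] - off)
        if not recs:
            seq = seg[hit_iv[0]:hit_iv[1]]
            strand = h.strand
            if strand == "-":
                seq = revcomp(seq)
            copies.append(ElementCopy(h.read_id, seq, h.interval, strand, False))
            continue
        merged = merge([(r.qstart, r.qend) for r in recs])
        # keep the merged block overlapping the original hit
        block = max(merged, key=lambda iv: max(0, min(iv[1], hit_iv[1]) - max(iv[0], hit_iv[0])))
        minus = sum(r.qend - r.qstart for r in recs if r.strand == "-")
        plus = sum(r.qend - r.qstart for r in recs if r.strand == "+")
        strand = "-" if minus > plus else "+"
        seq = seg[block[0]:block[1]]
        if strand == "-":
            seq = revcomp(seq)
        copies.append(ElementCopy(h.read_id, seq, (off + block[0], off + block[1]), strand, False))

    if anchor_t:
        merged = merge(anchor_t)
        block = max(merged, key=lambda iv: iv[1] - iv[0])
    else:
        block = (anchor.interval[0] - a_off, anchor.interval[1] - a_off)
    copies.append(ElementCopy(anchor.read_id, a_seg[block[0]:block[1]],
                              (a_off + block[0], a_off + block[1]), anchor.strand, False))

    modal = float(np.median([len(c.sequence) for c in copies]))
    return [ElementCopy(c.read_id, c.sequence, c.interval, c.strand,
                        len(c.sequence) >= full_frac * modal)
            for c in copies]


# ---------------------------------------------------------------------------
# multiple alignment and consensus


def _mafft(seqs: Sequence[str]) -> list[str]:
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp, "in.fa")
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        proc = subprocess.run(["mafft", "--auto", "--quiet", str(path)],
                              capture_output=True, text=True, check=True)
    aligned: list[str] = []
    for chunk in proc.stdout.split(">")[1:]:
        lines = chunk.splitlines()
        aligned.append("".join(lines[1:]).upper())
    return aligned


def majority_consensus(aligned: Sequence[str]) -> str:
    """Per-column majority base; gap-majority columns removed; ties resolved
    to the IUPAC code of the tied bases."""
    ncol = len(aligned[0])
    out = []
    for j in range(ncol):
        col = [s[j] for s in aligned]
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        gap = counts.pop("-", 0)
        if not counts or gap > len(col) / 2:
            continue
        top = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == top and b in "ACGT")
        out.append(IUPAC.get(tied, max(sorted(counts), key=lambda b: counts[b])))
    return "".join(out)


def msa_consensus(copies: Sequence[str | ElementCopy], min_copies: int = 2) -> str:
    """Progressive-MSA majority consensus of element copies (mafft-backed)."""
    seqs = [c.sequence if isinstance(c, ElementCopy) else c for c in copies]
    if len(seqs) < min_copies:
        raise ValueError(f"need >= {min_copies} copies, got {len(seqs)}")
    if len(seqs) < 10:
        warnings.warn(f"consensus from only {len(seqs)} copies")
    if len(set(seqs)) == 1:
        return seqs[0]
    return majority_consensus(_mafft(seqs))


# ---------------------------------------------------------------------------
# short-read polishing


def map_refine(consensus: str, short_reads: ReadSet, rounds: int = 3,
               min_depth: int = 3, k: int = 13) -> str:
    """Polish a consensus by iterative short-read mapping and majority calls.

    Reads are placed by a shared-k-mer anchor and aligned semi-globally; a
    position is rewritten (substitution, deletion, or single insertion) only
    when covered by at least ``min_depth`` reads whose majority disagrees
    with the current base.  Stops early once a round changes nothing.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    for _ in range(rounds):
        new = _refine_round(consensus, short_reads, min_depth, k)
        if new == consensus:
            break
        consensus = new
    return consensus


def _refine_round(consensus: str, short_reads: ReadSet, min_depth: int, k: int) -> str:
    L = len(consensus)
    index: dict[str, int] = {}
    for pos in range(0, L - k + 1):
        index.setdefault(consensus[pos:pos + k], pos)
    base_idx = {b: i for i, b in enumerate("ACGT-")}
    counts = np.zeros((5, L), dtype=np.int32)
    inserts: dict[int, dict[str, int]] = {}

    for read in short_reads:
        for seq in (read.sequence, revcomp(read.sequence)):
            anchor = next(((index[seq[p:p + k]], p) for p in range(0, len(seq) - k + 1, 5)
                           if seq[p:p + k] in index), None)
            if anchor is None:
                continue
            cpos, rpos = anchor
            off = cpos - rpos
            w0 = max(0, off - 20)
            w1 = min(L, off + len(seq) + 20)
            window = consensus[w0:w1]
            res = edlib.align(seq, window, mode="HW", task="path",
                              k=max(5, int(0.35 * len(seq))))
            if res["editDistance"] < 0:
                continue
            t = w0 + res["locations"][0][0]
            q = 0
            for n, op in parse_cigar(res["cigar"]):
                if op in "=XM":
                    for i in range(n):
                        counts[base_idx.get(seq[q + i], 4), t + i] += 1
                    t += n
                    q += n
                elif op == "D":   # in target, absent from read
                    counts[4, t:t + n] += 1
                    t += n
                elif op == "I":   # in read, absent from target
                    if n == 1 and 0 < t < L:
                        ins = inserts.setdefault(t, {})
                        ins[seq[q]] = ins.get(seq[q], 0) + 1
                    q += n
            break  # one orientation is enough

    depth = counts.sum(axis=0)
    out: list[str] = []
    for pos in range(L):
        here = consensus[pos]
        if depth[pos] >= min_depth:
            best = int(np.argmax(counts[:, pos]))
            call = "ACGT-"[best]
            if call != "-":
                out.append(call)
            # deletion: drop the base
        else:
            out.append(here)
        nxt = inserts.get(pos + 1)
        if nxt:
            base, cnt = max(nxt.items(), key=lambda kv: kv[1])
            if cnt >= min_depth and cnt > depth[pos] / 2:
                out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# annotation


def _frames(seq: str) -> list[tuple[int, str]]:
    """Six reading frames as (frame, peptide); frame in {1,2,3,-1,-2,-3}."""
    out = []
    for sign, s in ((1, seq), (-1, revcomp(seq))):
        for off in range(3):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            out.append((sign * (off + 1), str(Seq(sub).translate())))
    return out


def annotate_domains(consensus: str, domain_db: Mapping[str, str],
                     max_e: float = 1e-5, max_overlap: int = 30) -> list[DomainHit]:
    """Ordered, collinearly chained protein-domain hits on a consensus.

    Six-frame translated local alignment (BLOSUM80) against the supplied
    domain proteins; hits above threshold are chained left-to-right without
    overlap, strongest first.
    """
    if not domain_db:
        raise ValueError("domain database must be non-empty")
    L = len(consensus)
    hits: list[DomainHit] = []
    for frame, pep in _frames(consensus):
        off = abs(frame) - 1
        for key in sorted(domain_db):
            hit = protein_local(domain_db[key], pep)
            if hit.score <= 0:
                continue
            ev = evalue_protein(hit.score, L // 3, len(domain_db[key]))
            if ev > max_e:
                continue
            p0, p1 = hit.target_interval
            if frame > 0:
                nt0, nt1 = off + 3 * p0, off + 3 * p1
            else:
                nt0, nt1 = L - (off + 3 * p1), L - (off + 3 * p0)
            name = key.partition("#")[0]
            hits.append(DomainHit(name, frame, nt0, nt1, hit.score, ev))
    hits.sort(key=lambda h: (-h.score, h.evalue, h.start, h.name))
    chained: list[DomainHit] = []
    for h in hits:
        # same-domain hits may not overlap at all: frameshifted translations
        # of a CDS echo weakly in adjacent frames and would duplicate the hit
        overlap = any(
            min(h.end, c.end) - max(h.start, c.start)
            > (0 if c.name == h.name else max_overlap)
            for c in chained)
        if not overlap:
            chained.append(h)
    chained.sort(key=lambda h: h.start)
    return chained


def detect_terminal_repeats(consensus: str, min_ltr: int = 100,
                            ltr_identity: float = 0.80, min_tir: int = 12,
                            end_slack: int = 20,
                            ) -> tuple[str, tuple[int, int], tuple[int, int]] | None:
    """Direct terminal repeats >= ``min_ltr`` bp at >= 80% identity -> LTR
    pair; terminal inverted repeats >= ``min_tir`` bp anchored at the ends ->
    TIR pair; neither -> None (truncated element)."""
    L = len(consensus)
    if L < 400:
        raise ValueError("consensus too short for terminal-repeat detection (>= 400 bp)")
    w = min(int(0.45 * L), L // 2)
    head, tail = consensus[:w], consensus[-w:]
    hit = best_local(head, tail, lenient=True)
    if hit.columns >= min_ltr and hit.identity >= ltr_identity:
        q0, q1 = hit.query_interval
        t0, t1 = hit.target_interval
        return ("LTR", (q0, q1), (L - w + t0, L - w + t1))
    head2 = consensus[: min_tir + end_slack + 30]
    tail2 = revcomp(consensus[-(min_tir + end_slack + 30):])
    hit = best_local(head2, tail2)
    if hit.columns >= min_tir and hit.identity >= 0.9 \
            and hit.query_interval[0] <= end_slack and hit.target_interval[0] <= end_slack:
        q0, q1 = hit.query_interval
        t0, t1 = hit.target_interval
        # tail2 is the reverse complement of the suffix: position t maps to L-1-t
        return ("TIR", (q0, q1), (L - t1, L - t0))
    return None


def annotate_35s(consensus: str, rrna_refs: Mapping[str, str],
                 max_divergence: float = 0.30) -> dict:
    """Locate the 18S, 5.8S and 26S genes on a 35S rDNA consensus and label
    the spacers between (ITS1/ITS2) and around (IGS) them.

    The gene order 18S < 5.8S < 26S is enforced; if the forward orientation
    does not satisfy it the reverse complement is annotated instead
    (``strand`` records which orientation the coordinates refer to).
    """
    if not rrna_refs:
        raise ValueError("rRNA reference sequences are required")
    order = [g for g in ("18S", "5.8S", "26S") if g in rrna_refs]

    def locate(seq: str) -> dict[str, tuple[int, int]]:
        found = {}
        for gene in order:
            ref = rrna_refs[gene]
            res = edlib.align(ref, seq, mode="HW", task="locations",
                              k=int(max_divergence * len(ref)))
            if res["editDistance"] >= 0:
                s, e = res["locations"][0]
                found[gene] = (s, e + 1)
        return found

    result: dict = {"strand": "+", "features": [], "warnings": []}
    found = locate(consensus)
    starts = [found[g][0] for g in order if g in found]
    if starts != sorted(starts) or len(found) < len(order):
        flipped = locate(revcomp(consensus))
        fstarts = [flipped[g][0] for g in order if g in flipped]
        if len(flipped) > len(found) or (fstarts == sorted(fstarts) and starts != sorted(starts)):
            found, result["strand"] = flipped, "-"

    for gene in order:
        if gene not in found:
            result["warnings"].append(f"{gene} not located")
    present = [(g, *found[g]) for g in order if g in found]
    features = list(present)
    if len(present) >= 2:
        spacer_names = iter(["ITS1", "ITS2"])
        for (g1, _, e1), (g2, s2, _) in zip(present, present[1:]):
            if s2 > e1:
                features.append((next(spacer_names, "ITS"), e1, s2))
    L = len(consensus)
    if present:
        first_s, last_e = present[0][1], present[-1][2]
        # upstream of 18S is the 5' external transcribed spacer
        if first_s > 0:
            features.append(("ETS5" if present[0][0] == "18S" else "IGS", 0, first_s))
        if last_e < L:
            features.append(("IGS", last_e, L))
    result["features"] = sorted(features, key=lambda f: f[1])
    if result["warnings"]:
        warnings.warn("; ".join(result["warnings"]))
    return result


# ---------------------------------------------------------------------------
# end-to-end driver


def reconstruct(contig: str, long_reads: ReadSet, short_reads: ReadSet | None = None,
                domain_db: Mapping[str, str] | None = None, name: str = "repeat",
                top: int = 20, min_copies: int = 2) -> RepeatConsensus:
    """contig -> long-read search -> copy detection -> consensus -> polish."""
    hits = search_long_reads(contig, long_reads, top=top, contig_name=name)
    if not hits:
        raise ValueError(f"{name}: no long-read hit above threshold; reconstruction aborted")
    copies = detect_copies(hits, long_reads, contig)
    seq = msa_consensus(copies, min_copies=min_copies)
    if short_reads is not None:
        seq = map_refine(seq, short_reads)
    result = RepeatConsensus(name=name, sequence=seq, source_copy_count=len(copies))
    if len(seq) >= 400:
        tr = detect_terminal_repeats(seq)
        if tr:
            result.terminal_repeat_kind = tr[0]
            result.terminal_repeats = (tr[1], tr[2])
            result.repeat_class = "LTR_RT" if tr[0] == "LTR" else "TIR_DNA_TE"
    if domain_db:
        result.domains = annotate_domains(seq, domain_db)
    return result
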