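"""Synthetic genomes with planted repeat families, and read simulation.

The generator emulates the data a clustering-based repeatome study operates
on: a background genome of configurable GC content into which LTR
retrotransposons (identical terminal repeats, PBS/PPT, GAG-PR-RT-RH-INT
domain order), TIR DNA transposons, satellite arrays, a 35S rDNA unit and
5S rDNA tandem arrays (regular, long-spacer, pseudogenized) are planted as
independently diverged copies.  Every planted base is recorded in a
ground-truth manifest so downstream estimates can be scored against the
truth.

Coordinates are 0-based half-open; strands are "+"/"-"; all randomness flows
from explicit seeds.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from ._alignment import revcomp
from .prep import Read, ReadSet

RepeatClass = Literal["LTR_RT", "TIR_DNA_TE", "satellite", "rDNA_35S", "rDNA_5S", "unclassified"]
ArrayMode = Literal["regular", "long_nts", "pseudogenic"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

# standard codons used when reverse-translating planted domain peptides
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_AA = "ARNDCQEGHILKMFPSTWYV"


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def random_seq(n: int, rng: np.random.Generator, gc: float = 0.38) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def random_peptide(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def reverse_translate(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide)


def mutate(seq: str, divergence: float, rng: np.random.Generator,
           ts_tv: float = 2.0) -> str:
    """Substitute a ``divergence`` fraction of sites, transitions:transversions
    at ``ts_tv`` (so K2P-style structure is present in planted divergence)."""
    if divergence <= 0:
        return seq
    codes = encode(seq).copy()
    n = len(codes)
    sites = np.flatnonzero(rng.random(n) < divergence)
    if sites.size == 0:
        return seq
    u = rng.random(sites.size)
    p_ts = ts_tv / (ts_tv + 1.0)
    is_ts = u < p_ts
    # ACGT coded 0..3: transition partner is (i+2)%4 (A<->G, C<->T)
    offsets = np.where(is_ts, 2, np.where(rng.random(sites.size) < 0.5, 1, 3))
    codes[sites] = (codes[sites] + offsets) % 4
    return decode(codes)


def apply_indel_errors(seq: str, error_rate: float, rng: np.random.Generator,
                       sub_frac: float = 0.5, ins_frac: float = 0.25) -> str:
    """Apply a long-read style error model: mixed substitutions and indels."""
    if error_rate <= 0:
        return seq
    codes = encode(seq)
    n = len(codes)
    err = rng.random(n) < error_rate
    kind = rng.random(n)
    subs = err & (kind < sub_frac)
    ins = err & (kind >= sub_frac) & (kind < sub_frac + ins_frac)
    dels = err & (kind >= sub_frac + ins_frac)
    out = codes.copy()
    sub_sites = np.flatnonzero(subs)
    out[sub_sites] = (out[sub_sites] + rng.integers(1, 4, sub_sites.size)) % 4
    keep = ~dels
    pieces = []
    last = 0
    ins_sites = np.flatnonzero(ins)
    for pos in ins_sites:
        pieces.append(out[last:pos + 1][keep[last:pos + 1]])
        pieces.append(rng.integers(0, 4, 1).astype(np.uint8))
        last = pos + 1
    pieces.append(out[last:][keep[last:]])
    return decode(np.concatenate(pieces))


# ---------------------------------------------------------------------------
# repeat templates


@dataclass(frozen=True)
class RepeatTemplate:
    """A repeat family's reference sequence with annotated features.

    ``features`` are (name, start, end) intervals in 0-based half-open
    coordinates on ``sequence``.  For LTR retrotransposons the 5' and 3'
    terminal repeats are identical at generation time.  ``domain_proteins``
    holds the planted domain peptides (the translated-search database for
    annotation).
    """

    name: str
    repeat_class: RepeatClass
    sequence: str
    features: tuple[tuple[str, int, int], ...] = ()
    domain_proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for fname, s, e in self.features:
            if not (0 <= s < e <= n):
                raise ValueError(f"feature {fname} [{s},{e}) outside sequence of length {n}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> tuple[int, int]:
        for fname, s, e in self.features:
            if fname == name:
                return s, e
        raise KeyError(name)


# domain peptide lengths as fractions of the internal coding budget
_LTR_DOMAINS = (("GAG", 0.22), ("PR", 0.10), ("RT", 0.30), ("RH", 0.16), ("INT", 0.22))
_PBS_LEN, _PPT_LEN = 18, 15


def build_ltr_element(internal_length: int, ltr_length: int, seed: int,
                      name: str = "LTR_element", with_cd: bool = False,
                      gc: float = 0.38) -> RepeatTemplate:
    """An LTR retrotransposon template: LTR5 == LTR3, PBS just downstream of
    LTR5, PPT just upstream of LTR3, internal domains in GAG-PR-RT-RH-INT
    order (chromovirus-style CD after INT when requested)."""
    if ltr_length < 100:
        raise ValueError("ltr_length too small: the terminal repeat needs >= 100 bp")
    rng = np.random.default_rng(seed)
    domains = list(_LTR_DOMAINS) + ([("CD", 0.08)] if with_cd else [])
    # leave ~15% of the internal region non-coding (UTRs / linkers)
    coding_budget = internal_length - _PBS_LEN - _PPT_LEN
    aa_total = int(coding_budget * 0.85) // 3
    min_aa = 30 * len(domains)
    if aa_total < min_aa:
        raise ValueError(
            f"internal_length too small: the domain set needs >= "
            f"{(min_aa * 3 + _PBS_LEN + _PPT_LEN) * 100 // 85} bp (limiting feature: RT)")
    total_frac = sum(f for _, f in domains)
    ltr = random_seq(ltr_length, rng, gc)
    pbs = random_seq(_PBS_LEN, rng, gc)
    ppt = "".join(rng.choice(["A", "G"], size=_PPT_LEN, p=[0.4, 0.6]))

    parts = [ltr, pbs]
    features = [("LTR5", 0, ltr_length), ("PBS", ltr_length, ltr_length + _PBS_LEN)]
    pos = ltr_length + _PBS_LEN
    n_gaps = len(domains) + 1
    coding_nt = aa_total * 3
    gap_total = internal_length - _PBS_LEN - _PPT_LEN - coding_nt
    gap_sizes = [gap_total // n_gaps] * n_gaps
    gap_sizes[-1] += gap_total - sum(gap_sizes)
    proteins: dict[str, str] = {}
    for (dom, frac), gap in zip(domains, gap_sizes):
        spacer = random_seq(gap, rng, gc)
        parts.append(spacer)
        pos += gap
        pep = random_peptide(max(30, int(aa_total * frac / total_frac)), rng)
        cds = reverse_translate(pep)
        proteins[dom] = pep
        parts.append(cds)
        features.append((dom, pos, pos + len(cds)))
        pos += len(cds)
    parts.append(random_seq(gap_sizes[-1], rng, gc))
    pos += gap_sizes[-1]
    parts.append(ppt)
    features.append(("PPT", pos, pos + _PPT_LEN))
    pos += _PPT_LEN
    parts.append(ltr)
    features.append(("LTR3", pos, pos + ltr_length))
    seq = "".join(parts)
    return RepeatTemplate(name, "LTR_RT", seq, tuple(features), proteins)


def build_tir_element(internal_length: int, tir_length: int, seed: int,
                      name: str = "TIR_element", gc: float = 0.38) -> RepeatTemplate:
    """A cut-and-paste DNA transposon: terminal inverted repeats flanking a
    transposase ORF (CACTA/En-Spm style)."""
    if tir_length < 10:
        raise ValueError("tir_length must be >= 10")
    if internal_length < 400:
        raise ValueError("internal_length too small to host a transposase (>= 400 bp)")
    rng = np.random.default_rng(seed)
    tir = random_seq(tir_length, rng, gc)
    aa = (int(internal_length * 0.8)) // 3
    pep = random_peptide(aa, rng)
    cds = reverse_translate(pep)
    pad = internal_length - len(cds)
    left = random_seq(pad // 2, rng, gc)
    right = random_seq(pad - pad // 2, rng, gc)
    seq = tir + left + cds + right + revcomp(tir)
    features = (
        ("TIR", 0, tir_length),
        ("transposase", tir_length + len(left), tir_length + len(left) + len(cds)),
        ("TIR", len(seq) - tir_length, len(seq)),
    )
    return RepeatTemplate(name, "TIR_DNA_TE", seq, features, {"transposase": pep})


def build_satellite(monomer_length: int, seed: int, name: str = "satellite",
                    gc: float = 0.38) -> RepeatTemplate:
    rng = np.random.default_rng(seed)
    return RepeatTemplate(name, "satellite", random_seq(monomer_length, rng, gc))


def build_35s_unit(seed: int, name: str = "rDNA_35S", gene_lengths: tuple[int, int, int] = (1800, 160, 3400),
                   spacer_lengths: tuple[int, int, int, int] = (600, 250, 300, 2000),
                   gc: float = 0.50) -> RepeatTemplate:
    """A 35S rDNA unit: 5'ETS-18S-ITS1-5.8S-ITS2-26S-IGS."""
    rng = np.random.default_rng(seed)
    ets, its1, its2, igs = (random_seq(n, rng, gc) for n in spacer_lengths)
    g18, g58, g26 = (random_seq(n, rng, gc + 0.05) for n in gene_lengths)
    parts = [ets, g18, its1, g58, its2, g26, igs]
    names = ["ETS5", "18S", "ITS1", "5.8S", "ITS2", "26S", "IGS"]
    features, pos = [], 0
    for fname, part in zip(names, parts):
        features.append((fname, pos, pos + len(part)))
        pos += len(part)
    return RepeatTemplate(name, "rDNA_35S", "".join(parts), tuple(features))


def build_5s_template(seed: int, gene_length: int = 121, nts_length: int = 977,
                      name: str = "rDNA_5S") -> RepeatTemplate:
    """One 5S rDNA monomer: the 5S gene followed by the non-transcribed spacer."""
    rng = np.random.default_rng(seed)
    gene = random_seq(gene_length, rng, 0.53)   # 5S genes are GC-rich
    nts = random_seq(nts_length, rng, 0.38)
    features = (("gene_5S", 0, gene_length), ("NTS", gene_length, gene_length + nts_length))
    return RepeatTemplate(name, "rDNA_5S", gene + nts, features)


# ---------------------------------------------------------------------------
# 5S arrays


@dataclass(frozen=True)
class MonomerRecord:
    start: int
    end: int
    divergence: float
    detectable: bool   # False for hyper-mutated (pseudogenized) monomers


@dataclass(frozen=True)
class ArrayBuild:
    sequence: str
    nts_lengths: tuple[int, ...]
    label: ArrayMode
    monomers: tuple[MonomerRecord, ...]


def build_5s_array(gene: str, nts: str, n_monomers: int, mode: ArrayMode, seed: int,
                   divergence: float = 0.02,
                   hyper_divergence: float = 0.35,
                   hyper_fraction: float = 0.4,
                   spacer_monomers: float = 1.5) -> ArrayBuild:
    """A 5S rDNA tandem array in one of three organizations.

    regular      head-to-tail (gene+NTS) x n at low per-copy divergence
    long_nts     one or more spacers elongated by internal tandem duplication
                 of an NTS segment
    pseudogenic  a fraction of monomers hyper-mutated beyond the detection
                 threshold and interrupted by non-repeat spacers of at least
                 one monomer length
    """
    if not gene or not nts:
        raise ValueError("gene and NTS sequences must be non-empty")
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    rng = np.random.default_rng(seed)
    monomer_len = len(gene) + len(nts)
    parts: list[str] = []
    records: list[MonomerRecord] = []
    nts_lengths: list[int] = []
    pos = 0

    if mode == "pseudogenic":
        n_hyper = max(1, int(np.ceil(hyper_fraction * n_monomers)))
        # disruptions stay interior so the "pseudogenic" label is re-derivable
        # from the array structure: the first and last monomers remain intact
        # and every inserted spacer is flanked by intact monomers
        interior = list(range(1, n_monomers - 1))
        if interior:
            n_hyper = min(n_hyper, len(interior))
            hyper = set(rng.choice(interior, size=n_hyper, replace=False).tolist())
        else:
            hyper = {0}
        n_spacers = max(1, n_monomers // 3)
        spacer_candidates = [i for i in range(n_monomers - 1)
                             if i not in hyper and i + 1 not in hyper]
        if spacer_candidates:
            spacer_after = set(rng.choice(
                spacer_candidates, size=min(n_spacers, len(spacer_candidates)),
                replace=False).tolist())
        else:
            spacer_after = {0}
    else:
        hyper, spacer_after = set(), set()

    long_idx = set()
    if mode == "long_nts":
        long_idx = {int(rng.integers(0, n_monomers))}

    for i in range(n_monomers):
        div = hyper_divergence if i in hyper else divergence
        this_nts = nts
        if i in long_idx:
            # internal tandem duplication of an NTS segment
            seg_len = int(rng.integers(len(nts) // 3, 2 * len(nts) // 3))
            seg_start = int(rng.integers(0, len(nts) - seg_len))
            seg = nts[seg_start:seg_start + seg_len]
            this_nts = nts[:seg_start + seg_len] + seg + nts[seg_start + seg_len:]
        monomer = mutate(gene + this_nts, div, rng)
        parts.append(monomer)
        records.append(MonomerRecord(pos, pos + len(monomer), div, i not in hyper))
        nts_lengths.append(len(monomer) - len(gene))
        pos += len(monomer)
        if i in spacer_after and i < n_monomers - 1:
            spacer = random_seq(int(spacer_monomers * monomer_len), rng)
            parts.append(spacer)
            pos += len(spacer)

    return ArrayBuild("".join(parts), tuple(nts_lengths), mode, tuple(records))


# ---------------------------------------------------------------------------
# genome assembly


@dataclass(frozen=True)
class FamilySpec:
    template: RepeatTemplate
    target_proportion: float
    per_copy_divergence: float = 0.02
    arrangement: Literal["dispersed", "tandem"] = "dispersed"

    def __post_init__(self) -> None:
        if not (0 <= self.per_copy_divergence <= 0.3):
            raise ValueError("per_copy_divergence must be in [0, 0.3]")


@dataclass(frozen=True)
class ArraySpec:
    template: RepeatTemplate          # rDNA_5S template (gene + NTS)
    n_monomers: int
    mode: ArrayMode


@dataclass(frozen=True)
class GenomeSpec:
    genome_length: int
    families: tuple[FamilySpec, ...] = ()
    array_specs: tuple[ArraySpec, ...] = ()
    seed: int = 0
    gc: float = 0.38

    def __post_init__(self) -> None:
        if sum(f.target_proportion for f in self.families) >= 1:
            raise ValueError("sum of target proportions must be < 1")


@dataclass(frozen=True)
class CopyRecord:
    family: str
    start: int
    end: int
    strand: str
    divergence: float


@dataclass(frozen=True)
class ArrayRecord:
    family: str
    start: int
    end: int
    label: ArrayMode
    nts_lengths: tuple[int, ...]
    monomers: tuple[MonomerRecord, ...]   # coordinates relative to genome


@dataclass
class GroundTruth:
    """The simulator's manifest: what was planted, where, and how diverged."""

    genome_length: int
    proportions: dict[str, float]
    copies: list[CopyRecord]
    arrays: list[ArrayRecord]

    def family_bp(self, family: str) -> int:
        return sum(c.end - c.start for c in self.copies if c.family == family)

    def intervals(self, family: str | None = None) -> list[tuple[int, int, str]]:
        return [(c.start, c.end, c.family) for c in self.copies
                if family is None or c.family == family]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genome_length": self.genome_length,
            "proportions": self.proportions,
            "copies": [vars(c) for c in self.copies],
            "arrays": [
                {
                    "family": a.family, "start": a.start, "end": a.end,
                    "label": a.label, "nts_lengths": list(a.nts_lengths),
                    "monomers": [vars(m) for m in a.monomers],
                }
                for a in self.arrays
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tstart\tend\tstrand\tdivergence\n")
            for c in self.copies:
                fh.write(f"{c.family}\t{c.start}\t{c.end}\t{c.strand}\t{c.divergence}\n")


def _place(length: int, occupied: list[tuple[int, int]], genome_length: int,
           rng: np.random.Generator, tries: int = 2000) -> int:
    """Pick a start for a non-overlapping interval of ``length``."""
    starts = [iv[0] for iv in occupied]
    for _ in range(tries):
        s = int(rng.integers(0, genome_length - length + 1))
        i = bisect_left(starts, s)
        if i > 0 and occupied[i - 1][1] > s:
            continue
        if i < len(occupied) and occupied[i][0] < s + length:
            continue
        insort(occupied, (s, s + length))
        starts.insert(bisect_left(starts, s), s)
        return s
    raise ValueError("could not place all planted copies: proportions unreachable "
                     "within genome_length")


def build_genome(spec: GenomeSpec) -> tuple[str, GroundTruth]:
    """Background sequence with each family planted as independently diverged
    copies until the realized proportion is within +-10% relative of target."""
    rng = np.random.default_rng(spec.seed)
    L = spec.genome_length
    genome = encode(random_seq(L, rng, spec.gc)).copy()
    occupied: list[tuple[int, int]] = []
    copies: list[CopyRecord] = []
    arrays: list[ArrayRecord] = []

    for fam in spec.families:
        tmpl = fam.template
        unit = len(tmpl)
        target_bp = fam.target_proportion * L
        n_copies = max(1, round(target_bp / unit))
        planned = [unit] * n_copies
        realized = n_copies * unit
        if abs(realized / target_bp - 1) > 0.10:
            # top up (or trim the last copy) with a fragment to hit the target
            if realized < target_bp:
                frag = int(target_bp - realized)
                if frag >= 200:
                    planned.append(frag)
            else:
                excess = int(realized - target_bp)
                if unit - excess >= 200:
                    planned[-1] = unit - excess
        if fam.arrangement == "tandem":
            # contiguous blocks of diverged copies (a satellite array)
            n_arrays = max(1, len(planned) // 8)
            per_array = int(np.ceil(len(planned) / n_arrays))
            blocks = [planned[i:i + per_array] for i in range(0, len(planned), per_array)]
            for block in blocks:
                block_seqs = [mutate(tmpl.sequence[:ln], fam.per_copy_divergence, rng)
                              for ln in block]
                block_seq = "".join(block_seqs)
                s = _place(len(block_seq), occupied, L, rng)
                genome[s:s + len(block_seq)] = encode(block_seq)
                pos = s
                for cs in block_seqs:
                    copies.append(CopyRecord(tmpl.name, pos, pos + len(cs), "+",
                                             fam.per_copy_divergence))
                    pos += len(cs)
        else:
            for ln in planned:
                copy = mutate(tmpl.sequence[:ln], fam.per_copy_divergence, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                planted = copy if strand == "+" else revcomp(copy)
                s = _place(ln, occupied, L, rng)
                genome[s:s + ln] = encode(planted)
                copies.append(CopyRecord(tmpl.name, s, s + ln, strand,
                                         fam.per_copy_divergence))

    for aspec in spec.array_specs:
        tmpl = aspec.template
        gs, ge = tmpl.feature("gene_5S")
        ns, ne = tmpl.feature("NTS")
        build = build_5s_array(tmpl.sequence[gs:ge], tmpl.sequence[ns:ne],
                               aspec.n_monomers, aspec.mode,
                               seed=int(rng.integers(2**31)))
        s = _place(len(build.sequence), occupied, L, rng)
        genome[s:s + len(build.sequence)] = encode(build.sequence)
        arrays.append(ArrayRecord(
            tmpl.name, s, s + len(build.sequence), build.label, build.nts_lengths,
            tuple(MonomerRecord(m.start + s, m.end + s, m.divergence, m.detectable)
                  for m in build.monomers)))
        for m in build.monomers:
            copies.append(CopyRecord(tmpl.name, s + m.start, s + m.end, "+", m.divergence))

    proportions = {}
    for fam in spec.families:
        proportions[fam.template.name] = sum(
            c.end - c.start for c in copies if c.family == fam.template.name) / L
    for aspec in spec.array_specs:
        proportions[aspec.template.name] = sum(
            c.end - c.start for c in copies if c.family == aspec.template.name) / L

    return decode(genome), GroundTruth(L, proportions, copies, arrays)


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class ShortReadParams:
    n_pairs: int
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: float = 30.0
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must be <= insert_mean")


@dataclass(frozen=True)
class LongReadParams:
    n_reads: int
    length_range: tuple[int, int] = (500, 72_000)
    error_rate: float = 0.12       # indel-dominated, configurable
    median_length: int = 8_000
    length_sigma: float = 0.7

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo <= 0 or hi <= lo:
            raise ValueError("length_range must be positive and increasing")


def simulate_short_reads(genome: str, params: ShortReadParams, seed: int,
                         species_code: str = "") -> ReadSet:
    """Uniformly positioned error-bearing read pairs (mate reverse-complemented)."""
    if params.n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    L = len(genome)
    if L <= params.insert_mean:
        raise ValueError("genome shorter than the mean insert size")
    rng = np.random.default_rng(seed)
    rl = params.read_length
    n = params.n_pairs
    inserts = np.clip(np.rint(rng.normal(params.insert_mean, params.insert_sd, n)).astype(int),
                      rl, L - 1)
    starts = rng.integers(0, L - inserts, n)
    arr = encode(genome)
    fwd = arr[starts[:, None] + np.arange(rl)]
    rev_start = starts + inserts - rl
    rev = arr[rev_start[:, None] + np.arange(rl)]
    rev = 3 - rev[:, ::-1]  # reverse complement: A<->T, C<->G in code space

    if params.error_rate > 0:
        for mat in (fwd, rev):
            mask = rng.random(mat.shape) < params.error_rate
            mat[mask] = (mat[mask] + rng.integers(1, 4, int(mask.sum()))) % 4

    prefix = f"{species_code}|" if species_code else ""
    reads: list[Read] = []
    sources: dict[str, tuple[int, int, str]] = {}
    for i in range(n):
        id1, id2 = f"{prefix}r{i}/1", f"{prefix}r{i}/2"
        reads.append(Read(id1, decode(fwd[i]), id2))
        reads.append(Read(id2, decode(rev[i]), id1))
        s, ins = int(starts[i]), int(inserts[i])
        sources[id1] = (s, s + rl, "+")
        sources[id2] = (s + ins - rl, s + ins, "-")
    return ReadSet(reads, species_code=species_code,
                   provenance=["simulate_short_reads"], sources=sources)


def simulate_long_reads(genome: str, params: LongReadParams, seed: int,
                        species_code: str = "") -> ReadSet:
    """Log-normal length, indel-dominated-error long reads."""
    if params.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    L = len(genome)
    lo, hi = params.length_range
    lengths = np.clip(
        np.rint(rng.lognormal(np.log(params.median_length), params.length_sigma,
                              params.n_reads)).astype(int),
        lo, min(hi, L))
    starts = rng.integers(0, L - lengths + 1, params.n_reads)
    prefix = f"{species_code}|" if species_code else ""
    reads: list[Read] = []
    sources: dict[str, tuple[int, int, str]] = {}
    for i in range(params.n_reads):
        s, ln = int(starts[i]), int(lengths[i])
        frag = genome[s:s + ln]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = apply_indel_errors(frag, params.error_rate, rng)
        rid = f"{prefix}lr{i}"
        reads.append(Read(rid, frag))
        sources[rid] = (s, s + ln, strand)
    return ReadSet(reads, species_code=species_code,
                   provenance=["simulate_long_reads"], sources=sources)


def write_genome_fasta(genome: str, path: str | Path, name: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i:i + 80] + "\n")
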