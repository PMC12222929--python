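"""Read containers and pre-processing: filter, subsample, trim, pool.

The pre-processing pipeline mirrors the standard protocol for clustering-based
repeatome profiling: contaminant filtering, random subsampling of read pairs,
fixed-length trimming (all-100-nt input keeps the similarity thresholds
homogeneous), and pooling of per-species subsamples with species-coded read
ids for comparative runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._alignment import SemiGlobalHit, best_local_both_strands, minimizers

logger = logging.getLogger(__name__)

SPECIES_SEP = "|"


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    mate_id: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def species_code(self) -> str:
        return self.id.split(SPECIES_SEP, 1)[0] if SPECIES_SEP in self.id else ""


@dataclass
class ReadSet:
    """A set of (optionally paired) reads flowing through the pipeline.

    ``sources`` optionally records, for simulated reads, the genome interval
    and strand each read was drawn from: id -> (start, end, strand).
    """

    reads: list[Read]
    species_code: str = ""
    provenance: list[str] = field(default_factory=list)
    sources: dict[str, tuple[int, int, str]] | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids must be unique")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def by_id(self) -> dict[str, Read]:
        return {r.id: r for r in self.reads}

    def pairs(self) -> list[tuple[Read, Read]]:
        """Mate pairs, each returned once (first read id < mate id)."""
        idx = self.by_id()
        out = []
        for r in self.reads:
            if r.mate_id and r.id < r.mate_id and r.mate_id in idx:
                out.append((r, idx[r.mate_id]))
        return out

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.reads]

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reads:
            counts[r.species_code] = counts.get(r.species_code, 0) + 1
        return counts

    # ------------------------------------------------------------------ I/O
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f">{r.id}\n{r.sequence}\n")

    def to_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, species_code: str = "") -> "ReadSet":
        reads = []
        name, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    if name is not None:
                        reads.append(Read(name, "".join(chunks)))
                    name, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line.upper())
        if name is not None:
            reads.append(Read(name, "".join(chunks)))
        return cls(reads, species_code=species_code, provenance=[str(path)])

    @classmethod
    def from_fastq(cls, path: str | Path, species_code: str = "") -> "ReadSet":
        reads = []
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip().upper()
                fh.readline()
                fh.readline()
                reads.append(Read(header[1:].split()[0].strip(), seq))
        return cls(reads, species_code=species_code, provenance=[str(path)])


def pair_reads(readset: ReadSet) -> ReadSet:
    """Infer mate pairing from /1 /2 id suffixes."""
    by_stem: dict[str, list[Read]] = {}
    for r in readset.reads:
        stem = r.id[:-2] if r.id.endswith(("/1", "/2")) else r.id
        by_stem.setdefault(stem, []).append(r)
    reads = []
    for stem, group in by_stem.items():
        if len(group) == 2:
            a, b = sorted(group, key=lambda r: r.id)
            reads.append(replace(a, mate_id=b.id))
            reads.append(replace(b, mate_id=a.id))
        else:
            reads.extend(group)
    return replace(readset, reads=reads)


# ---------------------------------------------------------------------------
# pipeline stages


def filter_by_reference(readset: ReadSet, contaminant_refs: Mapping[str, str] | Sequence[str],
                        min_identity: float = 0.90, min_coverage: float = 0.80,
                        k: int = 15) -> tuple[ReadSet, int]:
    """Drop reads (and their mates) matching a contaminant reference.

    A read is contaminant-derived when a local alignment against any
    reference reaches ``min_identity`` over at least ``min_coverage`` of the
    read length.  A shared-15-mer prefilter avoids aligning unrelated reads.
    Returns the surviving reads and the number of removed reads.
    """
    refs = list(contaminant_refs.values()) if isinstance(contaminant_refs, Mapping) else list(contaminant_refs)
    if not refs or not any(refs):
        raise ValueError("contaminant references must be non-empty")
    if len(readset) == 0:
        logger.warning("filter_by_reference called on an empty read set")
        return replace(readset, reads=[]), 0

    ref_kmers: set[str] = set()
    for ref in refs:
        ref_kmers.update(minimizers(ref, k=k, w=1))

    flagged: set[str] = set()
    for r in readset.reads:
        if not (minimizers(r.sequence, k=k, w=1) & ref_kmers):
            continue
        for ref in refs:
            hit = best_local_both_strands(r.sequence, ref)
            if hit.identity >= min_identity and hit.columns >= min_coverage * len(r.sequence):
                flagged.add(r.id)
                if r.mate_id:
                    flagged.add(r.mate_id)
                break
    survivors = [r for r in readset.reads if r.id not in flagged]
    logger.info("filter_by_reference: %d in, %d removed", len(readset), len(flagged))
    out = replace(readset, reads=survivors)
    return out, len(flagged)


def _units(readset: ReadSet) -> list[tuple[Read, ...]]:
    """Sampling units: mate pairs plus unpaired singletons, in input order."""
    idx = readset.by_id()
    seen: set[str] = set()
    units: list[tuple[Read, ...]] = []
    for r in readset.reads:
        if r.id in seen:
            continue
        if r.mate_id and r.mate_id in idx:
            units.append((r, idx[r.mate_id]))
            seen.update((r.id, r.mate_id))
        else:
            units.append((r,))
            seen.add(r.id)
    return units


def subsample(readset: ReadSet, n_pairs: int, seed: int) -> ReadSet:
    """Uniform pair-preserving sampling without replacement."""
    units = _units(readset)
    if n_pairs > len(units):
        raise ValueError(f"requested {n_pairs} pairs but only {len(units)} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(units), size=n_pairs, replace=False)
    reads = [r for i in sorted(chosen) for r in units[i]]
    logger.info("subsample: %d units in, %d out", len(units), n_pairs)
    return replace(readset, reads=reads)


def trim_to_length(readset: ReadSet, length: int = 100) -> tuple[ReadSet, int]:
    """Truncate reads to their first ``length`` bases; drop shorter reads
    together with their mates.  Returns (trimmed set, dropped-unit count)."""
    if length < 1:
        raise ValueError("trim length must be >= 1")
    dropped = 0
    reads = []
    for unit in _units(readset):
        if any(len(r) < length for r in unit):
            dropped += 1
            continue
        reads.extend(replace(r, sequence=r.sequence[:length]) for r in unit)
    logger.info("trim_to_length: dropped %d units", dropped)
    return replace(readset, reads=reads), dropped


def pool_species(readsets: Iterable[ReadSet], per_species_n: int, seed: int) -> ReadSet:
    """Concatenate per-species random subsamples of ``per_species_n`` reads,
    prefixing ids with the species code."""
    rng = np.random.default_rng(seed)
    pooled: list[Read] = []
    provenance: list[str] = []
    for rs in readsets:
        if len(rs) < per_species_n:
            raise ValueError(f"species {rs.species_code!r} has {len(rs)} reads < {per_species_n}")
        if not rs.species_code:
            raise ValueError("each pooled read set needs a species_code")
        chosen = rng.choice(len(rs.reads), size=per_species_n, replace=False)
        idset = {rs.reads[i].id for i in chosen}
        prefix = "" if rs.reads[0].species_code == rs.species_code else \
            f"{rs.species_code}{SPECIES_SEP}"
        for i in sorted(chosen):
            r = rs.reads[i]
            mate = r.mate_id if (r.mate_id in idset) else None
            pooled.append(Read(
                f"{prefix}{r.id}",
                r.sequence,
                f"{prefix}{mate}" if mate else None,
            ))
        provenance.extend(rs.provenance)
    return ReadSet(pooled, species_code="pooled", provenance=provenance)
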