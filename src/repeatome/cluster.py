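"""Similarity-graph read clustering with abundance accounting and annotation.

Reads are grouped under the canonical repeat-clustering thresholds (90%
identity over at least 55% of the read length, either strand).  Candidate
pairs come from shared minimizers and are verified by exact local alignment;
clusters are the connected components of the verified graph.  This is a
documented simplification of graph-community clustering pipelines: the
thresholds are the published ones, the community-detection step is not
reproduced.  Consequently the method assumes the low-coverage operating
regime of read-clustering repeat profiling (single-copy genome coverage
well below 1x), where connected components and communities coincide.

Reported ("top") clusters are those holding at least 0.01% of the analyzed
reads; contig building is attempted only for clusters of five or more reads.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
from Bio.Seq import Seq

from ._alignment import (
    UnionFind,
    _DEFAULT_ALIGNER,
    best_local,
    evalue_nt,
    evalue_protein,
    minimizers,
    protein_local,
    revcomp,
)
from .prep import ReadSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityParams:
    min_identity: float = 0.90
    min_coverage: float = 0.55     # fraction of the shorter read length
    kmer_seed_size: int = 13
    minimizer_window: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("min_identity and min_coverage must be in (0, 1]")


DEFAULT_PARAMS = SimilarityParams()


def similar(read_a: str, read_b: str, params: SimilarityParams = DEFAULT_PARAMS) -> bool:
    """True iff the best local alignment on either strand reaches
    ``min_identity`` over at least ``min_coverage`` of the shorter read.

    Identity counts gap columns as mismatches.  Thresholds are applied to
    the maximal-scoring local alignment, so a shared block shorter than the
    coverage floor does not qualify even if flanking noise could be glued on.
    """
    if not read_a or not read_b:
        raise ValueError("reads must be non-empty")
    min_len = min(len(read_a), len(read_b))
    min_cols = params.min_coverage * min_len
    # a passing alignment scores at least this much under +1/-3 scoring
    score_floor = min_cols * (params.min_identity - 3 * (1 - params.min_identity))
    for target in (read_b, revcomp(read_b)):
        if _DEFAULT_ALIGNER.score(read_a, target) < score_floor:
            continue
        hit = best_local(read_a, target)
        if hit.identity >= params.min_identity and hit.columns >= min_cols:
            return True
    return False


def _fast_similar(read_a: str, read_b: str, read_b_rc: str,
                  params: SimilarityParams) -> bool:
    """Approximate `similar` via banded semi-global window searches (edlib).

    Windows spanning the coverage floor are taken from the start, middle and
    end of read_a and searched in read_b on both strands at the corresponding
    edit budget.  Used for large read sets; exact alignment remains the
    arbiter on small sets and in tests.
    """
    la = len(read_a)
    w = math.ceil(params.min_coverage * min(la, len(read_b)))
    w = min(w, la)
    k = int((1 - params.min_identity) * w) + 1
    offsets = sorted({0, max(0, (la - w) // 2), max(0, la - w)})
    for off in offsets:
        window = read_a[off:off + w]
        for target in (read_b, read_b_rc):
            if edlib.align(window, target, mode="HW", k=k)["editDistance"] >= 0:
                return True
    return False


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Annotation:
    name: str
    lineage: str
    evidence: str          # "nucleotide" | "protein" | "none"
    evalue: float
    identity: float
    span: int

    @property
    def unclassified(self) -> bool:
        return self.evidence == "none"


UNCLASSIFIED = Annotation("unclassified", "", "none", float("inf"), 0.0, 0)


@dataclass
class ReadCluster:
    cluster_id: str
    read_ids: tuple[str, ...]
    genome_proportion: float
    per_species_counts: dict[str, int] = field(default_factory=dict)
    annotation: Annotation | None = None
    supercluster_id: str | None = None
    reported: bool = False

    @property
    def size(self) -> int:
        return len(self.read_ids)

    @property
    def assemblable(self) -> bool:
        return self.size >= 5


@dataclass(frozen=True)
class Supercluster:
    supercluster_id: str
    cluster_ids: tuple[str, ...]
    link_counts: dict[tuple[str, str], int]


def reporting_floor(total_reads: int, floor: float = 1e-4) -> int:
    """Smallest cluster size reported at a proportion threshold (0.01% default)."""
    return math.ceil(floor * total_reads)


def build_clusters(readset: ReadSet, params: SimilarityParams = DEFAULT_PARAMS,
                   report_floor: float = 1e-4, verify: str = "auto",
                   exact_threshold: int = 20_000,
                   all_pairs_threshold: int = 500) -> list[ReadCluster]:
    """Cluster reads into connected components of the similarity graph.

    ``verify`` selects how candidate edges are confirmed: "exact" uses the
    `similar` contract, "fast" a banded approximation, "auto" switches to
    the approximation above ``exact_threshold`` reads.

    Up to ``all_pairs_threshold`` reads every pair is tested, which makes the
    result exactly the connected components of the `similar` relation; above
    it, candidate pairs come from shared minimizers (a recall heuristic).
    """
    n = len(readset)
    if n == 0:
        raise ValueError("cannot cluster an empty read set")
    if verify not in ("auto", "exact", "fast"):
        raise ValueError(f"unknown verify mode {verify!r}")
    use_exact = verify == "exact" or (verify == "auto" and n <= exact_threshold)

    seqs = readset.sequences()
    rcs = None if use_exact else [revcomp(s) for s in seqs]

    def candidate_groups():
        if n <= all_pairs_threshold:
            yield list(range(n))
            return
        buckets: dict[str, list[int]] = {}
        for i, s in enumerate(seqs):
            for m in minimizers(s, params.kmer_seed_size, params.minimizer_window):
                buckets.setdefault(m, []).append(i)
        for key in sorted(buckets):
            yield buckets[key]

    uf = UnionFind(n)
    failed: set[tuple[int, int]] = set()
    checked = 0
    for members in candidate_groups():
        if len(members) < 2:
            continue
        for ai in range(len(members) - 1):
            a = members[ai]
            for b in members[ai + 1:]:
                if uf.find(a) == uf.find(b):
                    continue
                pair = (a, b) if a < b else (b, a)
                if pair in failed:
                    continue
                checked += 1
                if use_exact:
                    ok = similar(seqs[a], seqs[b], params)
                else:
                    ok = _fast_similar(seqs[a], seqs[b], rcs[b], params)
                if ok:
                    uf.union(a, b)
                else:
                    failed.add(pair)
    logger.info("build_clusters: %d reads, %d edge checks", n, checked)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    ordered = sorted(components.values(), key=lambda m: (-len(m), readset.reads[m[0]].id))
    clusters = []
    for rank, members in enumerate(ordered, 1):
        ids = tuple(readset.reads[i].id for i in members)
        counts: dict[str, int] = {}
        for i in members:
            sp = readset.reads[i].species_code
            counts[sp] = counts.get(sp, 0) + 1
        prop = len(members) / n
        clusters.append(ReadCluster(
            cluster_id=f"CL{rank:04d}", read_ids=ids, genome_proportion=prop,
            per_species_counts=counts, reported=prop >= report_floor))
    return clusters


def link_superclusters(clusters: Sequence[ReadCluster],
                       mate_pairs: ReadSet | Iterable[tuple[str, str]],
                       min_links: float = 3) -> list[Supercluster]:
    """Join clusters bridged by at least ``min_links`` straddling mate pairs."""
    if isinstance(mate_pairs, ReadSet):
        mate_pairs = [(a.id, b.id) for a, b in mate_pairs.pairs()]
    where = {rid: ci for ci, cl in enumerate(clusters) for rid in cl.read_ids}
    links: dict[tuple[int, int], int] = {}
    for a, b in mate_pairs:
        ca, cb = where.get(a), where.get(b)
        if ca is None or cb is None or ca == cb:
            continue
        key = (ca, cb) if ca < cb else (cb, ca)
        links[key] = links.get(key, 0) + 1

    uf = UnionFind(len(clusters))
    for (ca, cb), count in links.items():
        if count >= min_links:
            uf.union(ca, cb)
    groups: dict[int, list[int]] = {}
    for ci in range(len(clusters)):
        groups.setdefault(uf.find(ci), []).append(ci)
    ordered = sorted(groups.values(),
                     key=lambda g: (-sum(clusters[c].size for c in g), clusters[g[0]].cluster_id))
    supers = []
    for rank, group in enumerate(ordered, 1):
        sid = f"SC{rank:04d}"
        cids = tuple(clusters[c].cluster_id for c in sorted(group, key=lambda c: -clusters[c].size))
        link_counts = {
            (clusters[ca].cluster_id, clusters[cb].cluster_id): count
            for (ca, cb), count in links.items() if ca in group and cb in group
        }
        for c in group:
            clusters[c].supercluster_id = sid
        supers.append(Supercluster(sid, cids, link_counts))
    return supers


# ---------------------------------------------------------------------------
# representative contigs


def cluster_representative(cluster: ReadCluster | Sequence[str], reads: ReadSet,
                           k: int = 25, max_length: int = 100_000) -> tuple[str, float]:
    """Greedy overlap-layout contig of a cluster's reads.

    Returns the highest-mean-depth contig and its mean depth.  Deterministic
    for a fixed input order.
    """
    ids = list(cluster.read_ids) if isinstance(cluster, ReadCluster) else list(cluster)
    if len(ids) < 5:
        raise ValueError("contig building needs a cluster of >= 5 reads")
    by_id = reads.by_id()
    oriented: list[str] = []
    for rid in ids:
        oriented.append(by_id[rid].sequence)
        oriented.append(revcomp(by_id[rid].sequence))

    index: dict[str, list[tuple[int, int]]] = {}   # kmer -> [(oriented_idx, pos)]
    for oi, seq in enumerate(oriented):
        for pos in range(0, len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((oi, pos))

    used = [False] * len(ids)

    def extend_right(contig: str) -> str:
        while len(contig) < max_length:
            tail = contig[-k:]
            best = None
            for oi, pos in index.get(tail, ()):
                ri = oi // 2
                if used[ri]:
                    continue
                seq = oriented[oi]
                ext = len(seq) - (pos + k)
                ov = min(pos + k, len(contig))
                if ov >= k:
                    d = edlib.align(seq[pos + k - ov:pos + k], contig[-ov:], mode="NW",
                                    k=max(2, int(0.1 * ov)))["editDistance"]
                    if d < 0:
                        continue
                if ext <= 0:
                    used[ri] = True
                    continue
                cand = (ext, ids[ri], oi, pos)
                if best is None or cand > best:
                    best = cand
            if best is None:
                break
            ext, _, oi, pos = best
            used[oi // 2] = True
            contig += oriented[oi][pos + k:]
        return contig

    def support(contig: str) -> int:
        """Total read bases placed on the contig (anchor k-mer placement)."""
        cov = 0
        ctg_kmers = {contig[p:p + k]: p for p in range(0, len(contig) - k + 1)}
        for rid in ids:
            seq = by_id[rid].sequence
            for probe in (seq, revcomp(seq)):
                hitpos = next((ctg_kmers[probe[p:p + k]] - p
                               for p in range(0, len(probe) - k + 1, k)
                               if probe[p:p + k] in ctg_kmers), None)
                if hitpos is not None:
                    cov += min(len(contig), hitpos + len(seq)) - max(0, hitpos)
                    break
        return cov

    contigs: list[tuple[int, int, str]] = []
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    for ri in order:
        if used[ri]:
            continue
        used[ri] = True
        contig = extend_right(oriented[2 * ri])
        contig = revcomp(extend_right(revcomp(contig)))
        contigs.append((support(contig), len(contig), contig))
    # the representative maximises total read support, which favours the
    # longest well-covered assembly over short locally dense fragments
    cov, _, contig = max(contigs, key=lambda t: (t[0], t[1], t[2]))
    return contig, cov / max(1, len(contig))


# ---------------------------------------------------------------------------
# annotation


def _six_frames(seq: str) -> list[str]:
    frames = []
    for s in (seq, revcomp(seq)):
        for off in range(3):
            sub = s[off:]
            sub = sub[:len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()))
    return frames


def annotate_cluster(contig: str, repeat_db: Mapping[str, str] | None = None,
                     domain_db: Mapping[str, str] | None = None,
                     max_e: float = 1e-5) -> Annotation:
    """Label a contig by nucleotide search against a repeat database and
    six-frame translated search against a domain-protein database.

    The best label wins by E-value, ties broken by higher identity, longer
    span, then lexicographic name.  Database keys of the form
    ``name#lineage`` carry the lineage; otherwise lineage is empty.
    """
    repeat_db = dict(repeat_db or {})
    domain_db = dict(domain_db or {})
    if not repeat_db and not domain_db:
        warnings.warn("both annotation databases are empty; everything is unclassified")
        return UNCLASSIFIED

    candidates: list[tuple[float, float, int, str, Annotation]] = []
    nt_total = sum(len(s) for s in repeat_db.values())
    for key in sorted(repeat_db):
        entry = repeat_db[key]
        if len(contig) <= len(entry):
            # double the entry so contigs of tandem units match in any phase
            query, target = contig, entry + entry
        else:
            query, target = entry, contig
        best_d = None
        for t in (target, revcomp(target)):
            res = edlib.align(query, t, mode="HW", k=int(0.5 * len(query)))
            if res["editDistance"] >= 0 and (best_d is None or res["editDistance"] < best_d):
                best_d = res["editDistance"]
        if best_d is None:
            continue
        matches = len(query) - best_d
        ev = evalue_nt(matches - 2 * best_d, len(contig), max(nt_total, 1))
        name, _, lineage = key.partition("#")
        ann = Annotation(name, lineage, "nucleotide", ev, matches / len(query), len(query))
        candidates.append((ev, -ann.identity, -ann.span, name, ann))

    if domain_db:
        frames = _six_frames(contig)
        aa_total = sum(len(p) for p in domain_db.values())
        for key in sorted(domain_db):
            prot = domain_db[key]
            best_hit = None
            for pep in frames:
                hit = protein_local(prot, pep)
                if best_hit is None or hit.score > best_hit.score:
                    best_hit = hit
            if best_hit is None or best_hit.score <= 0:
                continue
            ev = evalue_protein(best_hit.score, len(contig) // 3, max(aa_total, 1))
            name, _, lineage = key.partition("#")
            ann = Annotation(name, lineage, "protein", ev, best_hit.identity, best_hit.columns)
            candidates.append((ev, -ann.identity, -ann.span, name, ann))

    if not candidates:
        return UNCLASSIFIED
    candidates.sort(key=lambda t: t[:4])
    best = candidates[0][4]
    return best if best.evalue <= max_e else UNCLASSIFIED


def annotate_clusters(clusters: Sequence[ReadCluster], reads: ReadSet,
                      repeat_db: Mapping[str, str] | None = None,
                      domain_db: Mapping[str, str] | None = None,
                      max_e: float = 1e-5) -> dict[str, str]:
    """Attach annotations to all reported, assemblable clusters in place.

    Returns the representative contigs built along the way, keyed by
    cluster id (only clusters large enough to assemble appear)."""
    contigs: dict[str, str] = {}
    for cl in clusters:
        if cl.reported and cl.assemblable:
            contig, _ = cluster_representative(cl, reads)
            contigs[cl.cluster_id] = contig
            cl.annotation = annotate_cluster(contig, repeat_db, domain_db, max_e=max_e)
        elif cl.reported:
            cl.annotation = UNCLASSIFIED
    return contigs


def quantify_by_mapping(family_contigs: Mapping[str, Sequence[str]], reads: ReadSet,
                        params: SimilarityParams = DEFAULT_PARAMS) -> dict[str, float]:
    """Genome proportion of each repeat from matching *all* reads against its
    cluster representatives.

    Clustering operates on a low-coverage subsample; abundances are then
    estimated over the full read set by assigning each read to the repeat
    whose contigs it matches best under the clustering thresholds (banded
    window approximation, exact 13-mer prefilter).  This decouples abundance
    precision from the clustering subsample size.
    """
    if not family_contigs:
        raise ValueError("no contigs to quantify against")
    import numpy as np

    sep = "#" * 10   # uncrossable separator between concatenated contigs
    k_seed = params.kmer_seed_size
    lut = np.full(256, 255, np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i

    def kmer_matrix(byte_rows: "np.ndarray") -> tuple["np.ndarray", "np.ndarray"]:
        """Rolling 2-bit k-mer codes per row plus a validity mask."""
        codes = lut[byte_rows]
        n = byte_rows.shape[1] - k_seed + 1
        out = np.zeros((byte_rows.shape[0], n), np.uint32)
        ok = np.ones((byte_rows.shape[0], n), bool)
        for j in range(k_seed):
            out = (out << np.uint32(2)) | codes[:, j:j + n]
            ok &= codes[:, j:j + n] != 255
        return out, ok

    targets: dict[str, tuple[str, str]] = {}
    fam_codes: dict[str, "np.ndarray"] = {}
    for fam, contigs in family_contigs.items():
        joined = sep.join(contigs)
        targets[fam] = (joined, revcomp(joined))
        both = targets[fam][0] + sep + targets[fam][1]
        row = np.frombuffer(both.encode(), np.uint8)[None, :]
        c, ok = kmer_matrix(row)
        fam_codes[fam] = np.unique(c[ok])

    names = sorted(family_contigs)
    counts = {fam: 0 for fam in names}
    min_kmer_hits = 3   # a borderline true match still shares ~10 exact seeds

    # group reads by length for vectorized candidate screening
    by_len: dict[int, list[int]] = {}
    seqs = reads.sequences()
    for i, s in enumerate(seqs):
        if len(s) >= k_seed:
            by_len.setdefault(len(s), []).append(i)

    for length, idxs in by_len.items():
        block = np.frombuffer("".join(seqs[i] for i in idxs).encode(),
                              np.uint8).reshape(len(idxs), length)
        codes, ok = kmer_matrix(block)
        cand_lists: list[list[str]] = [[] for _ in idxs]
        for fam in names:
            hits = np.isin(codes, fam_codes[fam]) & ok
            rows = np.nonzero(hits.sum(axis=1) >= min_kmer_hits)[0]
            for r in rows:
                cand_lists[r].append(fam)
        for r, cand in enumerate(cand_lists):
            if not cand:
                continue
            seq = seqs[idxs[r]]
            la = len(seq)
            w = min(la, math.ceil(params.min_coverage * la))
            kmax = int((1 - params.min_identity) * w) + 1
            offsets = sorted({0, max(0, (la - w) // 2), max(0, la - w)})
            best: tuple[int, str] | None = None
            for fam in cand:
                for off in offsets:
                    window = seq[off:off + w]
                    d = min((edlib.align(window, t, mode="HW", k=kmax)["editDistance"]
                             for t in targets[fam]), key=lambda x: x if x >= 0 else kmax + 1)
                    if d >= 0 and (best is None or d < best[0]):
                        best = (d, fam)
                        break   # any qualifying window settles this family
            if best is not None:
                counts[best[1]] += 1
    return {fam: c / len(reads) for fam, c in counts.items()}
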