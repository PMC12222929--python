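import itertools

import numpy as np
import pytest

from repeatome import cluster, simulate
from repeatome._alignment import UnionFind, best_local_both_strands, revcomp
from repeatome.cluster import SimilarityParams, similar
from repeatome.prep import Read, ReadSet

RNG = np.random.default_rng(42)


def _rand(n, rng=RNG):
    return simulate.random_seq(n, rng)


# ------------------------------------------------------------------ similar

def test_similar_identical_reads():
    s = _rand(100)
    assert similar(s, s)


def test_similar_strand_invariance():
    rng = np.random.default_rng(1)
    core = simulate.random_seq(70, rng)
    a = simulate.random_seq(15, rng) + core + simulate.random_seq(15, rng)
    b = simulate.random_seq(15, rng) + core + simulate.random_seq(15, rng)
    assert similar(a, b)
    assert similar(a, revcomp(b))
    assert similar(revcomp(a), b)


def test_similar_shared_block_thresholds():
    # 100-nt reads need >= 55 aligned columns at >= 90% identity; a shared
    # 60-nt exact block qualifies, a 50-nt block does not.  The oracle is the
    # maximal local alignment itself, checked explicitly alongside `similar`.
    rng = np.random.default_rng(2)
    for block_len, expect in ((60, True), (50, False)):
        block = simulate.random_seq(block_len, rng)
        pad_a = 100 - block_len
        a = simulate.random_seq(pad_a // 2, rng) + block + simulate.random_seq(pad_a - pad_a // 2, rng)
        b = simulate.random_seq(20, rng) + block + simulate.random_seq(80 - block_len, rng)
        hit = best_local_both_strands(a, b)
        qualifies = hit.identity >= 0.90 and hit.columns >= 0.55 * 100
        assert qualifies == expect, f"oracle mismatch at block {block_len}"
        assert similar(a, b) == expect


def test_similar_identity_floor():
    # 10% divergence over the full read sits at the identity boundary; 20%
    # divergence is clearly below it.
    rng = np.random.default_rng(3)
    a = simulate.random_seq(100, rng)
    bad = simulate.mutate(a, 0.20, np.random.default_rng(4))
    assert not similar(a, bad)
    assert similar(a, simulate.mutate(a, 0.04, np.random.default_rng(5)))


def test_similar_rejects_empty():
    with pytest.raises(ValueError):
        similar("", "ACGT")


def test_similarity_params_validation():
    with pytest.raises(ValueError):
        SimilarityParams(min_identity=1.5)


# ------------------------------------------------------------- build_clusters

def _family_readset(seed=7, n_pairs=150):
    """Two planted families plus background in a small genome."""
    fams = (
        simulate.FamilySpec(simulate.build_ltr_element(2000, 200, seed=1), 0.15),
        simulate.FamilySpec(simulate.build_tir_element(900, 40, seed=2), 0.08),
    )
    genome, truth = simulate.build_genome(
        simulate.GenomeSpec(60_000, families=fams, seed=seed))
    rs = simulate.simulate_short_reads(
        genome, simulate.ShortReadParams(n_pairs=n_pairs, error_rate=0.01), seed=seed + 1)
    return genome, truth, rs


def test_build_clusters_matches_brute_force_oracle():
    # exhaustive all-pairs `similar` + union-find is the clustering oracle
    _, _, rs = _family_readset()
    assert len(rs) == 300
    clusters = cluster.build_clusters(rs, verify="exact")

    seqs = rs.sequences()
    uf = UnionFind(len(seqs))
    for i, j in itertools.combinations(range(len(seqs)), 2):
        if similar(seqs[i], seqs[j]):
            uf.union(i, j)
    oracle = {}
    for i, r in enumerate(rs.reads):
        oracle.setdefault(uf.find(i), set()).add(r.id)
    got = {frozenset(c.read_ids) for c in clusters}
    want = {frozenset(m) for m in oracle.values()}
    assert got == want


def test_build_clusters_ordering_and_floor():
    _, _, rs = _family_readset(seed=8)
    clusters = cluster.build_clusters(rs, verify="exact", report_floor=0.01)
    sizes = [c.size for c in clusters]
    assert sizes == sorted(sizes, reverse=True)
    assert sum(sizes) == len(rs)
    floor = cluster.reporting_floor(len(rs), 0.01)
    for c in clusters:
        assert c.reported == (c.size >= floor)
        assert c.genome_proportion == pytest.approx(c.size / len(rs))


def test_reporting_floor_values():
    assert cluster.reporting_floor(200_000) == 20
    assert cluster.reporting_floor(1_000_000, 0.01) == 10_000


def test_link_superclusters():
    clusters = [
        cluster.ReadCluster("CL0001", ("a/1", "b/1", "c/1"), 0.3),
        cluster.ReadCluster("CL0002", ("a/2", "b/2", "c/2"), 0.3),
        cluster.ReadCluster("CL0003", ("x/1", "x/2"), 0.2),
    ]
    pairs = [("a/1", "a/2"), ("b/1", "b/2"), ("c/1", "c/2"), ("x/1", "x/2")]
    supers = cluster.link_superclusters(clusters, pairs, min_links=3)
    linked = next(s for s in supers if len(s.cluster_ids) > 1)
    assert set(linked.cluster_ids) == {"CL0001", "CL0002"}
    assert linked.link_counts[("CL0001", "CL0002")] == 3
    assert clusters[0].supercluster_id == clusters[1].supercluster_id
    assert clusters[2].supercluster_id != clusters[0].supercluster_id


# ------------------------------------------------- representative + annotate

def test_cluster_representative_extends_seed():
    rng = np.random.default_rng(11)
    template = simulate.random_seq(600, rng)
    reads = []
    for i in range(80):
        s = int(rng.integers(0, 500))
        reads.append(Read(f"r{i}", template[s:s + 100]))
    rs = ReadSet(reads)
    contig, depth = cluster.cluster_representative([r.id for r in reads], rs)
    assert len(contig) > 150
    assert depth > 1.0
    assert contig in template or revcomp(contig) in template


def test_annotate_cluster_nucleotide_and_rotation():
    rng = np.random.default_rng(12)
    sat = simulate.random_seq(300, rng)
    # rotated tandem-junction contig must still match the monomer entry
    rotated = sat[200:] + sat[:120]
    ann = cluster.annotate_cluster(rotated, repeat_db={"SAT_fam": sat})
    assert ann.name == "SAT_fam" and ann.evidence == "nucleotide"
    none = cluster.annotate_cluster(simulate.random_seq(300, rng),
                                    repeat_db={"SAT_fam": sat})
    assert none.unclassified


def test_annotate_cluster_protein_evidence():
    t = simulate.build_ltr_element(2500, 200, seed=3)
    s, e = t.feature("RT")
    contig = t.sequence[s - 60:e + 60]
    ann = cluster.annotate_cluster(contig, domain_db=t.domain_proteins)
    assert ann.evidence == "protein"
    assert ann.name == "RT"


def test_quantify_by_mapping_recovers_planted_share():
    genome, truth, _ = _family_readset(seed=9)
    rs = simulate.simulate_short_reads(
        genome, simulate.ShortReadParams(n_pairs=2_000, error_rate=0.01), seed=10)
    fams = {}
    for name in ("LTR_element", "TIR_element"):
        copies = [c for c in truth.copies if c.family == name][:3]
        fams[name] = [genome[c.start:c.end] for c in copies]
    est = cluster.quantify_by_mapping(fams, rs)
    for name in fams:
        true = truth.proportions[name]
        assert abs(est[name] - true) / true < 0.25
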