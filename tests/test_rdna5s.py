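import numpy as np
import pytest

from repeatome import rdna5s, simulate
from repeatome._alignment import revcomp
from repeatome.prep import Read, ReadSet
from repeatome.rdna5s import ClassifyParams, Monomer5S, derive_label

MONOMER_LEN = 1098   # 121-bp gene + 977-bp NTS


def _template(seed=31):
    t = simulate.build_5s_template(seed)
    gene = t.sequence[slice(*t.feature("gene_5S"))]
    nts = t.sequence[slice(*t.feature("NTS"))]
    return gene, nts


# ------------------------------------------------------------- labeling rule

def test_derive_label_rules():
    p = ClassifyParams()
    # long read, many monomers, regular spacing
    assert derive_label(7_000, 6, [0, 2, -1, 3, 0], MONOMER_LEN, p) == "regular"
    # few monomers or short read -> potentially regular
    assert derive_label(4_000, 3, [0, 1], MONOMER_LEN, p) == "potentially_regular"
    assert derive_label(5_500, 5, [0] * 4, MONOMER_LEN, p) == "potentially_regular"
    # any major gap dominates
    assert derive_label(9_000, 6, [0, 0, 3 * MONOMER_LEN, 0, 0], MONOMER_LEN, p) == "pseudogenic"
    # single monomer
    assert derive_label(8_000, 1, [], MONOMER_LEN, p) == "sparse"
    with pytest.raises(ValueError):
        derive_label(8_000, 0, [], MONOMER_LEN, p)


def test_gap_threshold_boundary():
    p = ClassifyParams()
    just_under = int(p.gap_frac * MONOMER_LEN)       # elongated NTS, not a break
    just_over = int(p.gap_frac * MONOMER_LEN) + 1
    assert derive_label(8_000, 6, [just_under] + [0] * 4, MONOMER_LEN, p) == "regular"
    assert derive_label(8_000, 6, [just_over] + [0] * 4, MONOMER_LEN, p) == "pseudogenic"


# ----------------------------------------------------------- scan + classify

def test_scan_monomers_counts_and_strands():
    gene, nts = _template()
    rng = np.random.default_rng(1)
    b = simulate.build_5s_array(gene, nts, 5, "regular", seed=2)
    read = simulate.random_seq(200, rng) + b.sequence + simulate.random_seq(200, rng)
    hits = rdna5s.scan_monomers(read, gene)
    assert len(hits) == 5
    hits_rc = rdna5s.scan_monomers(revcomp(read), gene)
    assert len(hits_rc) == 5
    assert all(h.strand == "-" for h in hits_rc)


def test_scan_monomers_detection_threshold():
    # lightly diverged genes are found, heavily pseudogenized ones are not
    gene, nts = _template()
    rng = np.random.default_rng(3)
    near = simulate.mutate(gene, 0.03, rng)
    far = simulate.mutate(gene, 0.50, rng)
    read = (simulate.random_seq(500, rng) + near + nts
            + far + nts + simulate.random_seq(500, rng))
    hits = rdna5s.scan_monomers(read, gene)
    assert len(hits) == 1
    assert abs(hits[0].start - 500) <= 3


def test_classify_reads_labels_rederivable():
    gene, nts = _template()
    monomer = Monomer5S(gene, nts)
    rng = np.random.default_rng(4)
    reads = []
    for i, mode in enumerate(("regular", "regular", "pseudogenic", "long_nts")):
        b = simulate.build_5s_array(gene, nts, 7, mode, seed=10 + i)
        seq = simulate.random_seq(150, rng) + b.sequence + simulate.random_seq(150, rng)
        reads.append(Read(f"{mode}{i}", seq))
    calls, no_call = rdna5s.classify_reads(ReadSet(reads), monomer)
    assert no_call == 0
    for call in calls:
        # every label is re-derivable from the reported fields
        assert call.label == derive_label(call.read_length, call.monomer_count,
                                          call.gaps, len(monomer))
    by_id = {c.read_id: c.label for c in calls}
    assert by_id["regular0"] == "regular"
    assert by_id["pseudogenic2"] == "pseudogenic"
    assert by_id["long_nts3"] in ("regular", "potentially_regular")


# ----------------------------------------------------------- reconstruction

def test_reconstruct_gene_from_short_reads():
    gene, nts = _template()
    b = simulate.build_5s_array(gene, nts, 30, "regular", seed=5, divergence=0.01)
    rng = np.random.default_rng(6)
    genome = simulate.random_seq(20_000, rng) + b.sequence + simulate.random_seq(20_000, rng)
    rs = simulate.simulate_short_reads(
        genome, simulate.ShortReadParams(n_pairs=1_500, error_rate=0.005), seed=7)
    seed_gene = simulate.mutate(gene, 0.10, rng)   # diverged relative as seed
    recon, frac = rdna5s.reconstruct_gene(rs, seed_gene)
    ident = sum(a == b2 for a, b2 in zip(recon, gene)) / len(gene)
    assert ident >= 0.98
    # mapped fraction approximates the array's genome share
    true_share = len(b.sequence) * (121 / MONOMER_LEN) / len(genome)
    assert 0.3 * true_share < frac < 3 * true_share


def test_build_monomer_period_recovery():
    gene, nts = _template()
    reads = []
    for i in range(6):
        b = simulate.build_5s_array(gene, nts, 6, "regular", seed=20 + i, divergence=0.01)
        reads.append(Read(f"arr{i}", b.sequence))
    monomer, used, n_units = rdna5s.build_monomer(ReadSet(reads), gene)
    assert used == 6 and n_units >= 20
    assert abs(len(monomer) - MONOMER_LEN) <= 10


def test_build_monomer_requires_periodicity():
    gene, nts = _template()
    rng = np.random.default_rng(8)
    junk = ReadSet([Read("x", simulate.random_seq(5_000, rng))])
    with pytest.raises(ValueError, match="periodicity"):
        rdna5s.build_monomer(junk, gene)


# ---------------------------------------------------------------- variants

def test_nts_variants_flags_elongation_with_repetition():
    gene, nts = _template()
    monomer = Monomer5S(gene, nts)
    reads, rng = [], np.random.default_rng(9)
    for i in range(5):
        mode = "long_nts" if i == 0 else "regular"
        b = simulate.build_5s_array(gene, nts, 7, mode, seed=40 + i)
        reads.append(Read(f"r{i}", b.sequence))
    rs = ReadSet(reads)
    calls, _ = rdna5s.classify_reads(rs, monomer)
    variants = rdna5s.nts_variants(calls, reads=rs, monomer=monomer)
    elongated = [v for v in variants if v.kind == "elongated"]
    assert len(elongated) >= 1
    assert all(v.read_id == "r0" for v in elongated)
    assert any(v.internal_repetition for v in elongated)


def test_has_internal_repetition():
    rng = np.random.default_rng(10)
    plain = simulate.random_seq(600, rng)
    assert not rdna5s.has_internal_repetition(plain)
    seg = plain[100:400]
    dup = plain[:400] + seg + plain[400:]
    assert rdna5s.has_internal_repetition(dup)


def test_region_divergence_counts_variable_columns():
    aligned = ["AACCGGTT", "AACCGGAA", "AACCGCAT"]
    out = rdna5s.region_divergence(aligned, {"box": (0, 4)})
    assert out["box"] == 0.0
    assert out["remainder"] == pytest.approx(3 / 4)


def test_gc_content():
    assert rdna5s.gc_content("GGCC") == 1.0
    assert rdna5s.gc_content("AATT") == 0.0
    assert rdna5s.gc_content("GANC") == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        rdna5s.gc_content("NNN")


def test_monomer_read_share_rounding():
    out = rdna5s.monomer_read_share(319, 4_540_941)
    assert out["percent"] == pytest.approx(100 * 319 / 4_540_941)
    assert out["percent_rounded"] == 0.007
    assert out["percent_4sig"] == pytest.approx(0.007025, abs=5e-7)
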