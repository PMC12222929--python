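import numpy as np
import pytest

from repeatome import simulate
from repeatome._alignment import global_identity, revcomp


def test_encode_decode_roundtrip():
    s = "ACGTTGCA"
    assert simulate.decode(simulate.encode(s)) == s


def test_mutate_rate_and_transition_bias():
    rng = np.random.default_rng(0)
    seq = simulate.random_seq(20_000, rng)
    out = simulate.mutate(seq, 0.10, rng)
    diffs = sum(a != b for a, b in zip(seq, out))
    assert 0.08 < diffs / len(seq) < 0.12
    transitions = sum(1 for a, b in zip(seq, out)
                      if a != b and {a, b} in ({"A", "G"}, {"C", "T"}))
    assert transitions / diffs > 0.55   # ts:tv 2:1 -> ~2/3 transitions


def test_ltr_template_structure():
    t = simulate.build_ltr_element(4600, 500, seed=11)
    names = [f[0] for f in t.features]
    assert names == ["LTR5", "PBS", "GAG", "PR", "RT", "RH", "INT", "PPT", "LTR3"]
    l5, l3 = t.feature("LTR5"), t.feature("LTR3")
    assert t.sequence[l5[0]:l5[1]] == t.sequence[l3[0]:l3[1]]
    assert set(t.domain_proteins) == {"GAG", "PR", "RT", "RH", "INT"}


def test_ltr_template_too_small():
    with pytest.raises(ValueError, match="RT"):
        simulate.build_ltr_element(300, 500, seed=1)


def test_tir_template_inverted_repeats():
    t = simulate.build_tir_element(1900, 50, seed=12)
    assert t.sequence[:50] == revcomp(t.sequence[-50:])


def test_genome_proportions_match_ground_truth():
    fam = simulate.FamilySpec(simulate.build_ltr_element(4600, 500, seed=1), 0.10)
    g, truth = simulate.build_genome(simulate.GenomeSpec(300_000, families=(fam,), seed=2))
    assert len(g) == 300_000
    planted = truth.family_bp("LTR_element")
    assert truth.proportions["LTR_element"] == pytest.approx(planted / 300_000)
    assert abs(planted / 300_000 - 0.10) <= 0.011   # within +-10% relative
    # recorded copies really are diverged template copies
    c = truth.copies[0]
    seg = g[c.start:c.end] if c.strand == "+" else revcomp(g[c.start:c.end])
    assert global_identity(seg, fam.template.sequence) > 0.95


def test_short_reads_match_genome_coordinates():
    rng = np.random.default_rng(5)
    g = simulate.random_seq(5_000, rng)
    rs = simulate.simulate_short_reads(g, simulate.ShortReadParams(n_pairs=50, error_rate=0.0), seed=3)
    assert len(rs) == 100
    for r in rs:
        s, e, strand = rs.sources[r.id]
        seg = g[s:e]
        assert r.sequence == (seg if strand == "+" else revcomp(seg))


def test_long_read_lengths_and_sources():
    rng = np.random.default_rng(6)
    g = simulate.random_seq(100_000, rng)
    params = simulate.LongReadParams(n_reads=30, length_range=(500, 20_000), error_rate=0.0)
    rs = simulate.simulate_long_reads(g, params, seed=4)
    for r in rs:
        s, e, strand = rs.sources[r.id]
        assert 500 <= e - s <= 20_000
        seg = g[s:e]
        assert r.sequence == (seg if strand == "+" else revcomp(seg))


def test_5s_array_regular_lengths():
    rng = np.random.default_rng(7)
    gene = simulate.random_seq(121, rng, 0.53)
    nts = simulate.random_seq(977, rng)
    b = simulate.build_5s_array(gene, nts, 5, "regular", seed=8, divergence=0.0)
    assert len(b.sequence) == 5 * 1098
    assert b.nts_lengths == (977,) * 5
    assert all(m.detectable for m in b.monomers)


def test_5s_array_pseudogenic_structure_rederivable():
    rng = np.random.default_rng(9)
    gene = simulate.random_seq(121, rng, 0.53)
    nts = simulate.random_seq(977, rng)
    for seed in range(20):
        b = simulate.build_5s_array(gene, nts, 8, "pseudogenic", seed=seed)
        det = [m for m in b.monomers if m.detectable]
        # first/last intact and at least one major interruption between
        # detectable monomers (spacer or hyper-mutated monomer)
        assert b.monomers[0].detectable and b.monomers[-1].detectable
        gaps = [b2.start - a2.end for a2, b2 in zip(det, det[1:])]
        assert any(g > 0.75 * 1098 for g in gaps)


def test_5s_array_long_nts_elongation():
    rng = np.random.default_rng(10)
    gene = simulate.random_seq(121, rng, 0.53)
    nts = simulate.random_seq(977, rng)
    b = simulate.build_5s_array(gene, nts, 6, "long_nts", seed=11)
    assert max(b.nts_lengths) > 977 + 977 // 3 - 1
    assert sum(1 for n in b.nts_lengths if n > 1.2 * 977) == 1
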