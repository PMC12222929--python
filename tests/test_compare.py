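import math

import numpy as np
import pytest

from repeatome import compare


def test_count_site_patterns_pairwise_deletion():
    #      v ts     v tv  v gap  v N
    a = "ACGTACGTAC-TAN"
    b = "ACATACTTACGTAG"
    pair = compare.count_site_patterns(a, b)
    assert pair.n == 12                      # gap and N columns dropped
    assert pair.transitions == 1             # G<->A
    assert pair.transversions == 1           # G<->T
    assert pair.P == pytest.approx(1 / 12)
    assert pair.Q == pytest.approx(1 / 12)


def test_count_site_patterns_requires_alignment():
    with pytest.raises(ValueError):
        compare.count_site_patterns("ACGT", "ACG")
    with pytest.raises(ValueError):
        compare.count_site_patterns("NN--", "NNNN")


def test_k2p_closed_form_value():
    # independent oracle: d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)] at P=0.10, Q=0.05
    oracle = -0.5 * math.log((1 - 0.20 - 0.05) * math.sqrt(1 - 0.10))
    assert oracle == pytest.approx(0.1702, abs=5e-5)
    assert compare.k2p_from_pq(0.10, 0.05) == pytest.approx(oracle, rel=1e-12)


def test_k2p_q_zero_reduces_to_transition_only_form():
    # with Q=0: d = -1/2 ln(1-2P), the Jukes-Cantor-style transition limit
    for P in (0.01, 0.05, 0.15):
        assert compare.k2p_from_pq(P, 0.0) == pytest.approx(-0.5 * math.log(1 - 2 * P))


def test_k2p_saturation_raises():
    with pytest.raises(ValueError, match="saturation"):
        compare.k2p_from_pq(0.40, 0.25)
    with pytest.raises(ValueError, match="saturation"):
        compare.k2p_from_pq(0.10, 0.50)


def test_k2p_distance_identical_and_min_sites():
    assert compare.k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0
    with pytest.raises(ValueError, match="comparable"):
        compare.k2p_distance("ACGT" * 4, "ACGT" * 4)


def test_k2p_at_least_p_distance():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    a = "".join(rng.choice(bases, 2000))
    codes = np.frombuffer(a.encode(), dtype=np.uint8)
    lut = np.zeros(256, np.int8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    v = lut[codes].copy()
    hit = rng.random(2000) < 0.15
    v[hit] = (v[hit] + rng.integers(1, 4, hit.sum())) % 4
    b = "".join("ACGT"[i] for i in v)
    assert compare.k2p_distance(a, b) >= compare.p_distance(a, b)


def test_distance_matrix_symmetric_and_ordered():
    rng = np.random.default_rng(1)
    base = "".join(rng.choice(list("ACGT"), 500))

    def mut(seq, rate, seed):
        r = np.random.default_rng(seed)
        out = list(seq)
        for i in range(len(out)):
            if r.random() < rate:
                out[i] = r.choice([c for c in "ACGT" if c != out[i]])
        return "".join(out)

    seqs = {"a": base, "b": mut(base, 0.02, 2), "c": mut(base, 0.15, 3)}
    df, order = compare.distance_matrix(seqs)
    assert np.allclose(df.values, df.values.T)
    assert np.allclose(np.diag(df.values), 0)
    # a and b are nearest neighbours, so they are adjacent in the leaf order
    assert abs(order.index("a") - order.index("b")) == 1
    assert df.loc["a", "b"] < df.loc["a", "c"]


def test_tajima_rrt_constructed_counts():
    # 50 columns: 10 where only seq1 differs, 4 where only seq2 differs,
    # 2 where all three differ (uninformative), rest identical.
    n = 50
    out = ["A"] * n
    s1 = ["A"] * n
    s2 = ["A"] * n
    for i in range(10):
        s1[i] = "G"
    for i in range(10, 14):
        s2[i] = "C"
    s1[14], s2[14] = "G", "C"
    s1[15], s2[15] = "C", "G"
    res = compare.tajima_rrt("".join(s1), "".join(s2), "".join(out))
    assert (res.m1, res.m2) == (10, 4)
    assert res.chi2 == pytest.approx((10 - 4) ** 2 / 14)
    sym = compare.tajima_rrt("".join(s2), "".join(s1), "".join(out))
    assert (sym.m1, sym.m2) == (4, 10)
    assert sym.p_value == pytest.approx(res.p_value)
    assert 0 < res.p_value < 1


def test_tajima_rrt_equal_rates():
    res = compare.tajima_rrt("ACGT" * 10, "ACGT" * 10, "AAGT" * 10)
    assert res.chi2 == 0.0 and res.p_value == 1.0


def test_abundance_matrix_layers():
    rows = [
        ("SAT_A", {"HVIS": 200, "PRUP": 100}),
        ("SAT_A", {"HVIS": 100, "PRUP": 0}),     # second cluster, same repeat
        ("LTR_B", {"HVIS": 50, "PRUP": 150}),
    ]
    m = compare.abundance_matrix(rows, {"HVIS": 1_000_000, "PRUP": 500_000})
    assert m.counts.loc["SAT_A", "HVIS"] == 300
    assert m.within_genome.loc["SAT_A", "HVIS"] == pytest.approx(3e-4)
    assert m.within_genome.loc["LTR_B", "PRUP"] == pytest.approx(3e-4)
    assert m.relative_share.loc["SAT_A", "HVIS"] == pytest.approx(0.75)
    assert np.allclose(m.relative_share.sum(axis=1), 1.0)


def test_abundance_matrix_missing_totals():
    with pytest.raises(ValueError, match="missing"):
        compare.abundance_matrix([("r", {"X": 1})], {"Y": 10})
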