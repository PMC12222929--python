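import numpy as np
import pytest

from repeatome import consensus, simulate
from repeatome._alignment import revcomp
from repeatome.prep import Read, ReadSet


def test_majority_consensus_rules():
    aligned = ["ACGT-A", "ACGTTA", "ACATTA", "AC-TTA"]
    # col2: G,G,A,- -> G; col4: -,T,T,T -> T
    assert consensus.majority_consensus(aligned) == "ACGTTA"
    # gap-majority column is removed
    assert consensus.majority_consensus(["A-C", "A-C", "AGC"]) == "AC"
    # two-way tie becomes an IUPAC ambiguity code
    assert consensus.majority_consensus(["A", "G"]) == "R"


def test_msa_consensus_recovers_template():
    rng = np.random.default_rng(0)
    template = simulate.random_seq(400, rng)
    copies = [simulate.mutate(template, 0.05, np.random.default_rng(s)) for s in range(12)]
    cons = consensus.msa_consensus(copies)
    from repeatome._alignment import global_identity
    assert global_identity(cons, template) >= 0.98


def test_msa_consensus_needs_copies():
    with pytest.raises(ValueError):
        consensus.msa_consensus(["ACGT"])


def test_map_refine_fixes_planted_errors():
    rng = np.random.default_rng(1)
    truth = simulate.random_seq(500, rng)
    draft = list(truth)
    for pos in (100, 250, 400):
        draft[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[draft[pos]]
    draft = "".join(draft)
    reads = []
    for i in range(120):
        s = int(rng.integers(0, 400))
        seq = truth[s:s + 100]
        reads.append(Read(f"r{i}", seq if i % 2 else revcomp(seq)))
    polished = consensus.map_refine(draft, ReadSet(reads))
    assert polished == truth


def test_detect_terminal_repeats_ltr_and_tir():
    ltr = simulate.build_ltr_element(2500, 300, seed=2)
    kind, left, right = consensus.detect_terminal_repeats(ltr.sequence)
    assert kind == "LTR"
    assert left[0] <= 5 and right[1] >= len(ltr.sequence) - 5
    assert left[1] - left[0] >= 250

    tir = simulate.build_tir_element(1200, 40, seed=3)
    kind, left, right = consensus.detect_terminal_repeats(tir.sequence)
    assert kind == "TIR"
    assert left[0] <= 5 and right[1] >= len(tir.sequence) - 5

    rng = np.random.default_rng(4)
    assert consensus.detect_terminal_repeats(simulate.random_seq(2_000, rng)) is None


def test_annotate_domains_order():
    t = simulate.build_ltr_element(4000, 300, seed=5)
    hits = consensus.annotate_domains(t.sequence, t.domain_proteins)
    assert [h.name for h in hits] == ["GAG", "PR", "RT", "RH", "INT"]
    for h, name in zip(hits, ("GAG", "PR", "RT", "RH", "INT")):
        s, e = t.feature(name)
        assert abs(h.start - s) < 60 and abs(h.end - e) < 60
        assert h.strand == "+"


def test_annotate_domains_reverse_strand():
    t = simulate.build_ltr_element(4000, 300, seed=6)
    hits = consensus.annotate_domains(revcomp(t.sequence), t.domain_proteins)
    assert [h.name for h in hits] == ["INT", "RH", "RT", "PR", "GAG"]
    assert all(h.strand == "-" for h in hits)


def test_annotate_35s_order_and_spacers():
    unit = simulate.build_35s_unit(seed=7)
    refs = {g: unit.sequence[slice(*unit.feature(g))] for g in ("18S", "5.8S", "26S")}
    res = consensus.annotate_35s(unit.sequence, refs)
    assert res["strand"] == "+"
    names = [f[0] for f in res["features"]]
    assert names == ["ETS5", "18S", "ITS1", "5.8S", "ITS2", "26S", "IGS"]
    rev = consensus.annotate_35s(revcomp(unit.sequence), refs)
    assert rev["strand"] == "-"
    assert [f[0] for f in rev["features"]] == names


def test_search_and_reconstruct_end_to_end():
    # small full pipeline: planted element, long reads, contig probe
    fam = simulate.FamilySpec(simulate.build_ltr_element(1800, 200, seed=8),
                              0.25, per_copy_divergence=0.04)
    genome, truth = simulate.build_genome(
        simulate.GenomeSpec(60_000, families=(fam,), seed=9))
    long_reads = simulate.simulate_long_reads(
        genome, simulate.LongReadParams(n_reads=80, length_range=(1_000, 20_000),
                                        median_length=6_000, error_rate=0.06), seed=10)
    c = truth.copies[0]
    probe = genome[c.start:c.end]

    hits = consensus.search_long_reads(probe, long_reads, top=10)
    assert hits
    hit_ids = {h.read_id for h in hits}
    carrying = {r.id for r in long_reads
                if any(min(e, long_reads.sources[r.id][1]) - max(s, long_reads.sources[r.id][0]) > 500
                       for s, e, _ in truth.intervals("LTR_element"))}
    assert hit_ids <= carrying

    rc = consensus.reconstruct(probe, long_reads,
                               domain_db=fam.template.domain_proteins, name="LTR_element")
    from repeatome._alignment import global_identity
    ident = max(global_identity(rc.sequence, fam.template.sequence),
                global_identity(revcomp(rc.sequence), fam.template.sequence))
    assert ident >= 0.95
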