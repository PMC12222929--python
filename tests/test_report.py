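import json

import numpy as np
import pandas as pd
import pytest

from repeatome import compare, report, simulate
from repeatome._alignment import revcomp
from repeatome.cluster import Annotation, ReadCluster


def test_self_dotplot_tandem_offset():
    rng = np.random.default_rng(0)
    monomer = simulate.random_seq(1_000, rng)
    plot = report.self_dotplot(monomer + monomer)
    offsets = {x - y for x, y in plot.forward}
    assert 0 in offsets          # identity diagonal
    assert 1000 in offsets       # tandem-repeat diagonal at the monomer period
    assert -1000 in offsets
    # the period diagonal is fully populated, not a chance hit
    n_period = sum(1 for x, y in plot.forward if x - y == 1000)
    assert n_period >= 1_000 - plot.spec.word_size


def test_self_dotplot_random_sequence_mostly_diagonal():
    rng = np.random.default_rng(1)
    seq = simulate.random_seq(200, rng)
    plot = report.self_dotplot(seq)
    off_diag = [p for p in plot.forward if p[0] != p[1]]
    assert len(off_diag) <= 2        # expected chance matches << 1
    assert len(plot.forward) >= 200 - 10 + 1


def test_dotplot_reverse_layer():
    rng = np.random.default_rng(2)
    a = simulate.random_seq(300, rng)
    plot = report.dotplot(a, revcomp(a))
    assert len(plot.reverse) >= 300 - 10 + 1   # anti-diagonal on the reverse layer
    xy_sum = {x + y for x, y in plot.reverse}
    assert len(xy_sum) <= 3


def test_dotplot_zoom_and_dense():
    rng = np.random.default_rng(3)
    monomer = simulate.random_seq(400, rng)
    plot = report.self_dotplot(monomer + monomer)
    dense = plot.to_dense(bin_size=50)
    assert dense.shape == (16, 16)
    assert dense.trace() > 0
    z = plot.zoom(0, 0)
    assert z.x_length == 500 and z.y_length == 500
    assert all((p < 500).all() for p in z.forward)
    assert len(z.forward) == sum(1 for x, y in plot.forward if x < 500 and y < 500)


def test_dotplot_rejects_short_input():
    with pytest.raises(ValueError):
        report.dotplot("ACGT")


def _clusters():
    ann = Annotation("SAT_A", "satellite", "nucleotide", 1e-30, 0.98, 250)
    return [
        ReadCluster("CL0001", tuple(f"a{i}" for i in range(50)), 0.5, annotation=ann, reported=True),
        ReadCluster("CL0002", tuple(f"b{i}" for i in range(30)), 0.3, reported=True),
        ReadCluster("CL0003", ("c0",), 0.01, reported=False),
    ]


def test_cluster_table_contents():
    table = report.cluster_table(_clusters(), 100)
    assert list(table["reads"]) == [50, 30, 1]
    assert table.loc[0, "annotation"] == "SAT_A"
    assert table.loc[0, "genome_proportion"] == pytest.approx(0.5)
    assert not table.loc[2, "reported"]


def test_render_reports_writes_figures_and_tables(tmp_path):
    rng = np.random.default_rng(4)
    matrix = compare.abundance_matrix(
        [("SAT_A", {"X": 300, "Y": 100}), ("LTR_B", {"X": 10, "Y": 90})],
        {"X": 1_000, "Y": 1_000})
    base = simulate.random_seq(400, rng)
    seqs = {"X": base,
            "Y": simulate.mutate(base, 0.03, rng),
            "Z": simulate.mutate(base, 0.20, rng)}
    dist, order = compare.distance_matrix(seqs)
    # abundance columns must cover the heatmap species order
    matrix = compare.abundance_matrix(
        [("SAT_A", {"X": 300, "Y": 100, "Z": 5}), ("LTR_B", {"X": 10, "Y": 90, "Z": 1})],
        {"X": 1_000, "Y": 1_000, "Z": 1_000})
    produced = report.render_reports(
        _clusters(), 100, tmp_path, abundance=matrix,
        distances=(dist, order), dotplots={"sat": base + base})
    for key in ("cluster_sizes", "abundance", "distance_heatmap", "dotplot_sat", "summary"):
        assert produced[key].exists()
        if produced[key].suffix == ".png":
            assert produced[key].with_suffix(".tsv").exists()

    summary = json.loads(produced["summary"].read_text())
    assert summary["total_reads"] == 100
    assert summary["reported_clusters"] == 2
    assert summary["repeat_fraction"] == pytest.approx(0.8)

    # every figure's TSV reproduces the plotted numbers
    heat = pd.read_csv(produced["distance_heatmap"].with_suffix(".tsv"),
                       sep="\t", index_col=0)
    assert list(heat.columns) == list(order)
    assert np.allclose(heat.values, dist.loc[list(order), list(order)].values)

    pts = pd.read_csv(produced["dotplot_sat"].with_suffix(".tsv"), sep="\t")
    plot = report.self_dotplot(base + base)
    assert len(pts) == len(plot.forward) + len(plot.reverse)
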