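"""Figures and tabular outputs for repeatome analyses.

Every rendered figure is backed by a plain-text table written next to it, so
results remain inspectable without an image viewer. Dotplots are computed as
exact word matches (default word size 10) on both strands, mirroring the
self-comparison views used to visualise tandem monomer structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ._alignment import revcomp
from .cluster import ReadCluster
from .compare import AbundanceMatrix


@dataclass(frozen=True)
class DotplotSpec:
    """Parameters of a word-match dotplot view."""

    word_size: int = 10
    zoom_window: int = 500   # side length (bp) of a zoomed-in panel


@dataclass
class Dotplot:
    """Exact word-match coordinates of a sequence self/pair comparison."""

    x_length: int
    y_length: int
    spec: DotplotSpec
    forward: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))
    reverse: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    def to_dense(self, bin_size: int = 1) -> np.ndarray:
        """Dense matrix of match counts; +1 for forward, -1 for reverse hits."""
        ny = -(-self.y_length // bin_size)
        nx = -(-self.x_length // bin_size)
        grid = np.zeros((ny, nx), dtype=int)
        for x, y in self.forward:
            grid[y // bin_size, x // bin_size] += 1
        for x, y in self.reverse:
            grid[y // bin_size, x // bin_size] -= 1
        return grid

    def zoom(self, x_start: int, y_start: int) -> "Dotplot":
        """Sub-plot restricted to a zoom_window-sized square."""
        w = self.spec.zoom_window
        out = Dotplot(min(w, self.x_length - x_start),
                      min(w, self.y_length - y_start), self.spec)
        for name in ("forward", "reverse"):
            pts = getattr(self, name)
            if len(pts):
                keep = ((pts[:, 0] >= x_start) & (pts[:, 0] < x_start + w)
                        & (pts[:, 1] >= y_start) & (pts[:, 1] < y_start + w))
                setattr(out, name, pts[keep] - [x_start, y_start])
        return out


def _word_positions(seq: str, word: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - word + 1):
        index.setdefault(seq[i:i + word], []).append(i)
    return index


def dotplot(seq_x: str, seq_y: str | None = None,
            spec: DotplotSpec = DotplotSpec()) -> Dotplot:
    """Word-match dotplot of seq_y (rows) against seq_x (columns).

    With seq_y omitted this is a self-comparison; the main diagonal of the
    forward layer is kept (it shows as the identity line, as in standard
    dotplot tools).
    """
    seq_x = seq_x.upper()
    seq_y = seq_x if seq_y is None else seq_y.upper()
    w = spec.word_size
    if len(seq_x) < w or len(seq_y) < w:
        raise ValueError(f"sequences must be at least word_size={w} long")
    index = _word_positions(seq_x, w)
    fwd: list[tuple[int, int]] = []
    rev: list[tuple[int, int]] = []
    for j in range(len(seq_y) - w + 1):
        word_seq = seq_y[j:j + w]
        for i in index.get(word_seq, ()):
            fwd.append((i, j))
        for i in index.get(revcomp(word_seq), ()):
            rev.append((i, j))
    plot = Dotplot(len(seq_x), len(seq_y), spec)
    if fwd:
        plot.forward = np.array(fwd, dtype=int)
    if rev:
        plot.reverse = np.array(rev, dtype=int)
    return plot


def self_dotplot(seq: str, spec: DotplotSpec = DotplotSpec()) -> Dotplot:
    return dotplot(seq, None, spec)


def render_dotplot(plot: Dotplot, path: str | Path, title: str = "") -> Path:
    """Render match coordinates to an image and a TSV of the same points."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    if len(plot.forward):
        ax.plot(plot.forward[:, 0], plot.forward[:, 1], ".", ms=1,
                color="black", label="forward")
    if len(plot.reverse):
        ax.plot(plot.reverse[:, 0], plot.reverse[:, 1], ".", ms=1,
                color="red", label="reverse")
    ax.set_xlim(0, plot.x_length)
    ax.set_ylim(plot.y_length, 0)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("position (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    rows = ([(x, y, "+") for x, y in plot.forward]
            + [(x, y, "-") for x, y in plot.reverse])
    pd.DataFrame(rows, columns=["x", "y", "strand"]).to_csv(
        path.with_suffix(".tsv"), sep="\t", index=False)
    return path


def cluster_table(clusters: Sequence[ReadCluster], total_reads: int) -> pd.DataFrame:
    """Per-cluster summary table (sizes, proportions, annotations)."""
    rows = []
    for c in clusters:
        rows.append({
            "cluster": c.cluster_id,
            "supercluster": c.supercluster_id or "",
            "reads": c.size,
            "genome_proportion": c.size / total_reads,
            "annotation": c.annotation.name if c.annotation else "",
            "lineage": c.annotation.lineage if c.annotation else "",
            "reported": c.reported,
        })
    return pd.DataFrame(rows)


def render_cluster_sizes(clusters: Sequence[ReadCluster], total_reads: int,
                         path: str | Path, top: int = 30) -> Path:
    """Bar chart of the largest clusters as genome proportions, with TSV."""
    path = Path(path)
    table = cluster_table(clusters, total_reads).head(top)
    fig, ax = plt.subplots(figsize=(8, 4))
    labels = [f"{r.cluster}\n{r.annotation}" if r.annotation else r.cluster
              for r in table.itertuples()]
    ax.bar(range(len(table)), table["genome_proportion"] * 100.0, color="steelblue")
    ax.set_xticks(range(len(table)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("genome proportion (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    table.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    return path


def render_abundance(matrix: AbundanceMatrix, path: str | Path,
                     order: Sequence[str] | None = None) -> Path:
    """Bubble plot: bubble area = within-genome %, colour = relative share.

    ``order`` is a species (column) ordering, typically the leaf order of the
    distance heatmap so both figures line up."""
    path = Path(path)
    within = matrix.within_genome
    share = matrix.relative_share
    if order is not None:
        within = within[list(order)]
        share = share[list(order)]
    fig, ax = plt.subplots(figsize=(2 + 0.7 * len(within.columns),
                                    2 + 0.35 * len(within)))
    for yi, repeat in enumerate(within.index):
        for xi, species in enumerate(within.columns):
            pct = within.loc[repeat, species] * 100.0
            if pct <= 0:
                continue
            ax.scatter(xi, yi, s=30 + 60 * pct,
                       c=[share.loc[repeat, species]], cmap="viridis",
                       vmin=0.0, vmax=1.0, edgecolors="black", linewidths=0.3)
    ax.set_xticks(range(len(within.columns)))
    ax.set_xticklabels(within.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(within.index)))
    ax.set_yticklabels(within.index, fontsize=7)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    stacked = pd.concat({"within_genome": within, "relative_share": share},
                        names=["layer"])
    stacked.to_csv(path.with_suffix(".tsv"), sep="\t")
    return path


def render_distance_heatmap(dist: pd.DataFrame, order: Sequence[str],
                            path: str | Path) -> Path:
    """Heatmap of a distance matrix in clustering order, with TSV."""
    path = Path(path)
    ordered = dist.loc[list(order), list(order)]
    fig, ax = plt.subplots(figsize=(1.5 + 0.5 * len(order),
                                    1.5 + 0.5 * len(order)))
    im = ax.imshow(ordered.values, cmap="magma_r")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=7)
    for i in range(len(order)):
        for j in range(len(order)):
            ax.text(j, i, f"{ordered.iat[i, j]:.2f}", ha="center",
                    va="center", fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8, label="K2P distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    ordered.to_csv(path.with_suffix(".tsv"), sep="\t")
    return path


def write_summary(summary: Mapping[str, object], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str)
                    + "\n")
    return path


def render_reports(clusters: Sequence[ReadCluster], total_reads: int,
                   outdir: str | Path,
                   abundance: AbundanceMatrix | None = None,
                   distances: tuple[pd.DataFrame, Sequence[str]] | None = None,
                   dotplots: Mapping[str, str] | None = None) -> dict[str, Path]:
    """Render the standard report set into a directory; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    produced: dict[str, Path] = {}
    produced["cluster_sizes"] = render_cluster_sizes(
        clusters, total_reads, outdir / "cluster_sizes.png")
    if abundance is not None:
        produced["abundance"] = render_abundance(
            abundance, outdir / "abundance.png",
            order=distances[1] if distances is not None else None)
    if distances is not None:
        produced["distance_heatmap"] = render_distance_heatmap(
            distances[0], distances[1], outdir / "distances.png")
    for name, seq in (dotplots or {}).items():
        produced[f"dotplot_{name}"] = render_dotplot(
            self_dotplot(seq), outdir / f"dotplot_{name}.png", title=name)
    reported = [c for c in clusters if c.reported]
    produced["summary"] = write_summary({
        "total_reads": total_reads,
        "clusters": len(clusters),
        "reported_clusters": len(reported),
        "reads_in_reported_clusters": int(sum(c.size for c in reported)),
        "repeat_fraction": sum(c.size for c in reported) / total_reads,
    }, outdir / "summary.json")
    return produced
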