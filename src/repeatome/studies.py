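"""End-to-end simulation studies exercising the pipeline against ground truth.

Each study builds synthetic data with a known manifest, runs the relevant
pipeline stage(s), and returns plain dictionaries of summary numbers.  Study
conditions (family sizes, divergences, error rates, read counts) are fixed
design choices of the evaluation, not tunable knobs; they are documented in
``docs/methods.md``.

Clustering studies follow the pipeline's own operating protocol: deep
simulated sequencing is subsampled to ~0.5x genome coverage before
clustering, the regime in which similarity components track repeat families.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from . import cluster as cl
from . import compare, consensus, prep, rdna5s, simulate
from ._alignment import global_identity, revcomp

LTR_DOMAIN_ORDER = ("GAG", "PR", "RT", "RH", "INT")


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# clustering recovery


def _recovery_templates() -> tuple[simulate.FamilySpec, ...]:
    ltr = simulate.build_ltr_element(4600, 500, seed=11, name="LTR_fam")
    tir = simulate.build_tir_element(1900, 50, seed=12, name="TIR_fam")
    sat = simulate.build_satellite(300, seed=13, name="SAT_fam")
    return (
        simulate.FamilySpec(ltr, 0.10, per_copy_divergence=0.02),
        simulate.FamilySpec(tir, 0.05, per_copy_divergence=0.02),
        simulate.FamilySpec(sat, 0.01, per_copy_divergence=0.02, arrangement="tandem"),
    )


def clustering_recovery_study(seed: int, n_seeds: int = 5,
                              genome_length: int = 1_000_000,
                              n_pairs: int = 100_000,
                              subsample_pairs: int = 2_500) -> dict:
    """Plant three repeat families (10% / 5% / 1%), sequence deeply, subsample
    to ~0.5x coverage, cluster, annotate, and compare estimated against true
    genome proportions."""
    families = _recovery_templates()
    repeat_db = {f"{f.template.name}#{f.template.repeat_class}": f.template.sequence
                 for f in families}
    estimates: dict[str, list[float]] = {f.template.name: [] for f in families}
    truths: dict[str, list[float]] = {f.template.name: [] for f in families}

    cluster_share: dict[str, list[float]] = {f.template.name: [] for f in families}

    for rep in range(n_seeds):
        s = _sub_seed(seed, rep)
        genome, truth = simulate.build_genome(simulate.GenomeSpec(
            genome_length, families=families, seed=s))
        all_reads = simulate.simulate_short_reads(
            genome, simulate.ShortReadParams(n_pairs=n_pairs), seed=_sub_seed(s, 1))
        reads = prep.subsample(all_reads, subsample_pairs, seed=_sub_seed(s, 2))
        clusters = cl.build_clusters(reads)
        cl.annotate_clusters(clusters, reads, repeat_db=repeat_db)
        by_id = reads.by_id()
        # quantification targets: the annotated clusters' member reads
        family_targets: dict[str, list[str]] = {}
        by_name: dict[str, int] = {}
        for c in clusters:
            if c.annotation and not c.annotation.unclassified:
                by_name[c.annotation.name] = by_name.get(c.annotation.name, 0) + c.size
                family_targets.setdefault(c.annotation.name, []).extend(
                    by_id[rid].sequence for rid in c.read_ids)
        props = cl.quantify_by_mapping(family_targets, all_reads)
        for fam in families:
            name = fam.template.name
            estimates[name].append(props.get(name, 0.0))
            cluster_share[name].append(by_name.get(name, 0) / len(reads))
            truths[name].append(truth.proportions[name])

    per_family = {}
    rel_errors = []
    for name in estimates:
        est = float(np.mean(estimates[name]))
        tru = float(np.mean(truths[name]))
        rel = (est - tru) / tru
        rel_errors.append(abs(rel))
        per_family[name] = {
            "true_proportion": tru, "estimated_proportion": est,
            "relative_error": rel,
            "per_seed_estimates": [float(x) for x in estimates[name]],
            "per_seed_cluster_share": [float(x) for x in cluster_share[name]],
        }
    return {
        "n_seeds": n_seeds,
        "reads_clustered": 2 * subsample_pairs,
        "families": per_family,
        "max_abs_relative_error": max(rel_errors),
        "mean_abs_relative_error": float(np.mean(rel_errors)),
    }


# ---------------------------------------------------------------------------
# LTR consensus reconstruction


def ltr_reconstruction_study(seed: int, genome_length: int = 600_000,
                             target_proportion: float = 0.28,
                             per_copy_divergence: float = 0.05,
                             n_long_reads: int = 360,
                             n_short_pairs: int = 20_000) -> dict:
    """Reconstruct a planted LTR element (~30 copies at 5% divergence) from
    long reads, polish with short reads, and score against the template."""
    template = simulate.build_ltr_element(4600, 500, seed=21, name="LTR_target")
    genome, truth = simulate.build_genome(simulate.GenomeSpec(
        genome_length,
        families=(simulate.FamilySpec(template, target_proportion,
                                      per_copy_divergence=per_copy_divergence),),
        seed=_sub_seed(seed, 0)))
    long_reads = simulate.simulate_long_reads(
        genome, simulate.LongReadParams(n_reads=n_long_reads, median_length=10_000,
                                        length_sigma=0.6, error_rate=0.08,
                                        length_range=(1_000, 60_000)),
        seed=_sub_seed(seed, 1))
    short_reads = simulate.simulate_short_reads(
        genome, simulate.ShortReadParams(n_pairs=n_short_pairs),
        seed=_sub_seed(seed, 2))

    # the probe stands in for a cluster contig: one diverged genomic copy
    probe_copy = truth.copies[0]
    probe = genome[probe_copy.start:probe_copy.end]
    result = consensus.reconstruct(probe, long_reads, short_reads=short_reads,
                                   name=template.name)

    fwd = global_identity(result.sequence, template.sequence)
    rev = global_identity(revcomp(result.sequence), template.sequence)
    oriented = result.sequence if fwd >= rev else revcomp(result.sequence)
    domains = consensus.annotate_domains(oriented, template.domain_proteins)
    order = tuple(d.name for d in domains if d.name in LTR_DOMAIN_ORDER)
    return {
        "n_copies_planted": len(truth.copies),
        "n_copies_used": result.source_copy_count,
        "consensus_length": len(result.sequence),
        "template_length": len(template.sequence),
        "identity": max(fwd, rev),
        "terminal_repeat_kind": result.terminal_repeat_kind,
        "domain_order": list(order),
        "domain_order_correct": order == LTR_DOMAIN_ORDER,
    }


# ---------------------------------------------------------------------------
# 5S array classification


def _array_read(gene: str, nts: str, mode: str, n_monomers: int, seed: int,
                error_rate: float, rng: np.random.Generator,
                **kwargs) -> tuple[str, str]:
    build = simulate.build_5s_array(gene, nts, n_monomers, mode, seed, **kwargs)
    flank_l = simulate.random_seq(int(rng.integers(100, 400)), rng)
    flank_r = simulate.random_seq(int(rng.integers(100, 400)), rng)
    read = simulate.apply_indel_errors(flank_l + build.sequence + flank_r,
                                       error_rate, rng)
    return read, build.label


def array_classification_study(seed: int, per_class: int = 50,
                               error_rate: float = 0.02) -> dict:
    """Simulate long reads of the three array organizations with
    well-separated parameters, rebuild the monomer from the regular subset,
    classify all reads, and score precision/recall per class."""
    template = simulate.build_5s_template(seed=31)
    g0, g1 = template.feature("gene_5S")
    n0, n1 = template.feature("NTS")
    gene, nts = template.sequence[g0:g1], template.sequence[n0:n1]
    rng = np.random.default_rng(_sub_seed(seed, 0))

    reads: list[prep.Read] = []
    truth: dict[str, str] = {}
    plans = (
        # (truth label, build mode, monomer-count sampler, build kwargs)
        ("regular", "regular", lambda: int(rng.integers(6, 9)), {}),
        ("potentially_regular", "regular", lambda: 3, {}),
        ("pseudogenic", "pseudogenic", lambda: 8,
         {"hyper_fraction": 0.25, "spacer_monomers": 1.5}),
    )
    i = 0
    for label, mode, n_fn, kwargs in plans:
        for _ in range(per_class):
            seq, _ = _array_read(gene, nts, mode, n_fn(), _sub_seed(seed, 100 + i),
                                 error_rate, rng, **kwargs)
            rid = f"lr{i}"
            reads.append(prep.Read(rid, seq))
            truth[rid] = label
            i += 1
    readset = prep.ReadSet(reads, provenance=["array_classification_study"])

    regular_set = prep.ReadSet([r for r in reads if truth[r.id] == "regular"])
    monomer, used, n_monomers = rdna5s.build_monomer(regular_set, gene)
    calls, no_call = rdna5s.classify_reads(readset, monomer)

    labels = ("regular", "potentially_regular", "pseudogenic")
    predicted = {c.read_id: c.label for c in calls}
    per_label = {}
    for lab in labels:
        tp = sum(1 for rid, t in truth.items() if t == lab and predicted.get(rid) == lab)
        pred_n = sum(1 for p in predicted.values() if p == lab)
        per_label[lab] = {
            "precision": tp / pred_n if pred_n else 0.0,
            "recall": tp / per_class,
        }
    return {
        "per_class": per_class,
        "monomer_length": len(monomer),
        "monomer_reads_used": used,
        "monomers_in_consensus": n_monomers,
        "no_call_reads": no_call,
        "calls": calls,
        "per_label": per_label,
        "min_precision": min(v["precision"] for v in per_label.values()),
        "min_recall": min(v["recall"] for v in per_label.values()),
    }


# ---------------------------------------------------------------------------
# K2P estimator consistency


def k2p_parameters_at(d: float, ts_tv: float = 2.0) -> tuple[float, float]:
    """Observed (P, Q) on the K2P model surface at distance ``d`` with the
    given expected transition/transversion ratio (P = ts_tv * Q)."""
    def f(q: float) -> float:
        return compare.k2p_from_pq(ts_tv * q, q) - d
    q = brentq(f, 1e-9, 1.0 / (2 * ts_tv + 1) - 1e-9)
    return ts_tv * q, q


def k2p_bias_study(seed: int, true_d: float = 0.1, n_sites: int = 1000,
                   n_reps: int = 200) -> dict:
    """Mean K2P estimate over replicate site patterns drawn at true d."""
    P, Q = k2p_parameters_at(true_d)
    rng = np.random.default_rng(_sub_seed(seed, 0))
    bases = "ACGT"
    # transitions in code space: A<->G (0,2), C<->T (1,3) => +2 mod 4
    anc = rng.integers(0, 4, size=(n_reps, n_sites))
    u = rng.random((n_reps, n_sites))
    other = anc.copy()
    ts = u < P
    tv = (u >= P) & (u < P + Q)
    other[ts] = (other[ts] + 2) % 4
    tv_shift = rng.choice([1, 3], size=int(tv.sum()))
    other[tv] = (other[tv] + tv_shift) % 4

    estimates = []
    for r in range(n_reps):
        a = "".join(bases[c] for c in anc[r])
        b = "".join(bases[c] for c in other[r])
        estimates.append(compare.k2p_distance(a, b))
    mean = float(np.mean(estimates))
    return {
        "true_d": true_d,
        "P": P,
        "Q": Q,
        "closed_form_check": compare.k2p_from_pq(P, Q),
        "n_reps": n_reps,
        "n_sites": n_sites,
        "mean_estimate": mean,
        "bias": mean - true_d,
        "sd": float(np.std(estimates, ddof=1)),
    }


# ---------------------------------------------------------------------------
# Tajima RRT calibration


def tajima_calibration_study(seed: int, n_sites: int = 1000, n_reps: int = 1000,
                             lineage_p: float = 0.05, outgroup_p: float = 0.15,
                             alpha: float = 0.05) -> dict:
    """Type-I error of the relative-rate test under equal lineage rates."""
    rng = np.random.default_rng(_sub_seed(seed, 0))
    bases = "ACGT"

    def mutate_codes(anc: np.ndarray, p: float) -> np.ndarray:
        out = anc.copy()
        mask = rng.random(anc.shape) < p
        out[mask] = (out[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
        return out

    anc = rng.integers(0, 4, size=(n_reps, n_sites))
    s1 = mutate_codes(anc, lineage_p)
    s2 = mutate_codes(anc, lineage_p)
    out = mutate_codes(anc, outgroup_p)

    rejections = 0
    for r in range(n_reps):
        a = "".join(bases[c] for c in s1[r])
        b = "".join(bases[c] for c in s2[r])
        o = "".join(bases[c] for c in out[r])
        if compare.tajima_rrt(a, b, o).p_value < alpha:
            rejections += 1
    return {
        "n_reps": n_reps,
        "n_sites": n_sites,
        "alpha": alpha,
        "rejections": rejections,
        "type_i_error": rejections / n_reps,
    }


# ---------------------------------------------------------------------------
# deterministic worked examples


def abundance_example() -> dict:
    """The two abundance-layer formulas on a fixed count table."""
    m = compare.abundance_matrix([("repeatX", {"A": 300, "B": 100})],
                                 {"A": 1_000_000, "B": 1_000_000})
    return {
        "relative_share_A": float(m.relative_share.loc["repeatX", "A"]),
        "within_genome_A": float(m.within_genome.loc["repeatX", "A"]),
        "relative_share_row_sum": float(m.relative_share.loc["repeatX"].sum()),
    }


def monomer_share_example() -> dict:
    """Percentage of long reads bearing a 5S monomer from published counts."""
    return rdna5s.monomer_read_share(319, 4_540_941)
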