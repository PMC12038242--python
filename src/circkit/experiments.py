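"""Self-contained benchmark experiments with known ground truth.

Each function builds its inputs with the synthetic-data generators, runs
one slice of the pipeline, and measures recovery against the planted
truth.  They are the package's acceptance surface: deterministic given a
seed, sized to run on one CPU in minutes, and returning plain dicts of
numbers.  Where a result is checked against an independent oracle (the
8-of-10 counting rule, the CLR closed form, BH step-up, pairwise AUC),
the oracle here is a direct brute-force transcription of the rule, kept
separate from the production code path it validates.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd

from . import classify as cls
from . import de as de_mod
from . import quant
from .discover import (
    BsjCatalog,
    BsjEntry,
    DetectorConfig,
    detect_anchor_backsplices,
    detect_annotated_backsplices,
    filter_candidates,
    union_catalogs,
)
from .index import KmerIndex
from .synth import (
    CircTruth,
    gene_abundances,
    generate_genome,
    plant_circrnas,
    simulate_cohort_matrix,
    simulate_library,
    transcript_weights,
)

# study-scale genome: ~2 Mb, 100 multi-exon genes
GENOME_KW = dict(
    n_chrom=1,
    n_genes=100,
    intron_len_range=(500, 3000),
    intergenic_len_range=(2000, 8000),
)


def _catalog_from_truth(truths: list[CircTruth], genome) -> BsjCatalog:
    """Catalog built directly from planted coordinates (quantification-only runs)."""
    entries = [
        BsjEntry(
            chrom=t.chrom,
            strand=t.strand,
            start=t.bsj_start,
            end=t.bsj_end,
            gene_id=t.gene_id,
            support=0,
            detectors={"truth": 0},
        )
        for t in truths
    ]
    entries.sort(key=lambda e: (e.chrom, e.start, e.end))
    return BsjCatalog(entries=entries)


def discovery_recovery(seed: int = 1, n_circ: int = 60, depth: int = 400_000) -> dict:
    """De novo BSJ discovery on error-free RNase R reads.

    Recall is measured over planted circRNAs covered by at least 10
    junction-spanning fragments (the read names say which), precision
    over every catalogued call, both at exact coordinates.
    """
    genome = generate_genome(seed=seed, **GENOME_KW)
    truths = plant_circrnas(genome, n_circ, seed=seed + 1)
    lib = simulate_library(
        genome, truths, rnase_r=True, depth=depth, error_rate=0.0, seed=seed + 2
    )
    junction_frags = pd.Series(
        [o.ref_id for o in lib.origins() if o.kind == "circ" and o.spans_bsj]
    ).value_counts()
    eligible = {
        t.circ_id: (t.chrom, t.bsj_start, t.bsj_end)
        for t in truths
        if junction_frags.get(t.circ_id, 0) >= 10
    }
    config = DetectorConfig()
    index = KmerIndex(genome.chromosomes, config.anchor_len)
    catalog = union_catalogs(
        filter_candidates(detect_anchor_backsplices(lib, index, config), genome.genes, config),
        filter_candidates(
            detect_annotated_backsplices(lib, index, genome.genes, config), genome.genes, config
        ),
    )
    called = catalog.coordinate_set()
    planted_all = {(t.chrom, t.bsj_start, t.bsj_end) for t in truths}
    tp_eligible = sum(1 for key in eligible.values() if key in called)
    precision = (
        sum(1 for key in called if key in planted_all) / len(called) if called else float("nan")
    )
    return {
        "recall": tp_eligible / len(eligible) if eligible else float("nan"),
        "precision": precision,
        "n_eligible": len(eligible),
        "n_called": len(called),
        "n_planted": len(truths),
    }


def bsj_counting_oracle(seed: int = 1, n_placements: int = 1000) -> dict:
    """count_bsj vs brute-force 8-of-10 window enumeration on random placements."""
    rng = np.random.default_rng(seed)
    offset, contig_len, mate_len = 100, 200, 150
    contig = "bsj|oracle"
    offsets = {contig: offset}
    names, placements = [], []
    for i in range(n_placements):
        pos = int(rng.integers(-mate_len, contig_len + 10))
        p1 = [(contig, pos, mate_len)]
        p2 = (
            [(contig, int(rng.integers(-mate_len, contig_len + 10)), mate_len)]
            if rng.random() < 0.5
            else []
        )
        names.append(f"frag{i}")
        placements.append((p1, p2))
    fp = quant.FragmentPlacements(names=names, placements=placements)
    fast = quant._count_junction_fragments(fp, offsets)[contig]

    # independent brute force: literal transcription of the rule
    window = set(range(offset - 5, offset + 5))
    slow = 0
    for p1, p2 in placements:
        counted = False
        for plist in (p1, p2):
            for _name, pos, length in plist:
                covered = set(range(pos, pos + length))
                if len(covered & window) >= 8:
                    counted = True
        slow += counted
    return {"agreement": float(fast == slow), "fast": fast, "brute_force": slow, "n": n_placements}


def clr_oracle(seed: int = 1, n_triples: int = 10_000) -> dict:
    """compute_clr vs exact rational #BSJ/(mean(#FSJ)+1) incl. absent-FSJ edges."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_triples):
        bsj = int(rng.integers(0, 500))
        fsj5 = None if rng.random() < 0.1 else int(rng.integers(0, 500))
        fsj3 = None if rng.random() < 0.1 else int(rng.integers(0, 500))
        got = quant.compute_clr(bsj, fsj5, fsj3)
        avail = [f for f in (fsj5, fsj3) if f is not None]
        expected = Fraction(bsj) / (
            (Fraction(sum(avail), len(avail)) if avail else Fraction(0)) + 1
        )
        if not math.isclose(got, float(expected), rel_tol=0, abs_tol=1e-12):
            mismatches += 1
    return {"agreement": float(mismatches == 0), "mismatches": mismatches, "n": n_triples}


def robust_filter_toy() -> dict:
    """20-feature toy matrix vs manual enumeration of the >=2-in->=3-replicates rule."""
    rng = np.random.default_rng(7)
    days = ["d0"] * 3 + ["d2"] * 3 + ["d6"] * 4
    samples = [f"s{i}" for i in range(10)]
    design = pd.DataFrame({"day": days}, index=samples)
    counts = pd.DataFrame(
        rng.integers(0, 4, size=(20, 10)), index=[f"f{i:02d}" for i in range(20)], columns=samples
    )
    kept = quant.robust_filter(counts, design, timepoint_col="day")
    manual = set()
    for f in counts.index:
        for day in set(days):
            cols = [s for s, d in zip(samples, days) if d == day]
            if len(cols) >= 3 and sum(counts.loc[f, c] >= 2 for c in cols) >= 3:
                manual.add(f)
    return {
        "agreement": float(set(kept.index) == manual),
        "n_kept": len(kept),
        "n_manual": len(manual),
        "n": 20,
    }


def de_calibration_and_recovery(seed: int = 1) -> dict:
    """NB Wald null calibration (5v5) and effect recovery (10v10, 5% planted)."""
    null = simulate_cohort_matrix(2000, 5, 0, dispersion=0.1, seed=seed)
    res0 = de_mod.nb_wald_test(null.counts, null.design, ("class", "healthy", "disease"))
    null_frac = float((res0["pvalue"] < 0.05).mean())

    planted = simulate_cohort_matrix(2000, 10, 100, effect_log2fc=2.0, dispersion=0.1,
                                     seed=seed + 1)
    res1 = de_mod.nb_wald_test(planted.counts, planted.design, ("class", "healthy", "disease"))
    inf = planted.truth["informative"]
    median_lfc = float(res1.loc[inf, "log2FoldChange"].median())
    pass_frac = float(
        ((res1.loc[inf, "log2FoldChange"].abs() > 1) & (res1.loc[inf, "padj"] < 0.05)).mean()
    )
    return {
        "null_fraction_p05": null_frac,
        "median_planted_log2fc": median_lfc,
        "planted_pass_fraction": pass_frac,
        "n_features": 2000,
    }


def bh_oracle(seed: int = 1, n_vectors: int = 1000) -> dict:
    """bh_adjust vs an independent step-up enumeration on random p-vectors."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        p = np.round(rng.random(m), 3)
        fast = de_mod.bh_adjust(p)
        # brute force: padj_i = min over k with p_(k) >= p_i of p_(k) * m / rank_k
        order = np.argsort(p, kind="stable")
        slow = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            candidates = [
                p[order[j]] * m / (j + 1) for j in range(rank_i - 1, m)
            ]
            slow[idx] = min(1.0, min(candidates))
        if not np.allclose(fast, slow, rtol=0, atol=1e-12):
            mismatches += 1
    return {"agreement": float(mismatches == 0), "mismatches": mismatches, "n": n_vectors}


def auc_oracle(seed: int = 1, n_sets: int = 1000) -> dict:
    """auc vs brute-force pairwise concordance, plus the two degenerate cases."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_sets):
        n = int(rng.integers(4, 40))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        fast = cls.auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum(
            1.0 if sp > sn else (0.5 if sp == sn else 0.0) for sp in pos for sn in neg
        )
        slow = conc / (len(pos) * len(neg))
        if not math.isclose(fast, slow, rel_tol=0, abs_tol=1e-12):
            mismatches += 1
    separated = cls.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    constant = cls.auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
    return {
        "agreement": float(mismatches == 0),
        "mismatches": mismatches,
        "separated_auc": separated,
        "constant_auc": constant,
        "n": n_sets,
    }


def feature_selection_recovery(seed: int = 1) -> dict:
    """Dual-rank recovery: planted informative features among the top-10."""
    cm = simulate_cohort_matrix(500, 20, 10, effect_log2fc=2.0, dispersion=0.1, seed=seed)
    X = np.log2(cm.counts + 1.0)
    y = (cm.design["class"] == "disease").astype(int).to_numpy()
    ranks = cls.rank_features(X, y, n_trees=500, seed=seed)
    top10 = set(ranks.index[:10])
    planted = set(cm.truth["informative"])
    return {"top10_planted": len(top10 & planted), "n_features": 500, "n_samples": 40}


def classifier_benchmark(seed: int = 1) -> dict:
    """Held-out AUC on a planted-effect cohort and null pooled 10-fold-CV AUC."""
    train = simulate_cohort_matrix(50, 30, 10, effect_log2fc=2.0, dispersion=0.1, seed=seed)
    test = simulate_cohort_matrix(50, 30, 10, effect_log2fc=2.0, dispersion=0.1, seed=seed + 1)
    y_tr = (train.design["class"] == "disease").astype(int).to_numpy()
    y_te = (test.design["class"] == "disease").astype(int).to_numpy()
    model = cls.tune_and_train_svm(np.log2(train.counts + 1.0), y_tr, seed=seed)
    held_out = cls.evaluate_on_cohort(model, np.log2(test.counts + 1.0), y_te)

    null = simulate_cohort_matrix(30, 50, 0, dispersion=0.1, seed=seed + 2)
    y_null = (null.design["class"] == "disease").astype(int).to_numpy()
    null_cv = cls.kfold_cv_classify(np.log2(null.counts + 1.0), y_null, k=10, seed=seed)
    return {
        "held_out_auc": held_out.auc,
        "null_cv_auc": null_cv.auc,
        "n_test": len(y_te),
        "n_null": len(y_null),
    }


def global_increase_recovery(
    seed: int = 1,
    fold: float = 2.8,
    n_genes: int = 60,
    n_circ: int = 40,
    depth: int = 30_000,
    replicates: int = 3,
) -> dict:
    """Recover a planted global circularization increase between two stages.

    The differentiated state multiplies every circRNA's output by
    ``fold`` while linear output is held constant in absolute fragments
    (depth compensation).  Reports the stage ratio of mean cumulative
    CPM-normalized BSJ counts and the stage ratio of total adjacent-FSJ
    counts.
    """
    genome = generate_genome(n_chrom=1, n_genes=n_genes, seed=seed)
    truths = plant_circrnas(genome, n_circ, seed=seed + 1)
    abund = gene_abundances(genome, seed=seed + 2)
    catalog = _catalog_from_truth(truths, genome)
    refs = quant.ReferenceSet.build(catalog, genome, genome.genes)

    w_ref = sum(transcript_weights(genome, truths, abundances=abund, circ_scale=1.0))
    states = {"progenitor": 1.0, "differentiated": fold}
    per_sample: dict[str, list] = {}
    lib_sizes: dict[str, int] = {}
    design_rows = []
    for state, scale in states.items():
        w = sum(transcript_weights(genome, truths, abundances=abund, circ_scale=scale))
        state_depth = int(round(depth * w / w_ref))
        for rep in range(replicates):
            sid = f"{state}_r{rep + 1}"
            lib = simulate_library(
                genome,
                truths,
                rnase_r=False,
                depth=state_depth,
                seed=seed + 10 + rep + (0 if scale == 1.0 else 100),
                sample_id=sid,
                abundances=abund,
                circ_scale=scale,
            )
            counts, libsize = quant.quantify_sample(lib, refs)
            per_sample[sid] = counts
            lib_sizes[sid] = libsize
            design_rows.append({"sample_id": sid, "stage": state})
    design = pd.DataFrame(design_rows).set_index("sample_id")
    matrix = quant.counts_to_matrix(per_sample)
    cpm = quant.compute_cpm(matrix, pd.Series(lib_sizes))
    metrics = quant.circ_metrics(cpm, matrix, design, stage_col="stage")
    cum = metrics.per_stage["cumulative_cpm"]
    cpm_ratio = float(cum["differentiated"] / cum["progenitor"])

    fsj_totals = {
        sid: sum((jc.fsj5 or 0) + (jc.fsj3 or 0) for jc in counts)
        for sid, counts in per_sample.items()
    }
    fsj = pd.Series(fsj_totals)
    fsj_ratio = float(
        fsj[design["stage"] == "differentiated"].mean()
        / fsj[design["stage"] == "progenitor"].mean()
    )
    return {
        "cumulative_cpm_ratio": cpm_ratio,
        "fsj_ratio": fsj_ratio,
        "planted_fold": fold,
        "n_samples": len(per_sample),
    }


def coherence_recovery(seed: int = 1, n_features: int = 200, concordant: float = 0.75) -> dict:
    """Quadrant coherence on cohorts with 75% concordant planted changes.

    Paired circRNA and host matrices are simulated with per-feature
    effects whose signs agree for a planted fraction of features; both
    are pushed through the NB Wald test and the estimated fold changes
    through the quadrant classifier.
    """
    rng = np.random.default_rng(seed)
    circ_sign = rng.choice([-1.0, 1.0], size=n_features)
    agree = rng.random(n_features) < concordant
    host_sign = np.where(agree, circ_sign, -circ_sign)
    magnitude = 1.5
    circ = simulate_cohort_matrix(
        n_features, 10, n_features, effect_log2fc=magnitude * circ_sign,
        dispersion=0.05, seed=seed + 1,
    )
    host = simulate_cohort_matrix(
        n_features, 10, n_features, effect_log2fc=magnitude * host_sign,
        dispersion=0.05, seed=seed + 2,
    )
    contrast = ("class", "healthy", "disease")
    res_c = de_mod.nb_wald_test(circ.counts, circ.design, contrast)
    res_h = de_mod.nb_wald_test(host.counts, host.design, contrast)
    q = quant.coherence_quadrants(
        res_c["log2FoldChange"].to_numpy(), res_h["log2FoldChange"].to_numpy()
    )
    q["planted_concordant"] = float(agree.mean())
    return q
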