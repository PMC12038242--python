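"""Quantification: contigs, 8-of-10 counting, CLR, CPM, metrics, quadrants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from circkit import quant
from circkit.discover import BsjCatalog, BsjEntry
from circkit.synth import GenomeModel


def _entry(chrom, start, end, gene_id="gene_x"):
    return BsjEntry(
        chrom=chrom, strand="+", start=start, end=end, gene_id=gene_id, support=5
    )


class TestJunctionLibrary:
    def test_contig_is_end_flank_plus_start_flank(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        genome = GenomeModel(chromosomes={"chr1": seq})
        cat = BsjCatalog(entries=[_entry("chr1", 100, 600)])
        (contig,) = quant.build_junction_library(cat, genome)
        assert contig.sequence == seq[500:600] + seq[100:200]
        assert contig.junction_offset == 100

    def test_short_circle_halves_truncated_without_duplication(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=500))
        genome = GenomeModel(chromosomes={"chr1": seq})
        cat = BsjCatalog(entries=[_entry("chr1", 100, 220)])  # 120 nt circle
        (contig,) = quant.build_junction_library(cat, genome)
        assert contig.junction_offset == 60
        assert contig.sequence == seq[160:220] + seq[100:160]
        assert len(contig.sequence) == 120

    def test_distinct_circles_distinct_ids(self):
        seq = "A" * 2000
        genome = GenomeModel(chromosomes={"chr1": seq})
        cat = BsjCatalog(entries=[_entry("chr1", 100, 600), _entry("chr1", 100, 900)])
        contigs = quant.build_junction_library(cat, genome)
        assert len({c.circ_id for c in contigs}) == 2


class TestWindowCounting:
    def test_eight_of_ten_rule_boundaries(self):
        off = 100
        # symmetric window [off-5, off+5); counting needs >= 8 nt covered
        assert quant.window_overlap(off - 5, 10, off) == 10
        assert quant.window_overlap(off - 5, 8, off) == 8  # [off-5, off+3) -> counted
        assert quant.window_overlap(off - 8, 10, off) == 7  # [off-8, off+2) -> not counted
        assert quant.window_overlap(off + 5, 150, off) == 0  # starts past the window

    def test_pair_over_window_counted_once(self):
        offsets = {"c": 100}
        both_mates = ([("c", 60, 150)], [("c", 40, 150)])
        fp = quant.FragmentPlacements(names=["f"], placements=[both_mates])
        assert quant._count_junction_fragments(fp, offsets)["c"] == 1

    def test_multimapped_fragment_counts_for_each_contig(self):
        offsets = {"c1": 100, "c2": 100}
        fp = quant.FragmentPlacements(
            names=["f"], placements=[([("c1", 60, 150), ("c2", 60, 150)], [])]
        )
        counts = quant._count_junction_fragments(fp, offsets)
        assert counts == {"c1": 1, "c2": 1}

    def test_brute_force_oracle_equivalence(self):
        """count machinery equals per-fragment overlap enumeration (random)."""
        rng = np.random.default_rng(42)
        offsets = {"c": 100}
        placements = []
        for _ in range(1500):
            p1 = [("c", int(rng.integers(-150, 220)), 150)]
            p2 = [("c", int(rng.integers(-150, 220)), 150)] if rng.random() < 0.6 else []
            placements.append((p1, p2))
        fp = quant.FragmentPlacements(
            names=[f"f{i}" for i in range(len(placements))], placements=placements
        )
        fast = quant._count_junction_fragments(fp, offsets)["c"]
        window = set(range(95, 105))
        slow = sum(
            any(
                len(set(range(pos, pos + ln)) & window) >= 8
                for plist in pair
                for (_n, pos, ln) in plist
            )
            for pair in placements
        )
        assert fast == slow


class TestClr:
    @pytest.mark.parametrize(
        ("bsj", "fsj5", "fsj3", "expected"),
        [
            (10, 4, 6, 10 / 6),
            (0, 7, 3, 0.0),
            (5, None, None, 5.0),
            (8, 4, None, 8 / 5),
            (8, None, 4, 8 / 5),
        ],
    )
    def test_formula(self, bsj, fsj5, fsj3, expected):
        assert quant.compute_clr(bsj, fsj5, fsj3) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            quant.compute_clr(-1, 0, 0)


class TestCpm:
    def test_value_and_scale_invariance(self):
        m = pd.DataFrame({"s1": [5, 0], "s2": [10, 0]}, index=["a", "b"])
        sizes = {"s1": 1_000_000, "s2": 2_000_000}
        cpm = quant.compute_cpm(m, sizes)
        assert cpm.loc["a", "s1"] == 5.0 and cpm.loc["a", "s2"] == 5.0
        assert (cpm.loc["b"] == 0).all()
        doubled = quant.compute_cpm(2 * m, {k: 2 * v for k, v in sizes.items()})
        pd.testing.assert_frame_equal(cpm, doubled)

    def test_sum_property(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.integers(0, 50, size=(30, 4)), columns=list("abcd"))
        sizes = m.sum(axis=0)
        cpm = quant.compute_cpm(m, sizes)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            quant.compute_cpm(pd.DataFrame({"s": [1]}), {"s": 0})


class TestRobustFilter:
    def _design(self):
        return pd.DataFrame(
            {"day": ["d0"] * 3 + ["d5"] * 3},
            index=[f"s{i}" for i in range(6)],
        )

    def test_rule_examples(self):
        design = self._design()
        m = pd.DataFrame(
            {
                "s0": [2, 2, 1], "s1": [2, 2, 1], "s2": [2, 0, 1],
                "s3": [0, 2, 1], "s4": [0, 2, 1], "s5": [0, 0, 1],
            },
            index=["kept", "kept2", "dropped_ones"],
        )
        # kept: (2,2,2) at d0; kept2: (2,2,2)? d0=(2,2,0) no, d5=(2,2,0) no -> dropped
        out = quant.robust_filter(m, design)
        assert list(out.index) == ["kept"]

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(8)
        design = self._design()
        m = pd.DataFrame(
            rng.integers(0, 5, size=(40, 6)), columns=design.index,
            index=[f"f{i}" for i in range(40)],
        )
        once = quant.robust_filter(m, design)
        assert set(once.index) <= set(m.index)
        pd.testing.assert_frame_equal(quant.robust_filter(once, design), once)

    def test_insufficient_replicates_warns_empty(self):
        design = pd.DataFrame({"day": ["d0", "d0", "d5", "d5"]}, index=list("abcd"))
        m = pd.DataFrame({"a": [5], "b": [5], "c": [5], "d": [5]}, index=["f"])
        with pytest.warns(UserWarning):
            out = quant.robust_filter(m, design)
        assert len(out) == 0


class TestCircMetrics:
    def test_stage_means_and_diversity(self):
        cpm = pd.DataFrame({"r1": [60.0, 40.0], "r2": [150.0, 50.0]}, index=["c1", "c2"])
        raw = pd.DataFrame({"r1": [3, 0], "r2": [5, 2]}, index=["c1", "c2"])
        design = pd.DataFrame({"stage": ["iPSC", "iPSC"]}, index=["r1", "r2"])
        m = quant.circ_metrics(cpm, raw, design)
        assert m.per_replicate.loc["r1", "cumulative_cpm"] == 100.0
        assert m.per_replicate.loc["r1", "diversity"] == 1
        assert m.per_replicate.loc["r1", "normalized_load"] == 100.0
        assert m.per_stage.loc["iPSC", "cumulative_cpm"] == 150.0  # mean(100, 200)


class TestCoherenceQuadrants:
    def test_enumerated_example(self):
        q = quant.coherence_quadrants([1, -1, 1, -2], [1, -1, -1, -0.5])
        assert (q["up_up"], q["down_down"], q["up_down"], q["down_up"]) == (1, 2, 1, 0)
        assert q["coherent_fraction"] == pytest.approx(0.75)

    def test_all_positive_and_zero_exclusion(self):
        assert quant.coherence_quadrants([1, 2], [3, 4])["coherent_fraction"] == 1.0
        q = quant.coherence_quadrants([1, 0, 1], [1, 1, np.nan])
        assert q["n"] == 1


@pytest.fixture(scope="module")
def refs(discovered_catalog, small_genome):
    return quant.ReferenceSet.build(discovered_catalog, small_genome, small_genome.genes)


class TestEndToEndQuantification:
    """Placement + counting against the simulator's ground truth."""

    def test_junction_reads_place_on_their_contig(
        self, untreated_reads, refs, small_truths
    ):
        placements = quant.assign_fragments(untreated_reads, refs)
        truth_region = {
            t.circ_id: f"bsj|{t.chrom}:{t.bsj_start + 1}-{t.bsj_end}" for t in small_truths
        }
        origins = untreated_reads.origins()
        on_contig = checked = 0
        for origin, (p1, p2) in zip(origins, placements.placements):
            if origin.kind != "circ" or not origin.spans_bsj:
                continue
            checked += 1
            names = {n for plist in (p1, p2) for (n, _p, _l) in plist}
            on_contig += truth_region[origin.ref_id] in names
        assert checked > 50
        # a junction-spanning FRAGMENT yields a contig placement only when a
        # mate both covers the junction and fits the 200 nt contig, i.e. the
        # junction lies within ~[50, 100] nt of that mate's start: roughly
        # 2 * 50 / 300 = 1/3 of spanning fragments for 300 nt fragments
        assert 0.2 < on_contig / checked < 0.5

    def test_linear_reads_place_on_genome_only_bsj(self, untreated_reads, refs):
        placements = quant.assign_fragments(untreated_reads, refs)
        for origin, (p1, p2) in zip(untreated_reads.origins(), placements.placements):
            if origin.kind == "lin":
                bsj_hits = {
                    n for plist in (p1, p2) for (n, _p, _l) in plist if n.startswith("bsj|")
                }
                assert not bsj_hits

    def test_clr_estimates_track_planted_truth(
        self, untreated_reads, refs, discovered_catalog, small_truths
    ):
        counts, _ = quant.quantify_sample(untreated_reads, refs)
        clr_est = {c.circ_id: quant.compute_clr(c.bsj, c.fsj5, c.fsj3) for c in counts}
        truth = {
            (t.chrom, t.bsj_start, t.bsj_end): t.clr_truth for t in small_truths
        }
        pairs = [
            (truth[(e.chrom, e.start, e.end)], clr_est[e.circ_id])
            for e in discovered_catalog
            if (e.chrom, e.start, e.end) in truth
        ]
        assert len(pairs) >= 15
        rho = spearmanr([a for a, _ in pairs], [b for _, b in pairs]).statistic
        assert rho >= 0.7
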