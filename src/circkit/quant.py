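"""Junction-library quantification of circRNAs in untreated libraries.

For every catalogued backsplice junction a 200 nt contig is built from
100 nt of genomic sequence on each side of the junction; for the two
adjacent forward splice junctions (FSJs) analogous spliced contigs are
built from the flanking exon sequence.  Untreated reads are placed
exactly (<= 2 mismatches, multi-placements retained) on genome + contigs,
and a fragment is counted for a junction when either mate covers at least
8 nt of the 10 nt window centred on it — the featureCounts
``-p -M --minOverlap 8`` semantics.

Downstream statistics: the circular-to-linear ratio
``CLR = #BSJ / (mean(#FSJ) + 1)``, CPM normalization, per-replicate
cumulative circularization and circRNA diversity, and the
coherent/opposing quadrant summary of circular vs linear changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discover import BsjCatalog, BsjEntry
from .index import KmerIndex, encode_seq
from .synth.genome import GeneModel, revcomp
from .synth.reads import ReadSet

FLANK = 100
WINDOW = 10
MIN_OVERLAP = 8


@dataclass(frozen=True)
class JunctionContig:
    circ_id: str
    sequence: str
    junction_offset: int


@dataclass
class JunctionCounts:
    """Per (circRNA, sample) BSJ and flanking FSJ fragment counts.

    ``fsj5`` / ``fsj3`` are None when the circle starts/ends at a
    terminal exon, i.e. the adjacent linear junction does not exist —
    distinct from an observed count of zero.
    """

    circ_id: str
    sample_id: str
    bsj: int
    fsj5: int | None
    fsj3: int | None


def build_junction_library(catalog: BsjCatalog, genome) -> list[JunctionContig]:
    """One 2 x 100 nt junction contig per catalogued circRNA.

    For circles shorter than 200 nt each half is truncated to
    ``circle_len // 2`` so no genomic base appears twice in the contig.
    """
    contigs = []
    for e in catalog:
        chrom = genome.chromosomes[e.chrom]
        span = e.end - e.start
        assert span >= 50, "catalog entries must have passed the distance filter"
        h = FLANK if span >= 2 * FLANK else span // 2
        seq = chrom[e.end - h : e.end] + chrom[e.start : e.start + h]
        contigs.append(JunctionContig(circ_id=e.circ_id, sequence=seq, junction_offset=h))
    return contigs


@dataclass(frozen=True)
class FsjContig:
    """Spliced contig across one annotated forward splice junction."""

    name: str
    sequence: str
    junction_offset: int


def _adjacent_fsjs(
    entry: BsjEntry, gene: GeneModel
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Adjacent FSJs as (donor exon index, acceptor exon index) pairs.

    Returned in genomic order: the junction just upstream of the circle
    start and the one just downstream of the circle end; None when the
    circle reaches a terminal exon.
    """
    starts = [s for s, _ in gene.exons]
    ends = [e for _, e in gene.exons]
    try:
        i_first = starts.index(entry.start)
        i_last = ends.index(entry.end)
    except ValueError:
        # breakpoints off exon boundaries: nearest enclosing exons
        i_first = int(np.searchsorted(starts, entry.start, side="right")) - 1
        i_last = int(np.searchsorted(ends, entry.end, side="left"))
        i_first = max(i_first, 0)
        i_last = min(i_last, gene.n_exons - 1)
    up = (i_first - 1, i_first) if i_first > 0 else None
    down = (i_last, i_last + 1) if i_last < gene.n_exons - 1 else None
    return up, down


def build_fsj_contigs(
    catalog: BsjCatalog, genome, annotation: list[GeneModel]
) -> tuple[dict[str, FsjContig], dict[str, tuple[str | None, str | None]]]:
    """FSJ contigs for every junction adjacent to a catalogued circle.

    Returns the contig map and, per circ_id, the (fsj5, fsj3) contig
    names in transcription orientation (on '-' genes the genomically
    downstream junction is the 5' one).
    """
    genes = {g.gene_id: g for g in annotation}
    contigs: dict[str, FsjContig] = {}
    links: dict[str, tuple[str | None, str | None]] = {}

    def make(gene: GeneModel, pair: tuple[int, int] | None) -> str | None:
        if pair is None:
            return None
        ia, ib = pair
        ea, eb = gene.exons[ia], gene.exons[ib]
        name = f"fsj|{gene.chrom}|{ea[1]}|{eb[0]}"
        if name not in contigs:
            chrom = genome.chromosomes[gene.chrom]
            left = chrom[max(ea[0], ea[1] - FLANK) : ea[1]]
            right = chrom[eb[0] : min(eb[1], eb[0] + FLANK)]
            contigs[name] = FsjContig(name=name, sequence=left + right, junction_offset=len(left))
        return name

    for e in catalog:
        gene = genes[e.gene_id]
        up, down = _adjacent_fsjs(e, gene)
        up_name, down_name = make(gene, up), make(gene, down)
        if gene.strand == "+":
            links[e.circ_id] = (up_name, down_name)
        else:
            links[e.circ_id] = (down_name, up_name)
    return contigs, links


@dataclass
class ReferenceSet:
    """Genome + BSJ contigs + FSJ contigs with a shared k-mer index."""

    sequences: dict[str, str]
    index: KmerIndex
    bsj_contigs: dict[str, JunctionContig]
    fsj_contigs: dict[str, FsjContig]
    fsj_links: dict[str, tuple[str | None, str | None]]

    @classmethod
    def build(
        cls, catalog: BsjCatalog, genome, annotation: list[GeneModel], k: int = 20
    ) -> "ReferenceSet":
        bsj = {c.circ_id: c for c in build_junction_library(catalog, genome)}
        fsj, links = build_fsj_contigs(catalog, genome, annotation)
        seqs = dict(genome.chromosomes)
        for cid, c in bsj.items():
            seqs[f"bsj|{cid}"] = c.sequence
        for name, c in fsj.items():
            seqs[name] = c.sequence
        return cls(
            sequences=seqs,
            index=KmerIndex(seqs, k),
            bsj_contigs=bsj,
            fsj_contigs=fsj,
            fsj_links=links,
        )


Placement = tuple[str, int, int]  # (reference name, position, mate length)


def place_mate(mate: str, index: KmerIndex, max_mismatches: int = 2) -> list[Placement]:
    """All full-length placements of a mate with <= ``max_mismatches``.

    Seed-and-verify with three non-overlapping exact seeds per
    orientation, which guarantees every placement with at most two
    mismatches is found for 150 nt mates.
    """
    k = index.k
    out: set[Placement] = set()
    for oriented in (mate, revcomp(mate)):
        codes = encode_seq(oriented)
        n = codes.size
        offsets = [0, k, 2 * k] if n >= 3 * k else [0, max(n - k, 0)]
        seen: set[tuple[str, int]] = set()
        for off in offsets:
            for name, pos in index.lookup_forward(oriented[off : off + k]):
                origin = (name, pos - off)
                if origin in seen:
                    continue
                seen.add(origin)
                prof = index.mismatch_profile(name, pos - off, codes)
                if prof is not None and int(prof.sum()) <= max_mismatches:
                    out.add((name, pos - off, n))
    return sorted(out)


@dataclass
class FragmentPlacements:
    names: list[str]
    placements: list[tuple[list[Placement], list[Placement]]]
    n_unplaced_mates: int = 0

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_placed_fragments(self) -> int:
        return sum(1 for p1, p2 in self.placements if p1 or p2)


def assign_fragments(
    reads: ReadSet, refs: ReferenceSet, max_mismatches: int = 2
) -> FragmentPlacements:
    """Place every mate on genome + contigs; multi-placements retained."""
    placements = []
    unplaced = 0
    for _name, m1, m2 in reads:
        p1 = place_mate(m1, refs.index, max_mismatches)
        p2 = place_mate(m2, refs.index, max_mismatches)
        unplaced += (not p1) + (not p2)
        placements.append((p1, p2))
    return FragmentPlacements(
        names=list(reads.names), placements=placements, n_unplaced_mates=unplaced
    )


def window_overlap(pos: int, length: int, junction_offset: int) -> int:
    """Overlap (nt) between a placement and the 10 nt junction window.

    The window spans ``[junction_offset - 5, junction_offset + 5)`` —
    5 nt on each side of the breakpoint.
    """
    lo = junction_offset - WINDOW // 2
    hi = junction_offset + WINDOW // 2
    return max(0, min(pos + length, hi) - max(pos, lo))


def _count_junction_fragments(
    placements: FragmentPlacements, offsets: dict[str, int]
) -> dict[str, int]:
    """Fragments covering >=8 nt of a junction window, per reference.

    A fragment (read pair) counts once per junction even when both mates
    cover it.
    """
    counts: dict[str, int] = {name: 0 for name in offsets}
    for p1, p2 in placements.placements:
        hit: set[str] = set()
        for plist in (p1, p2):
            for name, pos, length in plist:
                off = offsets.get(name)
                if off is not None and window_overlap(pos, length, off) >= MIN_OVERLAP:
                    hit.add(name)
        for name in hit:
            counts[name] += 1
    return counts


def count_bsj(placements: FragmentPlacements, refs: ReferenceSet) -> dict[str, int]:
    """#BSJ per circ_id for one sample."""
    offsets = {f"bsj|{cid}": c.junction_offset for cid, c in refs.bsj_contigs.items()}
    raw = _count_junction_fragments(placements, offsets)
    return {name.split("|", 1)[1]: n for name, n in raw.items()}


def count_fsj(
    placements: FragmentPlacements, refs: ReferenceSet
) -> dict[str, tuple[int | None, int | None]]:
    """(#FSJ5, #FSJ3) per circ_id; None where the junction does not exist."""
    offsets = {name: c.junction_offset for name, c in refs.fsj_contigs.items()}
    raw = _count_junction_fragments(placements, offsets)
    out: dict[str, tuple[int | None, int | None]] = {}
    for cid, (n5, n3) in refs.fsj_links.items():
        out[cid] = (
            raw[n5] if n5 is not None else None,
            raw[n3] if n3 is not None else None,
        )
    return out


def quantify_sample(
    reads: ReadSet, refs: ReferenceSet, max_mismatches: int = 2
) -> tuple[list[JunctionCounts], int]:
    """Full per-sample quantification: (junction counts, library size).

    Library size is the number of fragments with at least one placement
    anywhere in the reference set (genome or contigs).
    """
    placements = assign_fragments(reads, refs, max_mismatches)
    bsj = count_bsj(placements, refs)
    fsj = count_fsj(placements, refs)
    counts = [
        JunctionCounts(
            circ_id=cid,
            sample_id=reads.sample_id,
            bsj=bsj.get(cid, 0),
            fsj5=fsj.get(cid, (None, None))[0],
            fsj3=fsj.get(cid, (None, None))[1],
        )
        for cid in refs.bsj_contigs
    ]
    return counts, placements.n_placed_fragments


def counts_to_matrix(per_sample: dict[str, list[JunctionCounts]]) -> pd.DataFrame:
    """BSJ counts as a features x samples integer DataFrame."""
    data = {
        sample: {jc.circ_id: jc.bsj for jc in counts}
        for sample, counts in per_sample.items()
    }
    return pd.DataFrame(data).fillna(0).astype(int)


def robust_filter(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    timepoint_col: str = "day",
    min_reads: int = 2,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Keep features with >= ``min_reads`` in >= ``min_replicates``
    replicates of at least one time point (the robust-expression rule)."""
    groups = design.loc[list(matrix.columns)].groupby(timepoint_col, observed=True)
    if not any(len(cols) >= min_replicates for _, cols in groups.groups.items()):
        warnings.warn(
            f"no time point has >= {min_replicates} replicates; "
            "robust filter returns an empty matrix",
            stacklevel=2,
        )
        return matrix.iloc[0:0]
    keep = pd.Series(False, index=matrix.index)
    for _, cols in groups.groups.items():
        cols = list(cols)
        if len(cols) < min_replicates:
            continue
        keep |= (matrix[cols] >= min_reads).sum(axis=1) >= min_replicates
    return matrix.loc[keep]


def compute_clr(bsj: int, fsj5: int | None, fsj3: int | None) -> float:
    """CLR = #BSJ / (mean(#FSJ) + 1), the mean over the FSJs that exist."""
    if bsj < 0 or (fsj5 is not None and fsj5 < 0) or (fsj3 is not None and fsj3 < 0):
        raise ValueError("counts must be non-negative")
    available = [c for c in (fsj5, fsj3) if c is not None]
    mean_fsj = sum(available) / len(available) if available else 0.0
    return bsj / (mean_fsj + 1.0)


def clr_matrix(per_sample: dict[str, list[JunctionCounts]]) -> pd.DataFrame:
    data = {
        sample: {jc.circ_id: compute_clr(jc.bsj, jc.fsj5, jc.fsj3) for jc in counts}
        for sample, counts in per_sample.items()
    }
    return pd.DataFrame(data)


def compute_cpm(matrix: pd.DataFrame, library_sizes: pd.Series | dict) -> pd.DataFrame:
    """Counts per million placed fragments, per sample."""
    sizes = pd.Series(library_sizes, dtype=float).reindex(matrix.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    return matrix / sizes * 1e6


@dataclass
class CircMetrics:
    """Global circularization metrics.

    ``per_replicate`` columns: cumulative_cpm (sum of CPM-normalized BSJ
    counts), diversity (distinct expressed species), normalized_load
    (cumulative_cpm / diversity).  ``per_stage`` holds their means over
    the replicates of each stage.
    """

    per_replicate: pd.DataFrame
    per_stage: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def circ_metrics(
    cpm: pd.DataFrame,
    raw: pd.DataFrame,
    design: pd.DataFrame,
    stage_col: str = "stage",
    expression_threshold: int = 1,
) -> CircMetrics:
    diversity = (raw >= expression_threshold).sum(axis=0)
    cumulative = cpm.sum(axis=0)
    load = cumulative / diversity.replace(0, np.nan)
    per_rep = pd.DataFrame(
        {
            "cumulative_cpm": cumulative,
            "diversity": diversity,
            "normalized_load": load,
            "stage": design.loc[list(cpm.columns), stage_col],
        }
    )
    per_stage = per_rep.groupby("stage", observed=True)[
        ["cumulative_cpm", "diversity", "normalized_load"]
    ].mean()
    return CircMetrics(per_replicate=per_rep, per_stage=per_stage)


def coherence_quadrants(
    circ_changes: pd.Series | np.ndarray, linear_changes: pd.Series | np.ndarray
) -> dict:
    """Quadrant summary of paired circular vs linear log2 changes.

    Pairs with a zero or undefined member are excluded.  The coherent
    fraction is (up/up + down/down) over all included pairs.
    """
    c = np.asarray(circ_changes, dtype=float)
    l = np.asarray(linear_changes, dtype=float)
    if c.shape != l.shape:
        raise ValueError("paired change vectors must have equal length")
    ok = np.isfinite(c) & np.isfinite(l) & (c != 0) & (l != 0)
    c, l = c[ok], l[ok]
    up_up = int(((c > 0) & (l > 0)).sum())
    down_down = int(((c < 0) & (l < 0)).sum())
    up_down = int(((c > 0) & (l < 0)).sum())
    down_up = int(((c < 0) & (l > 0)).sum())
    total = up_up + down_down + up_down + down_up
    return {
        "up_up": up_up,
        "down_down": down_down,
        "up_down": up_down,
        "down_up": down_up,
        "n": total,
        "coherent_fraction": (up_up + down_down) / total if total else float("nan"),
    }
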