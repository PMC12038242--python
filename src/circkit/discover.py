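"""De novo backsplice-junction (BSJ) discovery from RNase R-treated reads.

Two bespoke detectors emulate the two families of circRNA callers used in
practice:

* **anchor** — find_circ-style: for a mate that does not align colinearly,
  the first and last ``anchor_len`` nt are placed exactly; when the
  terminal anchor lands upstream of the leading anchor on the same
  chromosome, both alignments are extended toward each other to the
  breakpoint with the fewest mismatches, and the resulting junction must
  show a GT..AG splice signal (in either transcription orientation).
* **annotation-exact** — CIRCexplorer2-style: the same anchor extension,
  but breakpoints are snapped to annotated exon boundaries within +-2 nt
  and candidates that cannot be snapped are dropped.  The annotation
  replaces the splice-signal requirement.

Candidates from any detector pass one filter (both breakpoints inside a
single annotated gene, genomic distance within [50 nt, 100 kb], minimum
read support) and the catalogs are merged by set union on coordinates,
mirroring the union-of-callers strategy that maximizes sensitivity.

Coordinates are 0-based half-open internally; ``BsjEntry.circ_id`` uses
the 1-based inclusive report notation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .coords import format_region
from .index import KmerIndex, encode_seq
from .synth.genome import GeneModel, revcomp
from .synth.reads import ReadSet


@dataclass
class DetectorConfig:
    anchor_len: int = 20
    max_mismatches: int = 2
    min_distance: int = 50
    max_distance: int = 100_000
    min_support_reads: int = 2
    require_gt_ag: bool = True
    snap_tolerance: int = 2

    def __post_init__(self) -> None:
        if self.anchor_len < 12:
            raise ValueError("anchor_len must be >= 12")
        if self.min_distance >= self.max_distance:
            raise ValueError("min_distance must be < max_distance")


@dataclass
class BsjCandidate:
    chrom: str
    strand: str
    start: int
    end: int
    support: int
    detector: str
    splice_signal: str | None = None

    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)


@dataclass
class BsjEntry:
    """A filtered, gene-assigned backsplice junction."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    support: int
    detectors: dict[str, int] = field(default_factory=dict)
    splice_signal: str | None = None

    @property
    def circ_id(self) -> str:
        return format_region(self.chrom, self.start, self.end)

    @property
    def span(self) -> int:
        return self.end - self.start

    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)


@dataclass
class BsjCatalog:
    entries: list[BsjEntry]
    genome_id: str | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def keys(self) -> set[tuple[str, str, int, int]]:
        return {e.key() for e in self.entries}

    def coordinate_set(self) -> set[tuple[str, int, int]]:
        return {(e.chrom, e.start, e.end) for e in self.entries}


class _Annotation:
    """Per-chromosome exon boundary arrays and gene spans."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        starts: dict[str, list[int]] = defaultdict(list)
        ends: dict[str, list[int]] = defaultdict(list)
        spans: dict[str, list[tuple[int, int, GeneModel]]] = defaultdict(list)
        for g in genes:
            spans[g.chrom].append((g.start, g.end, g))
            for s, e in g.exons:
                starts[g.chrom].append(s)
                ends[g.chrom].append(e)
        self.exon_starts = {c: np.unique(v) for c, v in starts.items()}
        self.exon_ends = {c: np.unique(v) for c, v in ends.items()}
        self.gene_spans = {c: sorted(v) for c, v in spans.items()}

    def snap(self, chrom: str, coord: int, which: str, tol: int) -> int | None:
        arr = (self.exon_starts if which == "start" else self.exon_ends).get(chrom)
        if arr is None or arr.size == 0:
            return None
        i = int(np.searchsorted(arr, coord))
        best, bd = None, tol + 1
        for j in (i - 1, i):
            if 0 <= j < arr.size:
                d = abs(int(arr[j]) - coord)
                if d < bd:
                    best, bd = int(arr[j]), d
        return best if bd <= tol else None

    def is_boundary_pair(self, chrom: str, start: int, end: int) -> bool:
        s = self.exon_starts.get(chrom)
        e = self.exon_ends.get(chrom)
        if s is None or e is None:
            return False
        return bool(
            s[np.searchsorted(s, start) : np.searchsorted(s, start, side="right")].size
            and e[np.searchsorted(e, end) : np.searchsorted(e, end, side="right")].size
        )

    def containing_genes(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        return [g for (gs, ge, g) in self.gene_spans.get(chrom, []) if gs <= start and end <= ge]


def splice_signal(chrom_seq: str, start: int, end: int) -> str | None:
    """GT..AG orientation of the junction's intron-side dinucleotides.

    '+' when the donor GT follows ``end`` and the acceptor AG precedes
    ``start``; '-' for the reverse-complement arrangement; None otherwise.
    """
    up = chrom_seq[max(start - 2, 0) : start]
    down = chrom_seq[end : end + 2]
    if up == "AG" and down == "GT":
        return "+"
    if up == "AC" and down == "CT":
        return "-"
    return None


def _unique_forward_hit(index: KmerIndex, kmer: str) -> tuple[str, int] | None | str:
    hits = index.lookup_forward(kmer)
    if not hits:
        return None
    if len(hits) > 1:
        return "multi"
    return hits[0]


def _scan_oriented(
    r: str,
    index: KmerIndex,
    config: DetectorConfig,
    annotation: _Annotation | None,
    diag: Counter,
) -> tuple[str, int, int] | None:
    """One orientation of one mate -> (chrom, start, end) or None."""
    k = config.anchor_len
    n = len(r)
    if n < 2 * k:
        return None
    lead = _unique_forward_hit(index, r[:k])
    if lead is None:
        diag["no_anchor"] += 1
        return None
    if lead == "multi":
        diag["multi_anchor"] += 1
        return None
    chrom, g1 = lead
    r_codes = encode_seq(r)
    ref = index._encoded[chrom]
    chromlen = ref.size

    # colinear placement at the leading anchor ends the analysis
    prof = index.mismatch_profile(chrom, g1, r_codes)
    if prof is not None and int(prof.sum()) <= config.max_mismatches:
        diag["colinear"] += 1
        return None

    term = _unique_forward_hit(index, r[-k:])
    if term is None:
        diag["no_anchor"] += 1
        return None
    if term == "multi":
        diag["multi_anchor"] += 1
        return None
    chrom2, g2 = term
    if chrom2 != chrom or g2 >= g1:
        diag["not_backsplice_order"] += 1
        return None

    # prefix mismatches: r[:b] vs ref[g1:g1+b]
    avail1 = min(n, chromlen - g1)
    pm = np.full(n + 1, n + 1, dtype=np.int64)
    if avail1 > 0:
        mis1 = ref[g1 : g1 + avail1] != r_codes[:avail1]
        pm[: avail1 + 1] = np.concatenate([[0], np.cumsum(mis1)])

    # suffix mismatches: r[b:] vs ref[g2+k-(n-b) : g2+k]
    right = g2 + k
    avail2 = min(n, right)
    sm = np.full(n + 1, n + 1, dtype=np.int64)
    if avail2 > 0:
        seg = ref[right - avail2 : right]
        mis2 = seg != r_codes[n - avail2 :]
        tail = np.concatenate([np.cumsum(mis2[::-1])[::-1], [0]])  # mism in r[b:]
        sm[n - avail2 :] = tail
    bs = np.arange(k, n - k + 1)
    mm = pm[bs] + sm[bs]
    # candidate interval per breakpoint
    starts = right - (n - bs)
    ends = g1 + bs
    ok = (mm <= config.max_mismatches) & (starts >= 2) & (ends + 2 <= chromlen) & (starts < ends)
    if not ok.any():
        diag["no_breakpoint"] += 1
        return None
    mm_ok = mm[ok]
    best = int(mm_ok.min())
    cand_b = bs[ok][mm_ok == best]

    if cand_b.size > 1:
        # tie-break: annotated boundaries, then GT..AG, then leftmost
        chrom_seq = index.sequences[chrom]
        tiers: list[np.ndarray] = []
        if annotation is not None:
            ann = np.array(
                [
                    annotation.is_boundary_pair(chrom, right - (n - b), g1 + b)
                    for b in cand_b
                ]
            )
            if ann.any():
                tiers.append(cand_b[ann])
        if not tiers:
            sig = np.array(
                [splice_signal(chrom_seq, right - (n - b), g1 + b) is not None for b in cand_b]
            )
            if sig.any():
                tiers.append(cand_b[sig])
        chosen_pool = tiers[0] if tiers else cand_b
        if chosen_pool.size > 1:
            diag["ambiguous_breakpoint"] += 1
        b = int(chosen_pool.min())
    else:
        b = int(cand_b[0])
    return (chrom, right - (n - b), g1 + b)


def _detect(
    reads: ReadSet,
    index: KmerIndex,
    config: DetectorConfig,
    annotation: _Annotation | None,
    detector: str,
    diagnostics: Counter | None,
) -> list[BsjCandidate]:
    diag: Counter = diagnostics if diagnostics is not None else Counter()
    support: Counter = Counter()
    signals: dict[tuple, str | None] = {}
    strands: dict[tuple, str] = {}
    for _name, m1, m2 in reads:
        frag_keys: set[tuple] = set()
        for mate in (m1, m2):
            found = None
            for oriented, aln_strand in ((mate, "+"), (revcomp(mate), "-")):
                found = _scan_oriented(oriented, index, config, annotation, diag)
                if found is not None:
                    break
            if found is None:
                continue
            chrom, start, end = found
            if annotation is not None:
                s_snap = annotation.snap(chrom, start, "start", config.snap_tolerance)
                e_snap = annotation.snap(chrom, end, "end", config.snap_tolerance)
                if s_snap is None or e_snap is None or s_snap >= e_snap:
                    diag["unsnappable"] += 1
                    continue
                start, end = s_snap, e_snap
            sig = splice_signal(index.sequences[chrom], start, end)
            if annotation is None and config.require_gt_ag and sig is None:
                diag["no_splice_signal"] += 1
                continue
            strand = sig if sig is not None else aln_strand
            key = (chrom, strand, start, end)
            frag_keys.add(key)
            signals.setdefault(key, sig)
            strands.setdefault(key, strand)
        for key in frag_keys:  # a fragment supports a junction once
            support[key] += 1
    return [
        BsjCandidate(
            chrom=c, strand=s, start=st, end=en, support=n, detector=detector,
            splice_signal=signals.get((c, s, st, en)),
        )
        for (c, s, st, en), n in sorted(support.items())
    ]


def detect_anchor_backsplices(
    reads: ReadSet,
    index: KmerIndex,
    config: DetectorConfig | None = None,
    diagnostics: Counter | None = None,
) -> list[BsjCandidate]:
    """Annotation-free anchor detector (find_circ-style)."""
    return _detect(reads, index, config or DetectorConfig(), None, "anchor", diagnostics)


def detect_annotated_backsplices(
    reads: ReadSet,
    index: KmerIndex,
    annotation: list[GeneModel],
    config: DetectorConfig | None = None,
    diagnostics: Counter | None = None,
) -> list[BsjCandidate]:
    """Annotation-guided detector: breakpoints snapped to exon boundaries."""
    ann = _Annotation(annotation)
    return _detect(
        reads, index, config or DetectorConfig(), ann, "annotation-exact", diagnostics
    )


def filter_candidates(
    candidates: list[BsjCandidate],
    annotation: list[GeneModel],
    config: DetectorConfig | None = None,
    genome_id: str | None = None,
) -> BsjCatalog:
    """Apply the single-gene, distance, and support constraints.

    A candidate is kept when both breakpoints fall inside exactly one
    gene's genomic span, the genomic distance is within
    [min_distance, max_distance], and support reaches
    ``min_support_reads``.  The entry takes the host gene's strand.
    """
    config = config or DetectorConfig()
    ann = _Annotation(annotation)
    merged: dict[tuple, BsjEntry] = {}
    for c in candidates:
        span = c.end - c.start
        if not (config.min_distance <= span <= config.max_distance):
            continue
        hosts = ann.containing_genes(c.chrom, c.start, c.end)
        if len(hosts) != 1:
            continue
        gene = hosts[0]
        key = (c.chrom, gene.strand, c.start, c.end)
        if key in merged:
            e = merged[key]
            e.support += c.support
            e.detectors[c.detector] = e.detectors.get(c.detector, 0) + c.support
        else:
            merged[key] = BsjEntry(
                chrom=c.chrom,
                strand=gene.strand,
                start=c.start,
                end=c.end,
                gene_id=gene.gene_id,
                support=c.support,
                detectors={c.detector: c.support},
                splice_signal=c.splice_signal,
            )
    entries = [e for e in merged.values() if e.support >= config.min_support_reads]
    entries.sort(key=lambda e: (e.chrom, e.start, e.end))
    return BsjCatalog(entries=entries, genome_id=genome_id)


def union_catalogs(*catalogs: BsjCatalog) -> BsjCatalog:
    """Set union on (chrom, strand, start, end); support summed per detector."""
    builds = {c.genome_id for c in catalogs if c.genome_id is not None}
    if len(builds) > 1:
        raise ValueError(f"catalogs come from different genome builds: {sorted(builds)}")
    merged: dict[tuple, BsjEntry] = {}
    for cat in catalogs:
        for e in cat:
            key = e.key()
            if key in merged:
                m = merged[key]
                m.support += e.support
                for d, n in e.detectors.items():
                    m.detectors[d] = m.detectors.get(d, 0) + n
                if m.splice_signal is None:
                    m.splice_signal = e.splice_signal
            else:
                merged[key] = BsjEntry(
                    chrom=e.chrom,
                    strand=e.strand,
                    start=e.start,
                    end=e.end,
                    gene_id=e.gene_id,
                    support=e.support,
                    detectors=dict(e.detectors),
                    splice_signal=e.splice_signal,
                )
    entries = sorted(merged.values(), key=lambda e: (e.chrom, e.start, e.end))
    return BsjCatalog(entries=entries, genome_id=builds.pop() if builds else None)
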