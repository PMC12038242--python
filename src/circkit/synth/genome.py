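"""Synthetic genome and circRNA ground truth.

The generator emulates the coordinate space the pipeline operates in: a
random near-uniform-GC genome carrying multi-exon genes with canonical
GT..AG splice signals written into every intron-facing exon flank, plus a
set of planted circRNAs whose backsplice junctions (BSJs) coincide with
annotated exon boundaries.  Each planted circRNA records its genomic
interval, the exons it circularizes, a per-state copy number and a planted
circular-to-linear ratio, so downstream discovery and quantification can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.array(list("ACGT"))

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered list of non-overlapping exons on one strand.

    Exons are 0-based half-open genomic intervals, sorted by start
    regardless of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if e - s < 20:
                raise ValueError(f"exon [{s},{e}) shorter than 20 nt")
            if s <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GenomeModel:
    """Chromosome sequences plus the gene models living on them."""

    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"{g.gene_id}: exon outside chromosome bounds")

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def spliced_sequence(self, gene: GeneModel) -> str:
        """mRNA sequence in transcription orientation."""
        chrom = self.chromosomes[gene.chrom]
        seq = "".join(chrom[s:e] for s, e in gene.exons)
        return seq if gene.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class CircTruth:
    """Planted circRNA: interval, circularized exons, per-state abundance."""

    circ_id: str
    gene_id: str
    chrom: str
    strand: str
    bsj_start: int
    bsj_end: int
    exon_indices: tuple[int, ...]
    copies_per_state: dict
    clr_truth: float

    def __post_init__(self) -> None:
        span = self.bsj_end - self.bsj_start
        if not (50 <= span <= 100_000):
            raise ValueError(f"{self.circ_id}: genomic distance {span} outside [50, 100000]")
        idx = self.exon_indices
        if tuple(idx) != tuple(range(idx[0], idx[-1] + 1)):
            raise ValueError("circularized exons must be contiguous")

    @property
    def span(self) -> int:
        return self.bsj_end - self.bsj_start

    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.bsj_start, self.bsj_end)


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


_B2I = {b: i for i, b in enumerate("ACGT")}


def _stamp(arr: np.ndarray, pos: int, motif: str) -> None:
    for i, b in enumerate(motif):
        arr[pos + i] = _B2I[b]


def generate_genome(
    n_chrom: int = 1,
    n_genes: int = 20,
    seed: int = 0,
    *,
    exon_len_range: tuple[int, int] = (160, 400),
    intron_len_range: tuple[int, int] = (200, 1200),
    n_exons_range: tuple[int, int] = (4, 9),
    intergenic_len_range: tuple[int, int] = (300, 1500),
    chrom_prefix: str = "chr",
) -> GenomeModel:
    """Generate a random genome with non-overlapping multi-exon genes.

    Genes are laid left to right along each chromosome, separated by
    random intergenic gaps; chromosome length follows from the layout.
    Every exon flank gets a canonical splice signal in the gene's
    transcription orientation (AG upstream of each exon start, GT
    downstream of each exon end on '+', the reverse complements on '-'),
    so splice-signal-aware detectors behave as they would on real introns.
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if exon_len_range[0] < 20:
        raise ValueError("exons must be at least 20 nt")
    if intron_len_range[0] < 30:
        raise ValueError("introns must be at least 30 nt")
    rng = np.random.default_rng(seed)

    per_chrom = [n_genes // n_chrom] * n_chrom
    for i in range(n_genes % n_chrom):
        per_chrom[i] += 1

    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    gi = 0
    for ci in range(n_chrom):
        name = f"{chrom_prefix}{ci + 1}"
        layouts: list[tuple[list[tuple[int, int]], str]] = []
        cursor = int(rng.integers(*intergenic_len_range))
        for _ in range(per_chrom[ci]):
            n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
            exons: list[tuple[int, int]] = []
            pos = cursor
            for k in range(n_ex):
                if k > 0:
                    pos += int(rng.integers(*intron_len_range))
                elen = int(rng.integers(*exon_len_range))
                exons.append((pos, pos + elen))
                pos += elen
            strand = "+" if rng.random() < 0.5 else "-"
            layouts.append((exons, strand))
            cursor = pos + int(rng.integers(*intergenic_len_range))
        chrom_len = cursor + int(rng.integers(*intergenic_len_range))
        arr = _random_sequence(rng, chrom_len)
        for exons, strand in layouts:
            for s, e in exons:
                if strand == "+":
                    _stamp(arr, s - 2, "AG")
                    _stamp(arr, e, "GT")
                else:
                    _stamp(arr, s - 2, "AC")  # revcomp(GT)
                    _stamp(arr, e, "CT")  # revcomp(AG)
        seq = "".join(BASES[arr])
        chromosomes[name] = seq
        for exons, strand in layouts:
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gi:04d}",
                    chrom=name,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
    model = GenomeModel(chromosomes=chromosomes, genes=genes)
    model.validate()
    return model


def plant_circrnas(
    genome: GenomeModel,
    n_circ: int,
    seed: int = 0,
    *,
    max_exons_per_circ: int = 3,
    max_circ_per_gene: int = 2,
    min_distance: int = 50,
    max_distance: int = 100_000,
    clr_log2_mean: float = -3.0,
    clr_log2_sd: float = 1.0,
    copies_per_state: dict | None = None,
) -> list[CircTruth]:
    """Plant circRNAs on contiguous internal exon runs of multi-exon genes.

    Only internal exons (never the first or last exon of the gene) are
    circularized so that every BSJ has both adjacent forward splice
    junctions and intron-side GT..AG signals.  The planted
    circular-to-linear ratio is lognormal, with a default median of
    2**-3: circRNAs are typically a small fraction of their host's
    output, and in aggregate a few percent of an untreated library.
    Per-state copy numbers default to a state multiplier of 1.0.
    """
    rng = np.random.default_rng(seed)
    eligible = [g for g in genome.genes if g.n_exons >= 3]
    if not eligible:
        raise ValueError("genome has no genes with >=3 exons; cannot plant circRNAs")

    slots: list[tuple[GeneModel, tuple[int, ...]]] = []
    for g in eligible:
        for first in range(1, g.n_exons - 1):
            for last in range(first, min(first + max_exons_per_circ, g.n_exons - 1)):
                idx = tuple(range(first, last + 1))
                span = g.exons[last][1] - g.exons[first][0]
                if min_distance <= span <= max_distance:
                    slots.append((g, idx))
    if not slots:
        raise ValueError("no exon run satisfies the genomic-distance constraint")

    order = rng.permutation(len(slots))
    per_gene: dict[str, int] = {}
    used: set[tuple] = set()
    truths: list[CircTruth] = []
    for oi in order:
        if len(truths) == n_circ:
            break
        g, idx = slots[oi]
        key = (g.chrom, g.strand, g.exons[idx[0]][0], g.exons[idx[-1]][1])
        if key in used or per_gene.get(g.gene_id, 0) >= max_circ_per_gene:
            continue
        used.add(key)
        per_gene[g.gene_id] = per_gene.get(g.gene_id, 0) + 1
        clr = float(2.0 ** rng.normal(clr_log2_mean, clr_log2_sd))
        cps = dict(copies_per_state) if copies_per_state else {"default": 1.0}
        truths.append(
            CircTruth(
                circ_id=f"circ_{len(truths) + 1:04d}",
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                bsj_start=g.exons[idx[0]][0],
                bsj_end=g.exons[idx[-1]][1],
                exon_indices=idx,
                copies_per_state=cps,
                clr_truth=clr,
            )
        )
    if len(truths) < n_circ:
        raise ValueError(
            f"could only plant {len(truths)} of {n_circ} circRNAs; "
            "increase genome size or relax constraints"
        )
    return truths


def circular_sequence(genome: GenomeModel, truth: CircTruth) -> str:
    """Spliced sequence of the circle in transcription orientation."""
    gene = genome.gene_by_id(truth.gene_id)
    chrom = genome.chromosomes[gene.chrom]
    seq = "".join(chrom[gene.exons[i][0] : gene.exons[i][1]] for i in truth.exon_indices)
    return seq if gene.strand == "+" else revcomp(seq)
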