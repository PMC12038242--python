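"""Round-trip readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Bio.SeqIO (gzip transparently, judged by file
suffix).  The GTF subset written here is the standard 9-column, 1-based
inclusive exon table with gene_id/transcript_id attributes; catalogs are
written both as BED6+ (0-based half-open) and as a report TSV in 1-based
inclusive notation.  Every writer has a reader that reproduces the
in-memory object exactly.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discover import BsjCatalog, BsjEntry
from .synth.cohort import CountMatrix
from .synth.genome import CircTruth, GeneModel, GenomeModel
from .synth.reads import ReadSet


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------- FASTA


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with _open_text(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path, "r") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ---------------------------------------------------------------- FASTQ


def write_fastq_pair(reads: ReadSet, path1: str | Path, path2: str | Path) -> None:
    for path, mates, mate_no in ((path1, reads.mates1, 1), (path2, reads.mates2, 2)):
        with _open_text(path, "w") as fh:
            for name, seq in zip(reads.names, mates):
                fh.write(f"@{name}/{mate_no}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq_pair(
    path1: str | Path, path2: str | Path, sample_id: str = "sample"
) -> ReadSet:
    def load(path):
        with _open_text(path, "r") as fh:
            recs = list(SeqIO.parse(fh, "fastq"))
        return [r.id.rsplit("/", 1)[0] for r in recs], [str(r.seq) for r in recs]

    names1, seqs1 = load(path1)
    names2, seqs2 = load(path2)
    if names1 != names2:
        raise ValueError("mate files are not in matching order")
    return ReadSet(names=names1, mates1=seqs1, mates2=seqs2, sample_id=sample_id)


# ------------------------------------------------------------------ GTF


def write_gtf(genes: list[GeneModel], path: str | Path, source: str = "circkit") -> None:
    with _open_text(path, "w") as fh:
        for g in genes:
            for i, (s, e) in enumerate(g.exons, start=1):
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    with _open_text(path, "r") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            if feature != "exon":
                continue
            fields = dict(
                kv.strip().split(" ", 1)
                for kv in attrs.strip().rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = fields["gene_id"].strip('"')
            rec = per_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].append((int(start1) - 1, int(end1)))
    genes = []
    for gid, rec in per_gene.items():
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_genome(genome: GenomeModel, fasta_path: str | Path, gtf_path: str | Path) -> None:
    write_fasta(genome.chromosomes, fasta_path)
    write_gtf(genome.genes, gtf_path)


def read_genome(fasta_path: str | Path, gtf_path: str | Path) -> GenomeModel:
    return GenomeModel(chromosomes=read_fasta(fasta_path), genes=read_gtf(gtf_path))


# -------------------------------------------------------------- catalog


def write_catalog_bed(catalog: BsjCatalog, path: str | Path) -> None:
    """BED6+2: chrom, start, end, circ_id, support, strand, gene_id, detectors."""
    with _open_text(path, "w") as fh:
        for e in catalog:
            det = ",".join(f"{d}:{n}" for d, n in sorted(e.detectors.items()))
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{e.circ_id}\t{e.support}\t{e.strand}"
                f"\t{e.gene_id}\t{det}\n"
            )


def read_catalog_bed(path: str | Path, genome_id: str | None = None) -> BsjCatalog:
    entries = []
    with _open_text(path, "r") as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _cid, support, strand, gene_id, det = (
                line.rstrip("\n").split("\t")
            )
            detectors = {}
            if det:
                for part in det.split(","):
                    d, n = part.rsplit(":", 1)
                    detectors[d] = int(n)
            entries.append(
                BsjEntry(
                    chrom=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                    gene_id=gene_id,
                    support=int(support),
                    detectors=detectors,
                )
            )
    return BsjCatalog(entries=entries, genome_id=genome_id)


def write_catalog_report(catalog: BsjCatalog, path: str | Path) -> None:
    """1-based inclusive report table (the notation used in publications)."""
    rows = [
        {
            "circRNA": e.circ_id,
            "chrom": e.chrom,
            "start": e.start + 1,
            "end": e.end,
            "strand": e.strand,
            "gene": e.gene_id,
            "support": e.support,
            "detectors": ",".join(sorted(e.detectors)),
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------- count tables


def write_count_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    df.index.name = None
    return df


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index.name = None
    return df


def write_cohort(cm: CountMatrix, matrix_path: str | Path, design_path: str | Path) -> None:
    write_count_matrix(cm.counts, matrix_path)
    write_design(cm.design, design_path)


def read_cohort(matrix_path: str | Path, design_path: str | Path) -> CountMatrix:
    return CountMatrix(
        counts=read_count_matrix(matrix_path).astype(int),
        design=read_design(design_path),
    )


# ---------------------------------------------------------- truth table


def write_truth_table(truths: list[CircTruth], path: str | Path) -> None:
    rows = [
        {
            "circ_id": t.circ_id,
            "gene_id": t.gene_id,
            "chrom": t.chrom,
            "strand": t.strand,
            "bsj_start": t.bsj_start,
            "bsj_end": t.bsj_end,
            "exon_indices": ",".join(map(str, t.exon_indices)),
            "clr_truth": t.clr_truth,
            "copies_per_state": ";".join(f"{k}={v}" for k, v in t.copies_per_state.items()),
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth_table(path: str | Path) -> list[CircTruth]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    truths = []
    for _, r in df.iterrows():
        cps = dict(
            (k, float(v))
            for k, v in (kv.split("=") for kv in str(r["copies_per_state"]).split(";"))
        )
        truths.append(
            CircTruth(
                circ_id=r["circ_id"],
                gene_id=r["gene_id"],
                chrom=r["chrom"],
                strand=r["strand"],
                bsj_start=int(r["bsj_start"]),
                bsj_end=int(r["bsj_end"]),
                exon_indices=tuple(int(i) for i in str(r["exon_indices"]).split(",")),
                copies_per_state=cps,
                clr_truth=float(r["clr_truth"]),
            )
        )
    return truths
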