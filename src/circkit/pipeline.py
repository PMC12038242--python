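"""End-to-end pipeline orchestration.

One config drives five stages — simulate, discover, quantify, de,
classify — each writing its outputs plus a manifest entry (files, seeds,
input hashes).  A stage is skipped on rerun when its outputs already
exist and nothing upstream was recomputed, so deleting one intermediate
recomputes that stage and everything downstream, nothing else.

Every stochastic stage receives a sub-seed derived from the global seed
by hashing the stage name, so stage-level results do not depend on
execution order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import de as de_mod
from . import io as ckio
from . import quant
from .discover import (
    DetectorConfig,
    detect_anchor_backsplices,
    detect_annotated_backsplices,
    filter_candidates,
    union_catalogs,
)
from .index import KmerIndex
from .synth import (
    gene_abundances,
    generate_genome,
    plant_circrnas,
    simulate_cohort_matrix,
    simulate_library,
    transcript_weights,
)

log = logging.getLogger("circkit")

STAGES = ("simulate", "discover", "quantify", "de", "classify")


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "circkit_run"
    # simulate
    n_chrom: int = 1
    n_genes: int = 60
    n_circ: int = 40
    stages: tuple[str, ...] = ("progenitor", "differentiated")
    replicates: int = 3
    discovery_depth: int = 120_000
    quant_depth: int = 40_000
    error_rate: float = 0.0
    circ_scale: dict = field(
        default_factory=lambda: {"progenitor": 1.0, "differentiated": 2.8}
    )
    cohort_features: int = 300
    cohort_informative: int = 10
    cohort_n_per_class: int = 30
    cohort_effect_log2fc: float = 2.0
    cohort_dispersion: float = 0.1
    # discover / quant / de / classify
    detector: dict = field(default_factory=dict)
    de_thresholds: dict = field(default_factory=lambda: asdict(de_mod.DeThresholds()))
    classifier_top_n: int = 10
    cv_folds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed, independent of execution order."""
    return (zlib.crc32(f"{stage}:{global_seed}".encode()) ^ global_seed) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stage runner with manifest bookkeeping and resume logic."""

    def __init__(self, config: PipelineConfig, resume: bool = True):
        self.cfg = config
        self.resume = resume
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: dict = {"seed": config.seed, "stages": {}}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        self._upstream_reran = False

    # ------------------------------------------------------------ utils
    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _record(self, stage: str, outputs: list[Path], seed: int | None) -> None:
        self.manifest["stages"][stage] = {
            "seed": seed,
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _fresh(self, outputs: list[Path]) -> bool:
        if not self.resume:
            return False
        return all(p.exists() for p in outputs) and not self._upstream_reran

    def _sample_design(self) -> pd.DataFrame:
        rows = []
        for stage in self.cfg.stages:
            for rep in range(1, self.cfg.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{stage}_r{rep}",
                        "stage": stage,
                        "day": stage,
                        "replicate": rep,
                        "rnase_r": False,
                    }
                )
        return pd.DataFrame(rows).set_index("sample_id")

    # ----------------------------------------------------------- stages
    def simulate(self) -> None:
        cfg = self.cfg
        seed = stage_seed(cfg.seed, "simulate")
        outs = [
            self._path(n)
            for n in (
                "genome.fa",
                "annotation.gtf",
                "truth.tsv",
                "design.tsv",
                "reads_rnaser_R1.fastq.gz",
                "reads_rnaser_R2.fastq.gz",
                "cohort_counts.tsv",
                "cohort_design.tsv",
            )
        ]
        design = self._sample_design()
        sample_outs = [
            self._path(f"reads_{sid}_R{m}.fastq.gz") for sid in design.index for m in (1, 2)
        ]
        if self._fresh(outs + sample_outs):
            log.info("simulate: outputs present, skipping")
            return
        log.info("simulate: genome with %d genes, %d circRNAs", cfg.n_genes, cfg.n_circ)
        genome = generate_genome(cfg.n_chrom, cfg.n_genes, seed=seed)
        truths = plant_circrnas(genome, cfg.n_circ, seed=seed + 1)
        ckio.write_genome(genome, self._path("genome.fa"), self._path("annotation.gtf"))
        ckio.write_truth_table(truths, self._path("truth.tsv"))
        ckio.write_design(design, self._path("design.tsv"))
        abund = gene_abundances(genome, seed=seed + 2)

        pooled = simulate_library(
            genome,
            truths,
            state=cfg.stages[-1],
            rnase_r=True,
            depth=cfg.discovery_depth,
            error_rate=cfg.error_rate,
            seed=seed + 3,
            sample_id="rnaser_pool",
            abundances=abund,
            circ_scale=float(cfg.circ_scale.get(cfg.stages[-1], 1.0)),
        )
        ckio.write_fastq_pair(
            pooled, self._path("reads_rnaser_R1.fastq.gz"), self._path("reads_rnaser_R2.fastq.gz")
        )
        # depth compensation: hold absolute linear output constant across
        # states while the circular share changes with circ_scale
        ref_stage = cfg.stages[0]
        w_ref = sum(
            transcript_weights(
                genome, truths, state=ref_stage, abundances=abund,
                circ_scale=float(cfg.circ_scale.get(ref_stage, 1.0)),
            )
        )
        depth_by_stage = {}
        for st in cfg.stages:
            w = sum(
                transcript_weights(
                    genome, truths, state=st, abundances=abund,
                    circ_scale=float(cfg.circ_scale.get(st, 1.0)),
                )
            )
            depth_by_stage[st] = int(round(cfg.quant_depth * w / w_ref))
        for i, (sid, row) in enumerate(design.iterrows()):
            lib = simulate_library(
                genome,
                truths,
                state=row["stage"],
                rnase_r=False,
                depth=depth_by_stage[row["stage"]],
                error_rate=cfg.error_rate,
                seed=seed + 10 + i,
                sample_id=sid,
                abundances=abund,
                circ_scale=float(cfg.circ_scale.get(row["stage"], 1.0)),
            )
            ckio.write_fastq_pair(
                lib, self._path(f"reads_{sid}_R1.fastq.gz"), self._path(f"reads_{sid}_R2.fastq.gz")
            )
        cohort = simulate_cohort_matrix(
            cfg.cohort_features,
            cfg.cohort_n_per_class,
            cfg.cohort_informative,
            effect_log2fc=cfg.cohort_effect_log2fc,
            dispersion=cfg.cohort_dispersion,
            seed=seed + 100,
        )
        ckio.write_cohort(cohort, self._path("cohort_counts.tsv"), self._path("cohort_design.tsv"))
        (self._path("cohort_truth.json")).write_text(
            json.dumps({"informative": cohort.truth["informative"]}, indent=2)
        )
        self._record("simulate", outs + sample_outs, seed)
        self._upstream_reran = True

    def discover(self) -> None:
        outs = [self._path("catalog.bed"), self._path("catalog_report.tsv")]
        if self._fresh(outs):
            log.info("discover: outputs present, skipping")
            return
        genome = ckio.read_genome(self._path("genome.fa"), self._path("annotation.gtf"))
        reads = ckio.read_fastq_pair(
            self._path("reads_rnaser_R1.fastq.gz"),
            self._path("reads_rnaser_R2.fastq.gz"),
            sample_id="rnaser_pool",
        )
        config = DetectorConfig(**self.cfg.detector)
        index = KmerIndex(genome.chromosomes, config.anchor_len)
        log.info("discover: %d read pairs through two detectors", len(reads))
        anchor = detect_anchor_backsplices(reads, index, config)
        annotated = detect_annotated_backsplices(reads, index, genome.genes, config)
        catalog = union_catalogs(
            filter_candidates(anchor, genome.genes, config),
            filter_candidates(annotated, genome.genes, config),
        )
        log.info("discover: %d catalogued backsplice junctions", len(catalog))
        ckio.write_catalog_bed(catalog, self._path("catalog.bed"))
        ckio.write_catalog_report(catalog, self._path("catalog_report.tsv"))
        self._record("discover", outs, None)
        self._upstream_reran = True

    def quantify(self) -> None:
        outs = [
            self._path(n)
            for n in (
                "bsj_counts.tsv",
                "clr.tsv",
                "library_sizes.tsv",
                "robust_counts.tsv",
                "metrics_per_replicate.tsv",
                "metrics_per_stage.tsv",
            )
        ]
        if self._fresh(outs):
            log.info("quantify: outputs present, skipping")
            return
        genome = ckio.read_genome(self._path("genome.fa"), self._path("annotation.gtf"))
        catalog = ckio.read_catalog_bed(self._path("catalog.bed"))
        design = ckio.read_design(self._path("design.tsv"))
        refs = quant.ReferenceSet.build(catalog, genome, genome.genes)
        per_sample: dict[str, list] = {}
        lib_sizes: dict[str, int] = {}
        for sid in design.index:
            reads = ckio.read_fastq_pair(
                self._path(f"reads_{sid}_R1.fastq.gz"),
                self._path(f"reads_{sid}_R2.fastq.gz"),
                sample_id=sid,
            )
            counts, libsize = quant.quantify_sample(reads, refs)
            per_sample[sid] = counts
            lib_sizes[sid] = libsize
            log.info("quantify: %s, library size %d", sid, libsize)
        matrix = quant.counts_to_matrix(per_sample)
        clr = quant.clr_matrix(per_sample)
        robust = quant.robust_filter(matrix, design, timepoint_col="day")
        sizes = pd.Series(lib_sizes, name="library_size")
        cpm = quant.compute_cpm(matrix, sizes)
        metrics = quant.circ_metrics(cpm, matrix, design, stage_col="stage")
        ckio.write_count_matrix(matrix, self._path("bsj_counts.tsv"))
        clr.to_csv(self._path("clr.tsv"), sep="\t", index_label="feature_id")
        sizes.to_frame().to_csv(self._path("library_sizes.tsv"), sep="\t", index_label="sample_id")
        ckio.write_count_matrix(robust, self._path("robust_counts.tsv"))
        metrics.per_replicate.to_csv(
            self._path("metrics_per_replicate.tsv"), sep="\t", index_label="sample_id"
        )
        metrics.per_stage.to_csv(self._path("metrics_per_stage.tsv"), sep="\t")
        self._record("quantify", outs, None)
        self._upstream_reran = True

    def de(self) -> None:
        outs = [
            self._path("de_stage.tsv"),
            self._path("de_clr.tsv"),
            self._path("de_cohort.tsv"),
        ]
        if self._fresh(outs):
            log.info("de: outputs present, skipping")
            return
        seed = stage_seed(self.cfg.seed, "de")
        design = ckio.read_design(self._path("design.tsv"))
        robust = ckio.read_count_matrix(self._path("robust_counts.tsv"))
        clr = pd.read_csv(self._path("clr.tsv"), sep="\t", index_col="feature_id")
        ref, test = self.cfg.stages[0], self.cfg.stages[-1]
        if len(robust):
            res = de_mod.nb_wald_test(robust, design, ("stage", ref, test))
        else:
            res = pd.DataFrame()
        res.to_csv(self._path("de_stage.tsv"), sep="\t", index_label="feature_id")
        clr_res = de_mod.differential_clr(
            clr.loc[clr.index.intersection(robust.index)],
            design,
            ("stage", ref, test),
            seed=seed,
        )
        clr_res.to_csv(self._path("de_clr.tsv"), sep="\t", index_label="feature_id")
        cohort = ckio.read_cohort(self._path("cohort_counts.tsv"), self._path("cohort_design.tsv"))
        classes = list(dict.fromkeys(cohort.design["class"]))
        cohort_res = de_mod.nb_wald_test(
            cohort.counts, cohort.design, ("class", classes[0], classes[1])
        )
        cohort_res.to_csv(self._path("de_cohort.tsv"), sep="\t", index_label="feature_id")
        self._record("de", outs, seed)
        self._upstream_reran = True

    def classify(self) -> None:
        outs = [
            self._path("feature_ranks.tsv"),
            self._path("cv_scores.tsv"),
            self._path("roc_points.tsv"),
            self._path("model_card.json"),
        ]
        if self._fresh(outs):
            log.info("classify: outputs present, skipping")
            return
        seed = stage_seed(self.cfg.seed, "classify")
        thr = self.cfg.de_thresholds
        cohort = ckio.read_cohort(self._path("cohort_counts.tsv"), self._path("cohort_design.tsv"))
        de_res = pd.read_csv(self._path("de_cohort.tsv"), sep="\t", index_col="feature_id")
        selected = cls.select_de_features(
            de_res, lfc_cut=thr["lfc_cut"], padj_cut=thr["padj_cut"]
        )
        labels = (cohort.design["class"] == cohort.design["class"].iloc[-1]).astype(int)
        log_expr = np.log2(cohort.counts + 1.0)
        ranks = cls.rank_features(log_expr.loc[selected], labels.to_numpy(), seed=seed)
        ranks.to_csv(self._path("feature_ranks.tsv"), sep="\t", index_label="feature_id")
        top = list(ranks.index[: self.cfg.classifier_top_n])
        roc = cls.kfold_cv_classify(
            log_expr.loc[top],
            labels.to_numpy(),
            k=min(self.cfg.cv_folds, len(labels)),
            learner=lambda m, y, s: cls.tune_and_train_svm(m, y, seed=s),
            seed=seed,
        )
        pd.DataFrame(
            {"sample_id": cohort.design.index, "score": roc.scores, "label": roc.labels}
        ).to_csv(self._path("cv_scores.tsv"), sep="\t", index=False)
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
            self._path("roc_points.tsv"), sep="\t", index=False
        )
        (self._path("model_card.json")).write_text(
            json.dumps(
                {
                    "selected_features": top,
                    "n_candidates": len(selected),
                    "cv_folds": min(self.cfg.cv_folds, len(labels)),
                    "auc": roc.auc,
                    "seed": seed,
                },
                indent=2,
            )
        )
        log.info("classify: pooled CV AUC %.3f on %d features", roc.auc, len(top))
        self._record("classify", outs, seed)
        self._upstream_reran = True


def run_pipeline(
    config: PipelineConfig, only: list[str] | None = None, resume: bool = True
) -> dict:
    """Run the requested stages in order; returns the manifest.

    With ``resume`` (the default) a stage whose outputs already exist is
    skipped unless something upstream was recomputed; ``resume=False``
    forces every requested stage to rerun.
    """
    run = PipelineRun(config, resume=resume)
    for stage in STAGES:
        if only is not None and stage not in only:
            continue
        getattr(run, stage)()
    return run.manifest
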