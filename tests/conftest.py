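"""Shared fixtures: one small synthetic study reused across test modules."""

from __future__ import annotations

import pytest

from circkit.discover import (
    DetectorConfig,
    detect_anchor_backsplices,
    detect_annotated_backsplices,
    filter_candidates,
    union_catalogs,
)
from circkit.index import KmerIndex
from circkit.synth import generate_genome, plant_circrnas, simulate_library


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(n_chrom=2, n_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_truths(small_genome):
    return plant_circrnas(small_genome, 18, seed=12)


@pytest.fixture(scope="session")
def treated_reads(small_genome, small_truths):
    return simulate_library(
        small_genome, small_truths, rnase_r=True, depth=60_000, error_rate=0.0, seed=13
    )


@pytest.fixture(scope="session")
def untreated_reads(small_genome, small_truths):
    return simulate_library(
        small_genome, small_truths, rnase_r=False, depth=30_000, error_rate=0.0, seed=14
    )


@pytest.fixture(scope="session")
def genome_index(small_genome):
    return KmerIndex(small_genome.chromosomes, 20)


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig()


@pytest.fixture(scope="session")
def discovered_catalog(treated_reads, genome_index, small_genome, detector_config):
    anchor = detect_anchor_backsplices(treated_reads, genome_index, detector_config)
    annotated = detect_annotated_backsplices(
        treated_reads, genome_index, small_genome.genes, detector_config
    )
    return union_catalogs(
        filter_candidates(anchor, small_genome.genes, detector_config),
        filter_candidates(annotated, small_genome.genes, detector_config),
    )
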