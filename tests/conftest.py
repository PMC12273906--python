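"""Shared fixtures: one small simulated study reused across test modules.

Everything is generated at test time from seeds; no data files ship with
the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from eccpipe import annotate as an
from eccpipe import circcall as cc
from eccpipe import simdata as sd

SMALL_LENGTHS = sd.LognormalDist.from_mean_median(2000.0, 1800.0, 500.0, 5000.0)


@pytest.fixture(scope="session")
def genome() -> sd.SimGenome:
    return sd.generate_genome(n_chroms=2, chrom_length=120_000, te_density=0.2, seed=7)


@pytest.fixture(scope="session")
def circle_population(genome):
    circles, truth = sd.simulate_circles(
        genome, n=100, length_model=SMALL_LENGTHS, chimeric_rate=0.05, seed=1)
    return circles, truth


@pytest.fixture(scope="session")
def read_set(genome, circle_population):
    circles, _ = circle_population
    reads, truth = sd.simulate_rca_reads(
        circles, rounds_model=sd.UniformDist(2.0, 8.0), error_rate=0.01,
        linear_contaminant_rate=0.2, min_read_length=200, genome=genome, seed=2)
    return reads, truth


@pytest.fixture(scope="session")
def called_monomers(read_set):
    reads, _ = read_set
    calls, summary = cc.call_circular(
        [(r.read_id, r.sequence, r.qualities) for r in reads],
        min_length=200, min_monomer=50)
    return calls, summary


@pytest.fixture(scope="session")
def databases(genome):
    genome_db, te_db, cds_db = an.build_databases(genome)
    family_map = dict(zip(genome.family_table()["family"],
                          genome.family_table()["superfamily"]))
    return genome_db, te_db, cds_db, family_map


@pytest.fixture(scope="session")
def errorfree_annotations(genome, circle_population, databases):
    """Annotations of error-free monomers (circle sequences at a random
    rotation), keyed by circle id — the truth-matched annotation set."""
    circles, _ = circle_population
    rng = np.random.default_rng(3)
    monomers = {c.circle_id: sd.rotate(c.sequence, int(rng.integers(0, len(c.sequence))))
                for c in circles}
    genome_db, te_db, cds_db, family_map = databases
    annotations, unmapped = an.annotate_monomers(
        monomers, genome_db, te_db, cds_db, family_map,
        chrom_lengths=genome.chrom_lengths)
    return annotations, unmapped


def truth_by_circle(circle_population):
    circles, _ = circle_population
    return {c.circle_id: c for c in circles}
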