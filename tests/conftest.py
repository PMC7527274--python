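"""Shared fixtures: small simulated datasets reused across test modules.

Everything is generated at test time from fixed seeds; session scope keeps
the heavier simulations to one run each.
"""

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=DeprecationWarning)

from hapline import SimConfig                                  # noqa: E402
from hapline.genotyping import call_dosage, filter_markers     # noqa: E402
from hapline.phasing import pairwise_linkage, phase_scaffolds  # noqa: E402
from hapline.pipeline import truth_genes_to_annotated          # noqa: E402
from hapline.simulate import (                                 # noqa: E402
    simulate_all, simulate_diploid_genome)
from hapline.synteny import chain_synteny_blocks, find_homologs  # noqa: E402


@pytest.fixture(scope="session")
def genome_truth():
    """Small diploid genome (2 x 600 kb, 30 genes/chromosome)."""
    cfg = SimConfig(seed=7, n_chromosomes=2, chrom_length=600_000,
                    genes_per_chromosome=30)
    return simulate_diploid_genome(cfg)


@pytest.fixture(scope="session")
def annotated_genes(genome_truth):
    return truth_genes_to_annotated(genome_truth)


@pytest.fixture(scope="session")
def homolog_hits(annotated_genes):
    g1 = [g for g in annotated_genes.values() if g.haplotype == 1]
    g2 = [g for g in annotated_genes.values() if g.haplotype == 2]
    return find_homologs(g1, g2)


@pytest.fixture(scope="session")
def synteny_blocks(homolog_hits, annotated_genes):
    return chain_synteny_blocks(homolog_hits, annotated_genes)


@pytest.fixture(scope="session")
def default_sim():
    """The default phasing-scale simulation: 2 chromosomes x 2 Mb, 200
    progeny at ~1x, ~500 scaffolds per haplotype."""
    cfg = SimConfig(seed=1)
    truth, pcm = simulate_all(cfg)
    return cfg, truth, pcm


@pytest.fixture(scope="session")
def default_genotypes(default_sim):
    _, _, pcm = default_sim
    return filter_markers(call_dosage(pcm))


@pytest.fixture(scope="session")
def default_phase(default_sim, default_genotypes):
    cfg, _, _ = default_sim
    gm = default_genotypes
    similarity = pairwise_linkage(gm)
    assignment = phase_scaffolds(gm, similarity,
                                 expected_groups=cfg.n_chromosomes)
    return similarity, assignment
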