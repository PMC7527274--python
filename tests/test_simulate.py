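"""Generator contracts: determinism, planted-variant statistics, Mendelian
segregation, selection at lethal loci, scaffold conservation and count model."""

import numpy as np
import pandas as pd
import pytest

from hapline import LethalLocus, SimConfig
from hapline.simulate import (
    fragment_into_scaffolds, simulate_all, simulate_diploid_genome,
    simulate_expression, simulate_methylation, simulate_progeny_counts,
    simulate_selfing_population)


def test_zero_divergence_haplotypes_identical():
    cfg = SimConfig(seed=3, n_chromosomes=1, chrom_length=200_000,
                    snp_rate=0.0, indel_rate=0.0, sv_count=0,
                    pav_gene_fraction=0.0, genes_per_chromosome=10)
    truth = simulate_diploid_genome(cfg)
    assert np.array_equal(truth.seqs[(1, 1)], truth.seqs[(1, 2)])
    assert len(truth.variants) == 0


def test_snp_count_within_binomial_bounds():
    L, rate = 1_000_000, 0.015
    cfg = SimConfig(seed=5, n_chromosomes=1, chrom_length=L, snp_rate=rate,
                    indel_rate=0.0, sv_count=0, pav_gene_fraction=0.0,
                    genes_per_chromosome=50)
    truth = simulate_diploid_genome(cfg)
    n_snp = int((truth.variants["class"] == "SNP").sum())
    mean = L * rate
    sigma = np.sqrt(L * rate * (1 - rate))
    assert abs(n_snp - mean) < 3 * sigma


def test_same_seed_reproduces_everything():
    cfg = SimConfig(seed=11, n_chromosomes=1, chrom_length=300_000,
                    genes_per_chromosome=15, n_progeny=30,
                    scaffold_n50=30_000)
    t1, p1 = simulate_all(cfg)
    t2, p2 = simulate_all(cfg)
    for key in t1.seqs:
        assert np.array_equal(t1.seqs[key], t2.seqs[key])
    pd.testing.assert_frame_equal(t1.variants, t2.variants)
    assert np.array_equal(p1.counts, p2.counts)
    assert np.array_equal(p1.progeny_totals, p2.progeny_totals)
    assert [s.segments for s in t1.scaffolds] == \
        [s.segments for s in t2.scaffolds]


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(snp_rate=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(chrom_length=100_000, genes_per_chromosome=100).validate()
    with pytest.raises(ValueError):
        SimConfig(lethal_loci=[LethalLocus(chrom=9, pos=1)]).validate()


class TestSelfingPopulation:
    def test_mendelian_ratio_at_neutral_locus(self):
        cfg = SimConfig(seed=2, n_chromosomes=1, chrom_length=400_000,
                        genes_per_chromosome=10, n_progeny=10_000)
        truth = simulate_diploid_genome(cfg)
        simulate_selfing_population(truth, cfg)
        d = truth.dosage_h1(1, np.array([200_000]))[:, 0]
        n = len(d)
        counts = np.bincount(d, minlength=3)
        for k, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[k] - n * p) < 3 * sigma

    def test_lethal_locus_excludes_recessive_homozygotes(self):
        locus = LethalLocus(chrom=1, pos=150_000, carrier_haplotype=2,
                            mode="lethal")
        cfg = SimConfig(seed=2, n_chromosomes=1, chrom_length=400_000,
                        genes_per_chromosome=10, n_progeny=500,
                        lethal_loci=[locus])
        truth = simulate_diploid_genome(cfg)
        simulate_selfing_population(truth, cfg)
        d1 = truth.dosage_h1(1, np.array([locus.pos]))[:, 0]
        carrier_dosage = 2 - d1
        assert (carrier_dosage < 2).all()

    def test_recombinant_fraction_matches_haldane(self):
        # two loci 10 cM apart on a 1-Morgan chromosome
        cfg = SimConfig(seed=9, n_chromosomes=1, chrom_length=1_000_000,
                        genes_per_chromosome=10, n_progeny=5_000)
        truth = simulate_diploid_genome(cfg)
        simulate_selfing_population(truth, cfg)
        pos = np.array([450_000, 550_000])      # 0.1 Morgan apart
        starts = truth.gamete_starts[1]
        xos = truth.gamete_xos[1]
        rec = 0
        n_gametes = 0
        for p in range(starts.shape[0]):
            for gam in range(2):
                haps = starts[p, gam] ^ (
                    np.searchsorted(xos[p][gam], pos) & 1)
                rec += haps[0] != haps[1]
                n_gametes += 1
        r = (1 - np.exp(-0.2)) / 2
        sigma = np.sqrt(n_gametes * r * (1 - r))
        assert abs(rec - n_gametes * r) < 3 * sigma


class TestScaffolding:
    def test_no_chimeras_means_single_haplotype_scaffolds(self, default_sim):
        _, truth, _ = default_sim
        assert all(len(s.segments) == 1 and not s.is_chimeric
                   for s in truth.scaffolds)

    def test_scaffold_lengths_partition_haplotypes(self, default_sim):
        _, truth, _ = default_sim
        assert sum(s.length for s in truth.scaffolds) == truth.total_length()

    def test_chimeric_count_within_binomial_bounds(self):
        cfg = SimConfig(seed=13, n_chromosomes=8, chrom_length=3_000_000,
                        genes_per_chromosome=30, n_progeny=20,
                        scaffold_n50=500_000, chimera_rate=0.3,
                        window_size=100_000)
        truth = simulate_diploid_genome(cfg)
        simulate_selfing_population(truth, cfg)
        scaffolds = fragment_into_scaffolds(truth, cfg)
        n = len(scaffolds)
        k = sum(s.is_chimeric for s in scaffolds)
        # chimera events convert eligible interval pairs; fraction ~ rate
        sigma = np.sqrt(n * 0.3 * 0.7)
        assert abs(k - n * 0.3) < 3.5 * sigma


class TestProgenyCounts:
    def test_zero_dosage_means_zero_counts(self, default_sim):
        _, truth, pcm = default_sim
        # scaffolds whose haplotype the progeny does not carry get no reads
        for si in range(0, len(truth.scaffolds), 97):
            s = truth.scaffolds[si]
            c, h, a, b = s.segments[0]
            d1 = truth.dosage_h1(c, np.array([(a + b) // 2]))[:, 0]
            d = d1 if h == 1 else 2 - d1
            assert (pcm.counts[si][d == 0] == 0).all()

    def test_poisson_mean_at_full_dosage(self):
        cfg = SimConfig(seed=21, n_chromosomes=1, chrom_length=1_000_000,
                        genes_per_chromosome=10, n_progeny=400,
                        scaffold_n50=100_000, library_size_cv=0.0)
        truth, pcm = simulate_all(cfg)
        G = truth.total_length()
        si = int(np.argmax(pcm.scaffold_lengths))
        s = truth.scaffolds[si]
        c, h, a, b = s.segments[0]
        d1 = truth.dosage_h1(c, np.array([(a + b) // 2]))[:, 0]
        d = d1 if h == 1 else 2 - d1
        cells = pcm.counts[si][d == 2]
        lam = pcm.progeny_totals[0] * pcm.scaffold_lengths[si] / G
        assert len(cells) > 30
        sem = np.sqrt(lam / len(cells))
        assert abs(cells.mean() - lam) < 4 * sem

    def test_doubling_coverage_doubles_counts(self):
        base = dict(seed=22, n_chromosomes=1, chrom_length=500_000,
                    genes_per_chromosome=10, n_progeny=50,
                    scaffold_n50=50_000)
        t1, p1 = simulate_all(SimConfig(coverage=1.0, **base))
        t2, p2 = simulate_all(SimConfig(coverage=2.0, **base))
        ratio = p2.counts.sum() / p1.counts.sum()
        assert abs(ratio - 2.0) < 0.05


class TestExpressionAndMethylation:
    def test_null_pairs_share_means(self):
        cfg = SimConfig(seed=31, n_chromosomes=1, chrom_length=400_000,
                        genes_per_chromosome=20, del_fraction=0.0)
        truth = simulate_diploid_genome(cfg)
        expr, del_truth = simulate_expression(truth, cfg)
        assert len(del_truth) == 0
        per_allele = expr.groupby(["pair_id", "haplotype"]).est_count.sum() \
                         .unstack("haplotype")
        log_ratio = np.log2((per_allele[1] + 1) / (per_allele[2] + 1))
        assert np.abs(log_ratio).max() < 1.0    # no fold-change beyond noise

    def test_replicates_differ_but_share_mean(self):
        cfg = SimConfig(seed=31, n_chromosomes=1, chrom_length=400_000,
                        genes_per_chromosome=20)
        truth = simulate_diploid_genome(cfg)
        expr, _ = simulate_expression(truth, cfg)
        wide = expr.pivot_table(index=["pair_id", "haplotype", "tissue"],
                                columns="replicate", values="est_count")
        assert not (wide[1] == wide[2]).all()

    def test_planted_dmr_level_difference(self):
        cfg = SimConfig(seed=33, n_chromosomes=1, chrom_length=400_000,
                        genes_per_chromosome=20, dmr_count=5)
        truth = simulate_diploid_genome(cfg)
        s1, s2, dmr_truth = simulate_methylation(truth, cfg)
        assert len(dmr_truth) == 5
        assert (s1.meth <= s1.depth).all() and (s2.meth <= s2.depth).all()
        d = dmr_truth.iloc[0]
        in1 = s1[(s1.pos >= d.start) & (s1.pos <= d.end)
                 & (s1.context == "CG")]
        lvl1 = in1.meth.sum() / in1.depth.sum()
        # CG inside a DMR is simulated at 0.9 vs 0.1
        expected = 0.9 if d.hyper_haplotype == 1 else 0.1
        assert abs(lvl1 - expected) < 0.1
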