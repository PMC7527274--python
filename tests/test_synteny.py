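"""Homolog screening, collinear chaining vs an exhaustive oracle, allelic
pairing, PAV calling, variant extraction and CDS-effect classification."""

import numpy as np
import pytest

from hapline.simulate import decode_seq, true_diversity_percent
from hapline.synteny import (
    AnnotatedGene, HomologHit, SyntenyBlock, alignment_stats,
    brute_force_longest_chain, call_all_variants, call_pav_genes,
    call_variants, chain_synteny_blocks, classify_cds_effect, find_homologs,
    intragenomic_diversity, pair_alleles, _chain_once)


def mk_gene(gid, chrom, hap, start, cds):
    return AnnotatedGene(gene_id=gid, chrom=chrom, haplotype=hap,
                         start=start, end=start + len(cds) - 1,
                         strand="+", cds=cds)


RNG = np.random.default_rng(99)
BASES = "ACGT"


def random_cds(n):
    return "".join(RNG.choice(list(BASES)) for _ in range(n))


class TestAlignmentStats:
    def test_identical_sequences(self):
        cds = random_cds(300)
        cov, ident, _ = alignment_stats(cds, cds)
        assert cov == pytest.approx(1.0)
        assert ident == pytest.approx(1.0)

    def test_thirty_percent_mismatches_rejected(self):
        cds = random_cds(300)
        mutated = list(cds)
        for i in range(0, 270, 3):      # 90 evenly spread mismatches
            mutated[i] = BASES[(BASES.index(mutated[i]) + 1) % 4]
        cov, ident, _ = alignment_stats(cds, "".join(mutated))
        assert ident == pytest.approx(0.70, abs=0.02)
        assert ident < 0.75

    def test_half_length_target_halves_coverage(self):
        cds = random_cds(300)
        cov, ident, _ = alignment_stats(cds, cds[:150])
        assert cov == pytest.approx(0.5, abs=0.02)


class TestFindHomologs:
    def test_threshold_gating(self):
        cds = random_cds(300)
        mutated = list(cds)
        for i in range(0, 270, 3):
            mutated[i] = BASES[(BASES.index(mutated[i]) + 1) % 4]
        genes1 = [mk_gene("a1", 1, 1, 1000, cds),
                  mk_gene("a2", 1, 1, 9000, cds)]
        genes2 = [mk_gene("b1", 1, 2, 1000, cds),
                  mk_gene("b2", 1, 2, 9000, "".join(mutated))]
        hits = find_homologs(genes1, genes2, prefilter_distance=1.0)
        pairs = {(h.gene_a, h.gene_b) for h in hits}
        assert ("a1", "b1") in pairs
        assert ("a2", "b2") not in pairs          # identity 0.70 < 0.75

    def test_empty_cds_skipped(self):
        genes1 = [mk_gene("a1", 1, 1, 1000, "")]
        genes2 = [mk_gene("b1", 1, 2, 1000, random_cds(300))]
        assert find_homologs(genes1, genes2) == []


class TestChaining:
    def test_perfectly_collinear_anchors_single_block(self):
        cds = {i: random_cds(300) for i in range(10)}
        genes = {}
        hits = []
        for i in range(10):
            ga = mk_gene(f"a{i}", 1, 1, 1000 + 5000 * i, cds[i])
            gb = mk_gene(f"b{i}", 1, 2, 1200 + 5000 * i, cds[i])
            genes[ga.gene_id] = ga
            genes[gb.gene_id] = gb
            hits.append(HomologHit(ga.gene_id, gb.gene_id, 1.0, 1.0, 300.0))
        blocks = chain_synteny_blocks(hits, genes, min_anchors=5)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 10

    def test_length_ratio_screen(self):
        # anchor span 100 kb on h1 vs 350 kb on h2 -> ratio 3.5 > 3
        genes, hits = {}, []
        for i in range(6):
            cds = random_cds(300)
            ga = mk_gene(f"a{i}", 1, 1, 1000 + 20_000 * i, cds)
            gb = mk_gene(f"b{i}", 1, 2, 1000 + 70_000 * i, cds)
            genes[ga.gene_id] = ga
            genes[gb.gene_id] = gb
            hits.append(HomologHit(ga.gene_id, gb.gene_id, 1.0, 1.0, 300.0))
        blocks = chain_synteny_blocks(hits, genes, min_anchors=5)
        assert blocks == []

    def test_inversion_splits_blocks(self):
        # forward run, 6 inverted anchors, forward run; small gap cap keeps
        # the flanking runs from bridging the inversion
        genes, hits = {}, []
        order2 = list(range(0, 7)) + list(range(12, 6, -1)) + list(range(13, 20))
        for i, j in enumerate(order2):
            cds = random_cds(300)
            ga = mk_gene(f"a{i}", 1, 1, 1000 + 5000 * i, cds)
            gb = mk_gene(f"b{i}", 1, 2, 1000 + 5000 * j, cds)
            genes[ga.gene_id] = ga
            genes[gb.gene_id] = gb
            hits.append(HomologHit(ga.gene_id, gb.gene_id, 1.0, 1.0, 300.0))
        blocks = chain_synteny_blocks(hits, genes, min_anchors=4, max_gap=1,
                                      min_block_coverage=0.0)
        orientations = [b.orientation for b in blocks]
        assert len(blocks) == 3
        assert orientations.count("+") == 2
        assert orientations.count("-") == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        anchors = [(int(rng.integers(0, 15)), int(rng.integers(0, 15)))
                   for _ in range(n)]
        anchors = list({a: None for a in anchors})        # dedupe
        coords = [(i, j, k) for k, (i, j) in enumerate(anchors)]
        best_dp = max(len(_chain_once(coords, 25, +1)),
                      len(_chain_once(coords, 25, -1)))
        assert best_dp == brute_force_longest_chain(anchors, 25)


class TestPairing:
    def make_universe(self, tandem=False):
        genes, hits = {}, []
        for i in range(6):
            cds = random_cds(300)
            ga = mk_gene(f"a{i}", 1, 1, 1000 + 5000 * i, cds)
            gb = mk_gene(f"b{i}", 1, 2, 1000 + 5000 * i, cds)
            genes[ga.gene_id] = ga
            genes[gb.gene_id] = gb
            hits.append(HomologHit(ga.gene_id, gb.gene_id, 1.0, 1.0, 300.0))
        if tandem:
            dup = mk_gene("a_dup", 1, 1, 3500, genes["a0"].cds)
            genes[dup.gene_id] = dup
            hits.append(HomologHit("a_dup", "b0", 1.0, 1.0, 299.0))
        blocks = chain_synteny_blocks(hits, genes, min_anchors=4)
        return genes, hits, blocks

    def test_one_to_one_all_reliable(self):
        genes, hits, blocks = self.make_universe()
        pairs = pair_alleles(blocks, hits, genes)
        assert len(pairs) == 6
        assert pairs.reliable.all()

    def test_tandem_duplicate_not_reliable(self):
        genes, hits, blocks = self.make_universe(tandem=True)
        pairs = pair_alleles(blocks, hits, genes)
        dup_rows = pairs[pairs.gene_h1 == "a_dup"]
        assert len(dup_rows) == 0 or not dup_rows.reliable.any()
        assert pairs.set_index("gene_h1").loc["a0", "reliable"]

    def test_gene_without_hit_unpaired(self):
        genes, hits, blocks = self.make_universe()
        orphan = mk_gene("orphan", 1, 1, 2500, random_cds(300))
        genes[orphan.gene_id] = orphan
        pairs = pair_alleles(blocks, hits, genes)
        assert "orphan" not in set(pairs.gene_h1)


class TestPav:
    def test_simulated_pav_recovered(self, genome_truth, annotated_genes,
                                     homolog_hits, synteny_blocks):
        pav = call_pav_genes(synteny_blocks, homolog_hits, annotated_genes)
        true_pav = {g.gene_id for g in genome_truth.genes if g.is_pav}
        called = set(pav.gene_id)
        evaluable = {g for g in true_pav
                     if g in annotated_genes}      # placed genes only
        if evaluable:
            assert len(called & evaluable) / len(evaluable) >= 0.9

    def test_unpaired_neighbourhood_is_not_pav(self):
        # gene and both neighbours lack homologs -> criterion (c) fails
        genes, hits = {}, []
        for i in range(8):
            cds = random_cds(300)
            ga = mk_gene(f"a{i}", 1, 1, 1000 + 5000 * i, cds)
            genes[ga.gene_id] = ga
            if i in (3, 4, 5):
                continue                # no homologs in the middle
            gb = mk_gene(f"b{i}", 1, 2, 1000 + 5000 * i, cds)
            genes[gb.gene_id] = gb
            hits.append(HomologHit(ga.gene_id, gb.gene_id, 1.0, 1.0, 300.0))
        blocks = chain_synteny_blocks(hits, genes, min_anchors=4,
                                      min_block_coverage=0.0)
        pav = call_pav_genes(blocks, hits, genes)
        assert "a4" not in set(pav.gene_id)

    def test_gene_outside_block_not_pav(self, annotated_genes,
                                        homolog_hits, synteny_blocks):
        far = mk_gene("far_away", 1, 1, 10_000_000, random_cds(300))
        genes = dict(annotated_genes)
        genes[far.gene_id] = far
        pav = call_pav_genes(synteny_blocks, homolog_hits, genes)
        assert "far_away" not in set(pav.gene_id)


def two_anchor_block(seq_a, seq_b, anchor_cds):
    """Block spanning seq pair, anchored by identical genes at both ends."""
    genes = {}
    la, lb = len(seq_a), len(seq_b)
    k = len(anchor_cds[0])
    genes["L1"] = mk_gene("L1", 1, 1, 1, seq_a[:k])
    genes["L2"] = mk_gene("L2", 1, 2, 1, seq_b[:k])
    genes["R1"] = mk_gene("R1", 1, 1, la - k + 1, seq_a[-k:])
    genes["R2"] = mk_gene("R2", 1, 2, lb - k + 1, seq_b[-k:])
    block = SyntenyBlock(block_id=1, chrom=1, orientation="+",
                         h1_start=1, h1_end=la, h2_start=1, h2_end=lb,
                         anchors=[("L1", "L2"), ("R1", "R2")])
    return block, genes


class TestCallVariants:
    def make_pair(self, edit=None):
        rng = np.random.default_rng(3)
        seq_a = "".join(rng.choice(list(BASES)) for _ in range(2000))
        seq_b = seq_a
        if edit == "snp":
            seq_b = seq_a[:1000] + ("A" if seq_a[1000] != "A" else "C") \
                + seq_a[1001:]
        elif edit == "ins60":
            ins = "".join(rng.choice(list(BASES)) for _ in range(60))
            seq_b = seq_a[:1000] + ins + seq_a[1000:]
        return seq_a, seq_b

    def run(self, seq_a, seq_b):
        anchor = (seq_a[:300], seq_b[:300])
        block, genes = two_anchor_block(seq_a, seq_b, anchor)
        return call_variants(block, seq_a, seq_b, genes)

    def test_identical_segments_no_variants(self):
        a, b = self.make_pair()
        variants, cols = self.run(a, b)
        assert len(variants) == 0
        assert cols == 2000

    def test_single_substitution_single_snp(self):
        a, b = self.make_pair("snp")
        variants, _ = self.run(a, b)
        assert len(variants) == 1
        assert variants.iloc[0]["class"] == "SNP"
        assert variants.iloc[0].pos_h1 == 1001

    def test_sixty_bp_insertion_is_sv(self):
        a, b = self.make_pair("ins60")
        variants, _ = self.run(a, b)
        svs = variants[variants["class"] == "SV"]
        assert len(svs) == 1
        assert svs.iloc[0].length == 60
        assert svs.iloc[0].kind == "INS"

    def test_role_swap_maps_insertions_to_deletions(self):
        a, b = self.make_pair("ins60")
        fwd, _ = self.run(a, b)
        rev, _ = self.run(b, a)
        assert (fwd["class"] == "SNP").sum() == (rev["class"] == "SNP").sum()
        assert (fwd.kind == "INS").sum() == (rev.kind == "DEL").sum()
        assert (fwd.kind == "DEL").sum() == (rev.kind == "INS").sum()

    def test_accepted_blocks_satisfy_screen_criteria(self, synteny_blocks):
        for b in synteny_blocks:
            assert b.length_ratio <= 3.0
            assert b.coverage > 0.5

    def test_simulated_recovery(self, genome_truth, annotated_genes,
                                synteny_blocks):
        cfg = genome_truth.config
        seqs1 = {c: decode_seq(genome_truth.seqs[(c, 1)])
                 for c in range(1, cfg.n_chromosomes + 1)}
        seqs2 = {c: decode_seq(genome_truth.seqs[(c, 2)])
                 for c in range(1, cfg.n_chromosomes + 1)}
        variants, cols = call_all_variants(synteny_blocks, seqs1, seqs2,
                                           annotated_genes)
        v = genome_truth.variants
        true_in_blocks = 0
        for blk in synteny_blocks:
            sel = v[(v.chrom == blk.chrom) & (v.pos_h1 >= blk.h1_start)
                    & (v.pos_h1 <= blk.h1_end) & (v["class"] == "SNP")]
            true_in_blocks += len(sel)
        called = int((variants["class"] == "SNP").sum())
        assert abs(called - true_in_blocks) / true_in_blocks < 0.05
        div = intragenomic_diversity(variants, cols)
        assert abs(div - true_diversity_percent(genome_truth)) \
            / true_diversity_percent(genome_truth) < 0.10


class TestEffects:
    BASE = ("ATG" + "GCT GAA CTT AAA GGT CAT ATT CCG".replace(" ", "") * 10
            + "TAA")

    def test_inframe_57bp_insertion_adds_19_residues(self):
        cds_a = self.BASE
        ins = "GCA" * 19                    # 57 nt, in frame, no stops
        k = 33                              # codon boundary
        cds_b = cds_a[:k] + ins + cds_a[k:]
        ann = classify_cds_effect(cds_a, cds_b)
        assert ann.effect == "inframe_insertion"
        assert ann.residues_changed == 19

    def test_premature_stop(self):
        cds_a = "ATG" + "CAA" * 20 + "TAA"
        cds_b = "ATG" + "CAA" * 10 + "TAA" + "CAA" * 9 + "TAA"
        ann = classify_cds_effect(cds_a, cds_b)
        assert ann.effect == "premature_stop"

    def test_synonymous(self):
        cds_a = "ATG" + "GCT" * 5 + "TAA"
        cds_b = "ATG" + "GCC" + "GCT" * 4 + "TAA"
        assert classify_cds_effect(cds_a, cds_b).effect == "synonymous"

    def test_missense_counts_residues(self):
        cds_a = "ATG" + "GCT" * 5 + "TAA"
        cds_b = "ATG" + "GAT" + "GCT" * 3 + "GAT" + "TAA"
        ann = classify_cds_effect(cds_a, cds_b)
        assert ann.effect == "missense"
        assert ann.residues_changed == 2

    def test_frameshift_precedence(self):
        cds_a = "ATG" + "GCT" * 10 + "TAA"
        cds_b = "ATG" + "G" + "GCT" * 10 + "TAA"
        assert classify_cds_effect(cds_a, cds_b).effect == "frameshift"

    def test_identical(self):
        cds = "ATG" + "GCT" * 5 + "TAA"
        assert classify_cds_effect(cds, cds).effect == "identical"

    def test_reference_internal_stop_flagged(self):
        cds_a = "ATG" + "CAA" * 3 + "TAA" + "CAA" * 3 + "TAA"
        cds_b = cds_a.replace("CAA", "CAA", 1)
        ann = classify_cds_effect(cds_a, cds_b)
        assert ann.pseudogene_like


class TestDiversity:
    def test_worked_arithmetic(self):
        import pandas as pd
        v = pd.DataFrame({"class": ["SNP"] * 21,
                          "length": [1] * 21})
        assert intragenomic_diversity(v, 1000) == pytest.approx(2.1)

    def test_no_variants_zero(self):
        import pandas as pd
        v = pd.DataFrame({"class": [], "length": []})
        assert intragenomic_diversity(v, 1000) == 0.0

    def test_zero_aligned_raises(self):
        import pandas as pd
        v = pd.DataFrame({"class": [], "length": []})
        with pytest.raises(ValueError):
            intragenomic_diversity(v, 0)
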