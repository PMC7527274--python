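"""Linkage correlation, grouping, haplotype splitting, rescue rules and
chimera detection/breaking."""

import numpy as np
import pandas as pd
import pytest

from hapline import SimConfig
from hapline.genotyping import MISSING, GenotypeMatrix, call_dosage
from hapline.phasing import (
    break_scaffolds, build_linkage_groups, detect_chimeras, masked_pearson,
    pairwise_linkage, phase_scaffolds, phasing_accuracy, rescue_unassigned,
    split_haplotypes)
from hapline.simulate import ProgenyCountMatrix, Scaffold, simulate_all


def geno(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    return GenotypeMatrix(
        scaffold_ids=[f"s{i}" for i in range(dosage.shape[0])],
        progeny_ids=[f"p{j}" for j in range(dosage.shape[1])],
        dosage=dosage, confidence=np.ones(dosage.shape))


@pytest.fixture(scope="module")
def base_vec():
    rng = np.random.default_rng(5)
    return rng.integers(0, 3, size=100).astype(np.int8)


class TestPairwiseLinkage:
    def test_identical_vectors_correlate_perfectly(self, base_vec):
        g = geno([base_vec, base_vec])
        r = pairwise_linkage(g)
        assert r[0, 1] == pytest.approx(1.0)

    def test_complementary_haplotypes_anticorrelate(self, base_vec):
        g = geno([base_vec, 2 - base_vec])
        assert pairwise_linkage(g)[0, 1] == pytest.approx(-1.0)

    def test_insufficient_overlap_is_missing(self, base_vec):
        other = base_vec.copy()
        other[:80] = MISSING
        g = geno([base_vec, other])
        assert np.isnan(pairwise_linkage(g, min_overlap=30)[0, 1])

    def test_constant_vector_is_missing_not_nan_propagation(self, base_vec):
        g = geno([base_vec, np.ones(100, dtype=np.int8)])
        r = pairwise_linkage(g)
        assert np.isnan(r[0, 1])
        assert r[0, 0] == 1.0

    def test_unlinked_chromosomes_near_zero(self, default_sim,
                                            default_genotypes,
                                            default_phase):
        _, truth, _ = default_sim
        similarity, _ = default_phase
        chrom = np.array([s.segments[0][0] for s in truth.scaffolds])
        a = np.flatnonzero(chrom == 1)[:40]
        b = np.flatnonzero(chrom == 2)[:40]
        cross = similarity[np.ix_(a, b)]
        assert np.nanmax(np.abs(cross)) < 0.3


class TestGrouping:
    def test_two_chromosomes_two_components(self, default_sim,
                                            default_phase):
        _, truth, _ = default_sim
        similarity, _ = default_phase
        groups = build_linkage_groups(similarity, threshold=0.7)
        assert len(groups) == 2

    def test_degenerate_threshold_gives_no_groups(self, default_phase):
        similarity, _ = default_phase
        assert build_linkage_groups(similarity, threshold=1.01) == []

    def test_partition_matches_true_chromosomes(self, default_sim,
                                                default_phase):
        _, truth, _ = default_sim
        similarity, _ = default_phase
        groups = build_linkage_groups(similarity, threshold=0.7)
        chrom = np.array([s.segments[0][0] for s in truth.scaffolds])
        n_informative = sum(len(g) for g in groups)
        n_pure = sum(np.bincount(chrom[g]).max() for g in groups)
        assert n_pure / n_informative >= 0.99


class TestSplit:
    def test_symmetric_construction_splits_cleanly(self, base_vec):
        g = geno([base_vec, base_vec, 2 - base_vec, 2 - base_vec])
        sim = pairwise_linkage(g)
        c1, c2, low = split_haplotypes(np.arange(4), sim)
        assert not low
        assert {tuple(sorted(c1)), tuple(sorted(c2))} == {(0, 1), (2, 3)}

    def test_identical_vectors_flagged_low_confidence(self, base_vec):
        g = geno([base_vec] * 4)
        sim = pairwise_linkage(g)
        c1, c2, low = split_haplotypes(np.arange(4), sim)
        assert low
        assert len(c1) and len(c2)

    def test_simulated_group_recovers_haplotypes(self, default_sim,
                                                 default_genotypes,
                                                 default_phase):
        _, truth, _ = default_sim
        similarity, assignment = default_phase
        acc = phasing_accuracy(assignment, truth.scaffolds)
        assert acc >= 0.95

    def test_complementarity_within_groups(self, default_phase):
        similarity, assignment = default_phase
        t = assignment.table
        for grp, sub in t[t.haplotype != 0].groupby("group"):
            i1 = sub.index[sub.haplotype == 1].to_numpy()
            i2 = sub.index[sub.haplotype == 2].to_numpy()
            within = np.concatenate([
                similarity[np.ix_(i1, i1)].ravel(),
                similarity[np.ix_(i2, i2)].ravel()])
            cross = similarity[np.ix_(i1, i2)].ravel()
            assert np.nanmean(within) > 0
            assert np.nanmean(cross) < 0


def rescue_fixture(rng, q_noise=0.05, second_corr_high=True,
                   same_hap=True):
    """Counts where the query correlates strongly with two targets."""
    n = 200
    base = rng.integers(0, 3, size=n).astype(float)
    other = rng.integers(0, 3, size=n).astype(float)
    lam = 40.0
    rows = []
    for v in (base, base, other, other):
        rows.append(rng.poisson(lam * (v + 0.2)))
    # query follows `base` (with optional noise to damp the 2nd correlation)
    qv = base.copy()
    flip = rng.random(n) < (0.02 if second_corr_high else 0.35)
    qv[flip] = rng.integers(0, 3, size=flip.sum())
    rows.append(rng.poisson(lam * (qv + 0.2)))
    counts = np.vstack(rows)
    pcm = ProgenyCountMatrix(
        scaffold_ids=["t1", "t2", "t3", "t4", "q"],
        scaffold_lengths=np.full(5, 10_000),
        progeny_ids=[f"p{j}" for j in range(n)],
        counts=counts, progeny_totals=np.full(n, 10_000),
        assembly_total_length=1_000_000)
    hap2 = 1 if same_hap else 2
    table = pd.DataFrame({
        "scaffold": pcm.scaffold_ids,
        "group": [1, 1, 2, 2, 0],
        "haplotype": [1, hap2, 1, 1, 0],
        "method": ["clustered"] * 4 + ["unassigned"],
        "support": [1.0] * 4 + [np.nan]})
    from hapline.phasing import PhaseAssignment
    return pcm, PhaseAssignment(table)


class TestRescue:
    def test_top_two_same_group_assigned(self):
        pcm, asg = rescue_fixture(np.random.default_rng(1))
        out = rescue_unassigned(asg, pcm)
        row = out.table[out.table.scaffold == "q"].iloc[0]
        assert row.haplotype == 1 and row.group == 1
        assert row.method == "rescued"
        assert row.support > 0.7

    def test_weak_second_correlation_unassigned(self):
        pcm, asg = rescue_fixture(np.random.default_rng(2),
                                  second_corr_high=False)
        out = rescue_unassigned(asg, pcm)
        assert out.table[out.table.scaffold == "q"].iloc[0].haplotype == 0

    def test_conflicting_haplotypes_unassigned(self):
        pcm, asg = rescue_fixture(np.random.default_rng(3), same_hap=False)
        out = rescue_unassigned(asg, pcm)
        assert out.table[out.table.scaffold == "q"].iloc[0].haplotype == 0

    def test_never_reassigns_clustered(self):
        pcm, asg = rescue_fixture(np.random.default_rng(4))
        out = rescue_unassigned(asg, pcm)
        before = asg.table[asg.table.haplotype != 0]
        after = out.table.loc[before.index]
        pd.testing.assert_frame_equal(before, after)


def window_pcm(vec, n_windows=10, flip_from=5, lam2=40.0):
    """Scaffold with per-window counts: first windows follow ``vec``,
    the rest its complement."""
    n = len(vec)
    w = 50_000
    G = 10_000_000
    T = np.full(n, int(lam2 * G / w))
    rng = np.random.default_rng(11)
    mats = []
    for i in range(n_windows):
        v = vec if i < flip_from else 2 - vec
        mats.append(rng.poisson(lam2 * v / 2.0))
    wmat = np.vstack(mats)
    edges = np.arange(0, (n_windows + 1) * w, w)
    counts = wmat.sum(axis=0)[None, :]
    pcm = ProgenyCountMatrix(
        scaffold_ids=["scf"], scaffold_lengths=np.array([n_windows * w]),
        progeny_ids=[f"p{j}" for j in range(n)],
        counts=np.vstack([counts]), progeny_totals=T,
        assembly_total_length=G,
        window_counts={"scf": (edges, wmat)})
    return pcm


class TestChimeras:
    def test_constructed_junction_found_at_boundary(self, base_vec):
        pcm = window_pcm(base_vec)
        reports = detect_chimeras(pcm, window_size=50_000)
        assert len(reports) == 1
        assert reports[0].breakpoints == [5 * 50_000]

    def test_non_chimeric_scaffold_clean(self, base_vec):
        pcm = window_pcm(base_vec, flip_from=10)
        reports = detect_chimeras(pcm, window_size=50_000)
        assert reports[0].breakpoints == []

    def test_simulated_recall_and_precision(self):
        cfg = SimConfig(seed=23, n_chromosomes=8, chrom_length=3_000_000,
                        genes_per_chromosome=30, n_progeny=200,
                        scaffold_n50=500_000, chimera_rate=0.2,
                        window_size=100_000)
        truth, pcm = simulate_all(cfg)
        true_bp = {s.scaffold_id: s.breakpoints
                   for s in truth.scaffolds if s.is_chimeric}
        assert len(true_bp) >= 6
        reports = detect_chimeras(pcm, window_size=cfg.window_size)
        tp = fp = 0
        for r in reports:
            for bp in r.breakpoints:
                truth_list = true_bp.get(r.scaffold_id, [])
                if any(abs(bp - t) <= cfg.window_size for t in truth_list):
                    tp += 1
                else:
                    fp += 1
        total = sum(len(v) for v in true_bp.values())
        assert tp / total >= 0.9
        assert tp / max(tp + fp, 1) >= 0.9

    def test_breaking_chimeras_improves_phasing(self):
        cfg = SimConfig(seed=29, n_chromosomes=4, chrom_length=3_000_000,
                        genes_per_chromosome=30, n_progeny=200,
                        scaffold_n50=600_000, chimera_rate=0.4,
                        window_size=100_000)
        truth, pcm = simulate_all(cfg)
        assert any(s.is_chimeric for s in truth.scaffolds)

        def phase_acc(m, scaffolds):
            gm = call_dosage(m)
            sim = pairwise_linkage(gm)
            asg = phase_scaffolds(gm, sim)
            return phasing_accuracy(asg, scaffolds)

        before = phase_acc(pcm, truth.scaffolds)
        reports = detect_chimeras(pcm, window_size=cfg.window_size)
        pcm2, scf2 = break_scaffolds(pcm, truth.scaffolds, reports)
        after = phase_acc(pcm2, scf2)
        assert after > before
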