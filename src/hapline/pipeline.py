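"""End-to-end orchestration: simulate -> genotype -> phase -> SD scan ->
synteny -> variants/effects -> DEL -> DMR, with a machine-readable summary.

Each stage writes its outputs under the run directory with a header noting
package version, config hash and seed.  When simulation truth is available
the summary additionally reports parameter-recovery metrics (phasing
accuracy, recovered diversity, DEL power, DMR recovery).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig, SimConfig
from .expression import del_summary, del_test
from .genotyping import call_dosage, filter_markers, normalize_counts
from .methylation import (annotate_gene_methylation, call_dmps, collapse_dmrs,
                          pair_sites)
from .phasing import (break_scaffolds, detect_chimeras, pairwise_linkage,
                      phase_scaffolds, phasing_accuracy, rescue_unassigned)
from .sdscan import exclusion_runs, scan_sd, window_genotypes
from .simulate import (ProgenyCountMatrix, TruthSet, allelic_pairs_truth,
                       decode_seq, simulate_all, simulate_expression,
                       simulate_methylation)
from .synteny import (AnnotatedGene, call_all_variants, call_pav_genes,
                      chain_synteny_blocks, classify_pairs, find_homologs,
                      intragenomic_diversity, pair_alleles)

logger = logging.getLogger(__name__)


def truth_genes_to_annotated(truth: TruthSet) -> dict[str, AnnotatedGene]:
    out = {}
    for g in truth.genes:
        out[g.gene_id] = AnnotatedGene(
            gene_id=g.gene_id, chrom=g.chrom, haplotype=g.haplotype,
            start=g.start, end=g.end, strand=g.strand, cds=g.cds(truth))
    return out


def run_pipeline(sim_config: SimConfig,
                 pipe_config: PipelineConfig | None = None,
                 outdir: str | Path | None = None,
                 stages: set[str] | None = None) -> dict:
    """Run the full pipeline on a fresh simulation; returns the summary.

    ``stages`` restricts execution (dependencies are always satisfied);
    valid names: phase, sdscan, synteny, expression, methylation.
    """
    if pipe_config is None:
        pipe_config = PipelineConfig()
    all_stages = {"phase", "sdscan", "synteny", "expression", "methylation"}
    stages = all_stages if stages is None else set(stages)
    unknown = stages - all_stages
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    summary: dict = {"seed": sim_config.seed,
                     "sim_config": sim_config.config_hash(),
                     "pipe_config": pipe_config.config_hash(),
                     "stages": sorted(stages)}
    write = outdir is not None
    if write:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    seed, chash = sim_config.seed, sim_config.config_hash()

    stage = "simulate"
    try:
        truth, pcm = simulate_all(sim_config)
        summary["n_scaffolds"] = len(truth.scaffolds)
        summary["n_progeny"] = truth.n_progeny
        summary["genome_length"] = truth.total_length()

        if write:
            _write_simulation(outdir, truth, pcm, seed, chash)

        stage = "genotype"
        gm = call_dosage(pcm, min_llr=pipe_config.min_llr,
                         min_lambda2=pipe_config.min_lambda2)
        gm = filter_markers(gm, max_missing=pipe_config.max_missing)
        summary["n_informative_scaffolds"] = int(gm.informative.sum())
        if write:
            io.write_tsv(outdir / "genotypes.tsv", gm.to_frame(),
                         seed, chash, index=True)

        assignment = None
        scaffolds = truth.scaffolds
        if "phase" in stages or "sdscan" in stages:
            stage = "phase"
            if sim_config.chimera_rate > 0 or pcm.window_counts:
                reports = detect_chimeras(
                    pcm, window_size=pipe_config.window_size,
                    contrary_threshold=pipe_config.contrary_threshold,
                    min_overlap=pipe_config.min_overlap,
                    min_llr=pipe_config.min_llr,
                    min_lambda2=pipe_config.min_lambda2)
                n_broken = sum(1 for r in reports if r.breakpoints)
                summary["n_chimeras_broken"] = n_broken
                if n_broken:
                    pcm, scaffolds = break_scaffolds(pcm, scaffolds, reports)
                    gm = call_dosage(pcm, min_llr=pipe_config.min_llr,
                                     min_lambda2=pipe_config.min_lambda2)
                    gm = filter_markers(gm,
                                        max_missing=pipe_config.max_missing)
                if write and reports:
                    io.write_bed(outdir / "chimera_breakpoints.bed",
                                 [(r.scaffold_id, bp + 1, bp + 1)
                                  for r in reports for bp in r.breakpoints],
                                 seed, chash)
            similarity = pairwise_linkage(gm,
                                          min_overlap=pipe_config.min_overlap)
            assignment = phase_scaffolds(
                gm, similarity, threshold=pipe_config.corr_threshold,
                min_group_size=pipe_config.min_group_size,
                expected_groups=sim_config.n_chromosomes)
            assignment = rescue_unassigned(
                assignment, pcm, threshold=pipe_config.rescue_threshold,
                min_overlap=pipe_config.min_overlap)
            summary["n_assigned_scaffolds"] = len(assignment.assigned())
            informative_ids = {sid for sid, ok
                               in zip(gm.scaffold_ids, gm.informative) if ok}
            summary["phasing_accuracy"] = phasing_accuracy(
                assignment, scaffolds, informative_ids)
            if write:
                io.write_tsv(outdir / "phase.tsv", assignment.table,
                             seed, chash)

        if "sdscan" in stages:
            stage = "sdscan"
            wt = window_genotypes(gm, assignment, scaffolds,
                                  window=pipe_config.sd_window,
                                  min_progeny=pipe_config.sd_min_n)
            sd = scan_sd(wt, alpha=pipe_config.sd_alpha,
                         min_n=pipe_config.sd_min_n,
                         exclusion_eps=pipe_config.exclusion_eps,
                         window_morgans=(pipe_config.sd_window
                                         * sim_config.map_length_morgans
                                         / sim_config.chrom_length))
            runs = exclusion_runs(sd)
            summary["sd_windows_testable"] = int(sd.windows.testable.sum())
            summary["sd_distorted_fraction"] = sd.distorted_fraction()
            summary["n_exclusion_runs"] = len(runs)
            if write:
                io.write_tsv(outdir / "sd_windows.tsv", sd.windows,
                             seed, chash)
                io.write_tsv(outdir / "exclusion_runs.tsv", runs, seed, chash)

        blocks, variants, genes = None, None, None
        if "synteny" in stages or "methylation" in stages:
            stage = "synteny"
            genes = truth_genes_to_annotated(truth)
            g1 = [g for g in genes.values() if g.haplotype == 1]
            g2 = [g for g in genes.values() if g.haplotype == 2]
            hits = find_homologs(
                g1, g2, min_coverage=pipe_config.homolog_min_coverage,
                min_identity=pipe_config.homolog_min_identity)
            blocks = chain_synteny_blocks(
                hits, genes, min_anchors=pipe_config.min_anchors,
                max_gap=pipe_config.max_anchor_gap,
                max_length_ratio=pipe_config.max_length_ratio,
                min_block_coverage=pipe_config.min_block_coverage)
            pairs = pair_alleles(blocks, hits, genes)
            pav = call_pav_genes(blocks, hits, genes)
            seqs1 = {c: decode_seq(truth.seqs[(c, 1)])
                     for c in range(1, sim_config.n_chromosomes + 1)}
            seqs2 = {c: decode_seq(truth.seqs[(c, 2)])
                     for c in range(1, sim_config.n_chromosomes + 1)}
            variants, aligned_cols = call_all_variants(
                blocks, seqs1, seqs2, genes,
                max_align_len=pipe_config.max_align_len)
            effects = classify_pairs(pairs, genes)
            summary["n_homolog_hits"] = len(hits)
            summary["n_blocks"] = len(blocks)
            summary["n_allelic_pairs"] = len(pairs)
            summary["n_reliable_pairs"] = int(pairs.reliable.sum())
            summary["n_pav_genes"] = len(pav)
            summary["n_snps"] = int((variants["class"] == "SNP").sum())
            summary["n_indels"] = int((variants["class"] == "indel").sum())
            summary["n_svs"] = int((variants["class"] == "SV").sum())
            summary["diversity_percent"] = intragenomic_diversity(
                variants, aligned_cols)
            summary["effect_counts"] = \
                effects.effect.value_counts().to_dict()
            if write:
                io.write_tsv(outdir / "blocks.tsv", pd.DataFrame(
                    [{"block_id": b.block_id, "chrom": b.chrom,
                      "orientation": b.orientation,
                      "h1_start": b.h1_start, "h1_end": b.h1_end,
                      "h2_start": b.h2_start, "h2_end": b.h2_end,
                      "n_anchors": len(b.anchors)} for b in blocks]),
                    seed, chash)
                io.write_tsv(outdir / "allelic_pairs.tsv", pairs, seed, chash)
                if len(pav):
                    io.write_bed(outdir / "pav_genes.bed",
                                 [(f"chr{r.chrom}_{r.haplotype}", r.start,
                                   r.end, r.gene_id)
                                  for r in pav.itertuples(index=False)],
                                 seed, chash)
                contigs = {f"chr{c}_1": len(truth.seqs[(c, 1)])
                           for c in range(1, sim_config.n_chromosomes + 1)}
                vcf_df = pd.DataFrame({
                    "chrom": [f"chr{c}_1" for c in variants.chrom],
                    "pos": variants.pos_h1, "ref": variants.ref,
                    "alt": variants.alt, "type": variants["class"]})
                io.write_vcf(outdir / "variants_h1.vcf", vcf_df,
                             "haplotype1", contigs, seed, chash)
                io.write_tsv(outdir / "effects.tsv", effects, seed, chash)

        if "expression" in stages:
            stage = "expression"
            expr, del_truth = simulate_expression(truth, sim_config)
            res = del_test(expr, max_cv=pipe_config.max_cv,
                           min_summed_tpm=pipe_config.min_summed_tpm,
                           fdr=pipe_config.fdr,
                           fdr_method=pipe_config.fdr_method)
            summ = del_summary(res)
            n_del = int(summ.is_del.sum()) if len(summ) else 0
            summary["n_del_pairs"] = n_del
            summary["n_tested_pairs"] = len(summ)
            if len(del_truth):
                called = set(summ.loc[summ.is_del, "pair_id"])
                truth_ids = set(del_truth.pair_id)
                summary["del_power"] = (len(called & truth_ids)
                                        / len(truth_ids))
            if write:
                io.write_tsv(outdir / "expression.tsv", expr, seed, chash)
                io.write_tsv(outdir / "del_results.tsv", res, seed, chash)

        if "methylation" in stages:
            stage = "methylation"
            sites1, sites2, dmr_truth = simulate_methylation(truth,
                                                             sim_config)
            paired = pair_sites(sites1, sites2, blocks, variants)
            dmps = call_dmps(paired,
                             thresholds=pipe_config.meth_thresholds,
                             min_depth=pipe_config.meth_min_depth,
                             max_p=pipe_config.meth_p)
            dmrs = collapse_dmrs(dmps, max_gap=pipe_config.dmr_max_gap,
                                 min_sites=pipe_config.dmr_min_sites)
            tp = allelic_pairs_truth(truth)
            gene_coords = {g.gene_id: (g.chrom, g.start, g.end)
                           for g in truth.genes}
            annotated = annotate_gene_methylation(
                dmrs, tp, gene_coords, flank=pipe_config.gene_flank)
            summary["n_paired_sites"] = int(
                paired[["chrom", "pos_h1"]].drop_duplicates().shape[0])
            summary["n_dmps"] = len(dmps)
            summary["n_dmrs"] = len(dmrs)
            summary["n_methylation_diff_pairs"] = int(
                annotated.differentially_methylated.sum())
            if len(dmr_truth):
                recovered = 0
                for t in dmr_truth.itertuples(index=False):
                    sel = dmrs[(dmrs.chrom.astype(str) == str(t.chrom))
                               & (dmrs.start <= t.end)
                               & (dmrs.end >= t.start)]
                    if len(sel):
                        recovered += 1
                summary["dmr_recovery"] = recovered / len(dmr_truth)
            if write:
                io.write_tsv(outdir / "dmps.tsv", dmps, seed, chash)
                if len(dmrs):
                    io.write_bed(outdir / "dmrs.bed",
                                 [(f"chr{r.chrom}_1", r.start, r.end,
                                   f"{r.context};hyper_h{r.hyper_haplotype}")
                                  for r in dmrs.itertuples(index=False)],
                                 seed, chash)
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        summary["failed_stage"] = stage
        raise

    if write:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        _write_report(outdir / "report.txt", summary)
    return summary


def _write_simulation(outdir: Path, truth: TruthSet, pcm: ProgenyCountMatrix,
                      seed: int, chash: str) -> None:
    from .simulate import scaffold_sequence
    cfg = truth.config
    for hap in (1, 2):
        io.write_fasta(outdir / f"haplotype{hap}.fasta",
                       [(f"chr{c}_{hap}", decode_seq(truth.seqs[(c, hap)]))
                        for c in range(1, cfg.n_chromosomes + 1)])
    gff = [io.Gff3Record(seqid=f"chr{g.chrom}_{g.haplotype}",
                         source="hapline_sim", type="gene",
                         start=g.start, end=g.end, strand=g.strand,
                         attributes={"ID": g.gene_id,
                                     "pair_id": str(g.pair_id),
                                     "is_pav": str(int(g.is_pav))})
           for g in truth.genes]
    io.write_gff3(outdir / "genes.gff3", gff, seed, chash)
    io.write_fasta(outdir / "scaffolds.fasta",
                   [(s.scaffold_id, scaffold_sequence(truth, s))
                    for s in truth.scaffolds])
    io.write_tsv(outdir / "counts.tsv", pcm.to_frame(), seed, chash,
                 index=True)
    io.write_tsv(outdir / "scaffold_truth.tsv", truth.scaffold_frame(),
                 seed, chash)
    io.write_tsv(outdir / "variant_truth.tsv", truth.variants, seed, chash)
    agp = []
    for s in truth.scaffolds:
        off = 0
        for i, (c, h, a, b) in enumerate(s.segments, start=1):
            agp.append(io.AgpRow(s.scaffold_id, off + 1, off + (b - a + 1),
                                 i, "W", f"chr{c}_{h}", a, b))
            off += b - a + 1
    io.write_agp(outdir / "scaffolds.agp", agp, seed, chash)


def _write_report(path: Path, summary: dict) -> None:
    with open(path, "w") as fh:
        fh.write("hapline pipeline report\n")
        fh.write("=======================\n")
        for k in sorted(summary):
            fh.write(f"{k}: {summary[k]}\n")
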