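"""Haplotype comparison: homologs, synteny blocks, allelic genes, PAV,
variant calling and CDS-effect classification.

The two phased haplotypes are compared gene-first: CDS-level homolog
screening (coverage > 75% and identity > 75%), collinear chaining of homolog
anchors into synteny blocks, best-homolog allelic pairing (mutual-best pairs
flagged reliable), presence/absence (PAV) calling for genes missing a
homolog inside otherwise collinear flanks, and base-level variant calling of
the inter-anchor sequence segments.  Variants are classified as SNPs,
indels (1-50 bp) or SVs (>50 bp); allelic CDS differences are classified by
their protein-level effect.

Coordinates are 1-based inclusive throughout this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

SV_MIN_LEN = 51          # SVs are >50 bp; indels are 1-50 bp


@dataclass
class AnnotatedGene:
    gene_id: str
    chrom: int | str
    haplotype: int
    start: int
    end: int
    strand: str
    cds: str


@dataclass
class HomologHit:
    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    score: float


@dataclass
class SyntenyBlock:
    block_id: int
    chrom: int | str
    orientation: str                  # '+' or '-'
    h1_start: int
    h1_end: int
    h2_start: int
    h2_end: int
    anchors: list[tuple[str, str]] = field(default_factory=list)
    # screening diagnostics
    length_ratio: float = 1.0
    coverage: float = 1.0


_CORE_ALIGNER = None


def _core_aligner() -> "Align.PairwiseAligner":
    """Fully penalized global affine aligner for small region cores."""
    global _CORE_ALIGNER
    if _CORE_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = -2.0
        aligner.open_gap_score = -4.0
        aligner.extend_gap_score = -1.0
        _CORE_ALIGNER = aligner
    return _CORE_ALIGNER


def _make_aligner(match: float = 1.0, mismatch: float = -2.0,
                  gap_open: float = -4.0, gap_extend: float = -1.0
                  ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def alignment_stats(query: str, target: str,
                    aligner: Align.PairwiseAligner | None = None
                    ) -> tuple[float, float, float]:
    """(coverage, identity, score) of the best pairwise alignment.

    coverage = aligned fraction of the query; identity = matches / columns
    within the aligned region (internal gaps count as columns).
    """
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(query, target)[0]
    blocks = aln.aligned                 # (target blocks, query blocks)
    tb, qb = blocks
    if len(tb) == 0:
        return 0.0, 0.0, float(aln.score)
    matches = 0
    aligned_q = 0
    for (ta, tz), (qa, qz) in zip(tb, qb):
        sub_t = target[ta:tz]
        sub_q = query[qa:qz]
        matches += sum(1 for x, y in zip(sub_t, sub_q) if x == y)
        aligned_q += qz - qa
    tspan = tb[-1][1] - tb[0][0]
    qspan = qb[-1][1] - qb[0][0]
    block_cols = sum(tz - ta for ta, tz in tb)
    columns = tspan + qspan - block_cols
    coverage = aligned_q / len(query) if len(query) else 0.0
    identity = matches / columns if columns else 0.0
    return coverage, identity, float(aln.score)


# ---------------------------------------------------------------------------
# Homolog screening
# ---------------------------------------------------------------------------

def find_homologs(genes_h1: list[AnnotatedGene], genes_h2: list[AnnotatedGene],
                  min_coverage: float = 0.75, min_identity: float = 0.75,
                  max_offset: int = 1_000_000,
                  prefilter_distance: float = 0.45,
                  aligner: Align.PairwiseAligner | None = None
                  ) -> list[HomologHit]:
    """Pairwise CDS comparison between haplotypes on homologous chromosomes.

    Candidates are limited to genes within ``max_offset`` bp; an edit-distance
    prefilter skips hopeless pairs before the full affine alignment computes
    coverage and identity against the acceptance thresholds.
    """
    if aligner is None:
        aligner = _make_aligner()
    hits = []
    by_chrom: dict = {}
    for g in genes_h2:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    for ga in genes_h1:
        if not ga.cds:
            logger.info("gene %s skipped: empty CDS", ga.gene_id)
            continue
        for gb in by_chrom.get(ga.chrom, []):
            if not gb.cds:
                continue
            if abs(gb.start - ga.start) > max_offset:
                continue
            maxlen = max(len(ga.cds), len(gb.cds))
            res = edlib.align(ga.cds, gb.cds, mode="NW", task="distance")
            if res["editDistance"] / maxlen > prefilter_distance:
                continue
            cov, ident, score = alignment_stats(ga.cds, gb.cds, aligner)
            if cov > min_coverage and ident > min_identity:
                hits.append(HomologHit(ga.gene_id, gb.gene_id,
                                       cov, ident, score))
    return hits


def best_hits(hits: list[HomologHit], genes: dict[str, AnnotatedGene]
              ) -> dict[str, HomologHit]:
    """Best-scoring accepted hit per gene (either side), score then
    partner-coordinate tie-break."""
    best: dict[str, HomologHit] = {}

    def partner_of(h: HomologHit, gene: str) -> str:
        return h.gene_b if h.gene_a == gene else h.gene_a

    for h in hits:
        for gene in (h.gene_a, h.gene_b):
            old = best.get(gene)
            if old is None:
                best[gene] = h
                continue
            po = genes[partner_of(old, gene)].start
            pn = genes[partner_of(h, gene)].start
            if (h.score, -pn) > (old.score, -po):
                best[gene] = h
    return best


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------

def _chain_once(anchors: list[tuple[int, int, int]], max_gap: int,
                sign: int) -> list[int]:
    """Longest chain with i strictly increasing and sign*j strictly
    increasing, gaps on both orders <= max_gap.  anchors: (i, j, anchor idx).
    Returns positions into ``anchors`` of the best chain."""
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    order = sorted(range(n), key=lambda k: (anchors[k][0], sign * anchors[k][1]))
    for a_pos, a in enumerate(order):
        ia, ja = anchors[a][0], sign * anchors[a][1]
        for b in order[:a_pos]:
            ib, jb = anchors[b][0], sign * anchors[b][1]
            if ib < ia and jb < ja and ia - ib <= max_gap + 1 \
                    and ja - jb <= max_gap + 1:
                if best_len[b] + 1 > best_len[a]:
                    best_len[a] = best_len[b] + 1
                    prev[a] = b
    end = int(np.argmax(best_len))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_synteny_blocks(hits: list[HomologHit],
                         genes: dict[str, AnnotatedGene],
                         min_anchors: int = 5, max_gap: int = 25,
                         max_length_ratio: float = 3.0,
                         min_block_coverage: float = 0.5
                         ) -> list[SyntenyBlock]:
    """Chain homolog anchors into collinear blocks, then screen the blocks:
    homologous chromosomes (by construction), length ratio <= 3, and anchor
    span covering > 50% of the block's territory (span extended halfway
    toward neighbouring blocks)."""
    per_chrom: dict = {}
    for h in hits:
        ga, gb = genes[h.gene_a], genes[h.gene_b]
        if ga.chrom != gb.chrom:
            continue
        per_chrom.setdefault(ga.chrom, []).append(h)
    blocks: list[SyntenyBlock] = []
    bid = 0
    for chrom, chrom_hits in sorted(per_chrom.items(), key=lambda kv: str(kv[0])):
        h1_genes = sorted({h.gene_a for h in chrom_hits},
                          key=lambda g: genes[g].start)
        h2_genes = sorted({h.gene_b for h in chrom_hits},
                          key=lambda g: genes[g].start)
        rank1 = {g: i for i, g in enumerate(h1_genes)}
        rank2 = {g: i for i, g in enumerate(h2_genes)}
        # dedupe anchors on (i, j), best score wins
        anchor_map: dict[tuple[int, int], HomologHit] = {}
        for h in chrom_hits:
            key = (rank1[h.gene_a], rank2[h.gene_b])
            if key not in anchor_map or h.score > anchor_map[key].score:
                anchor_map[key] = h
        remaining = [(i, j, h) for (i, j), h in sorted(anchor_map.items())]
        chrom_blocks = []
        while len(remaining) >= min_anchors:
            coords = [(i, j, k) for k, (i, j, _) in enumerate(remaining)]
            fwd = _chain_once(coords, max_gap, +1)
            rev = _chain_once(coords, max_gap, -1)
            chain, orientation = (fwd, "+") if len(fwd) >= len(rev) \
                else (rev, "-")
            if len(chain) < min_anchors:
                break
            chosen = [remaining[coords[k][2]] for k in chain]
            bid += 1
            anchors = [(h.gene_a, h.gene_b) for _, _, h in chosen]
            a_genes = [genes[a] for a, _ in anchors]
            b_genes = [genes[b] for _, b in anchors]
            blk = SyntenyBlock(
                block_id=bid, chrom=chrom, orientation=orientation,
                h1_start=min(g.start for g in a_genes),
                h1_end=max(g.end for g in a_genes),
                h2_start=min(g.start for g in b_genes),
                h2_end=max(g.end for g in b_genes),
                anchors=anchors)
            chrom_blocks.append(blk)
            used = {id(h) for _, _, h in chosen}
            remaining = [t for t in remaining if id(t[2]) not in used]
        # screening
        chrom_blocks.sort(key=lambda b: b.h1_start)
        for k, blk in enumerate(chrom_blocks):
            len1 = blk.h1_end - blk.h1_start + 1
            len2 = blk.h2_end - blk.h2_start + 1
            blk.length_ratio = max(len1, len2) / min(len1, len2)
            # territory: anchor span extended halfway toward the neighbouring
            # block; at chromosome edges, by one typical anchor spacing
            starts = sorted(genes[a].start for a, _ in blk.anchors)
            spacing = (float(np.median(np.diff(starts)))
                       if len(starts) > 1 else float(len1))
            left_ext = ((blk.h1_start - chrom_blocks[k - 1].h1_end) / 2
                        if k > 0 else spacing)
            right_ext = ((chrom_blocks[k + 1].h1_start - blk.h1_end) / 2
                         if k + 1 < len(chrom_blocks) else spacing)
            territory = len1 + max(left_ext, 0) + max(right_ext, 0)
            blk.coverage = len1 / territory if territory > 0 else 0.0
        accepted = [b for b in chrom_blocks
                    if b.length_ratio <= max_length_ratio
                    and b.coverage > min_block_coverage]
        blocks.extend(accepted)
    return blocks


def brute_force_longest_chain(anchors: list[tuple[int, int]],
                              max_gap: int = 25) -> int:
    """Exhaustive longest collinear subsequence (testing oracle, <=~15
    anchors): maximum over both orientations of the longest subset with
    strictly monotone (i, j) and gaps <= max_gap."""
    from itertools import combinations
    n = len(anchors)
    best = 0
    for sign in (+1, -1):
        pts = sorted((i, sign * j) for i, j in anchors)
        for size in range(n, best, -1):
            found = False
            for combo in combinations(range(n), size):
                ok = True
                for a, b in zip(combo, combo[1:]):
                    ia, ja = pts[a]
                    ib, jb = pts[b]
                    if not (ib > ia and jb > ja and ib - ia <= max_gap + 1
                            and jb - ja <= max_gap + 1):
                        ok = False
                        break
                if ok:
                    best = max(best, size)
                    found = True
                    break
            if found:
                break
    return best


# ---------------------------------------------------------------------------
# Allelic pairing and PAV
# ---------------------------------------------------------------------------

def pair_alleles(blocks: list[SyntenyBlock], hits: list[HomologHit],
                 genes: dict[str, AnnotatedGene]) -> pd.DataFrame:
    """Best-homolog pairing within blocks; mutual-best pairs are 'reliable'.

    Returns columns gene_h1, gene_h2, block_id, score, reliable.
    """
    best = best_hits(hits, genes)
    block_of = _block_lookup(blocks, genes)
    rows = []
    seen = set()
    for gid, h in best.items():
        ga = genes[h.gene_a]
        if gid != h.gene_a:          # iterate from the h1 side only
            continue
        partner = h.gene_b
        key = (h.gene_a, h.gene_b)
        if key in seen:
            continue
        seen.add(key)
        blk = block_of.get(h.gene_a)
        blk_b = block_of.get(h.gene_b)
        mutual = best.get(partner) is not None \
            and best[partner].gene_a == h.gene_a
        in_block = blk is not None and blk_b is not None \
            and blk.block_id == blk_b.block_id
        rows.append({"gene_h1": h.gene_a, "gene_h2": h.gene_b,
                     "block_id": blk.block_id if in_block else 0,
                     "chrom": ga.chrom, "score": h.score,
                     "reliable": bool(mutual and in_block)})
    return pd.DataFrame(rows, columns=["gene_h1", "gene_h2", "block_id",
                                       "chrom", "score", "reliable"])


def _block_lookup(blocks: list[SyntenyBlock], genes: dict[str, AnnotatedGene]
                  ) -> dict[str, SyntenyBlock]:
    out = {}
    for g in genes.values():
        for blk in blocks:
            if g.chrom != blk.chrom:
                continue
            lo, hi = ((blk.h1_start, blk.h1_end) if g.haplotype == 1
                      else (blk.h2_start, blk.h2_end))
            if lo <= g.start and g.end <= hi:
                out[g.gene_id] = blk
                break
    return out


def call_pav_genes(blocks: list[SyntenyBlock], hits: list[HomologHit],
                   genes: dict[str, AnnotatedGene],
                   min_flank: int = 2) -> pd.DataFrame:
    """Genes lacking any accepted homolog while sitting inside a synteny
    block whose >=2 nearest flanking genes on each side are paired and
    collinear.  Genes too close to a block edge are 'not evaluable'."""
    best = best_hits(hits, genes)
    block_of = _block_lookup(blocks, genes)
    has_hit = set()
    for h in hits:
        has_hit.add(h.gene_a)
        has_hit.add(h.gene_b)
    by_hap_chrom: dict = {}
    for g in genes.values():
        by_hap_chrom.setdefault((g.haplotype, g.chrom), []).append(g)
    for lst in by_hap_chrom.values():
        lst.sort(key=lambda g: g.start)
    rows = []
    for (hap, chrom), lst in sorted(by_hap_chrom.items(),
                                    key=lambda kv: (kv[0][0], str(kv[0][1]))):
        for idx, g in enumerate(lst):
            if g.gene_id in has_hit:
                continue
            blk = block_of.get(g.gene_id)
            if blk is None:
                continue
            left = lst[:idx][-min_flank:]
            right = lst[idx + 1:][:min_flank]
            if len(left) < min_flank or len(right) < min_flank:
                continue                   # too close to a block edge
            flank = left + right
            if not all(f.gene_id in best for f in flank):
                continue                   # nearest flanks must be paired
            partners = []
            ok = True
            for f in flank:
                h = best[f.gene_id]
                partner = h.gene_b if h.gene_a == f.gene_id else h.gene_a
                pg = genes[partner]
                if pg.chrom != chrom:
                    ok = False
                    break
                partners.append(pg.start)
            if not ok:
                continue
            diffs = np.diff(partners)
            collinear = bool((diffs > 0).all() or (diffs < 0).all())
            if collinear:
                rows.append({"gene_id": g.gene_id, "haplotype": hap,
                             "chrom": chrom, "start": g.start, "end": g.end,
                             "block_id": blk.block_id})
    return pd.DataFrame(rows, columns=["gene_id", "haplotype", "chrom",
                                       "start", "end", "block_id"])


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

def _left_normalize(seq: str, start0: int, length: int) -> int:
    """Shift a gap run left while the flanking base allows (VCF-style
    left-alignment).  ``seq`` is the sequence containing the gap bases,
    ``start0`` the 0-based start of the run."""
    i = start0
    while i > 0 and seq[i - 1] == seq[i + length - 1]:
        i -= 1
    return i


def _segments_from_anchors(block: SyntenyBlock,
                           genes: dict[str, AnnotatedGene]
                           ) -> list[tuple[int, int, int, int]]:
    """Split the block at anchor midpoints: (h1_lo, h1_hi, h2_lo, h2_hi),
    1-based inclusive.

    The cut points are the midpoints OF the anchor genes (homologous
    positions on both haplotypes by construction), not midpoints between
    anchors, whose two-haplotype coordinates drift apart across indels.
    """
    coords = [(genes[a].start, genes[a].end, genes[b].start, genes[b].end)
              for a, b in block.anchors]
    coords.sort()
    cuts1 = [block.h1_start - 1]
    cuts2 = [block.h2_start - 1]
    for a1s, a1e, a2s, a2e in coords[1:-1]:
        c1 = (a1s + a1e) // 2
        c2 = (a2s + a2e) // 2
        if c1 > cuts1[-1] and c2 > cuts2[-1]:
            cuts1.append(c1)
            cuts2.append(c2)
    cuts1.append(block.h1_end)
    cuts2.append(block.h2_end)
    segs = []
    for k in range(len(cuts1) - 1):
        segs.append((cuts1[k] + 1, cuts1[k + 1], cuts2[k] + 1, cuts2[k + 1]))
    return segs


def align_segment(h1_seg: str, h2_seg: str) -> list[tuple[str, int]]:
    """Edit path of h2 (query) against h1 (target) as (op, length) runs;
    ops 'M' (both), 'I' (extra in h2), 'D' (missing from h2)."""
    res = edlib.align(h2_seg, h1_seg, mode="NW", task="path")
    cigar = res["cigar"]
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ch, int(num)))
            num = ""
    return out


def _difference_regions(path: list[tuple[str, int]], a: str, b: str,
                        min_match_sep: int = 10
                        ) -> list[tuple[int, int, int, int]]:
    """Coalesce X/I/D runs separated by fewer than ``min_match_sep`` matched
    bases into difference regions (a_start, a_end, b_start, b_end),
    0-based half-open.

    A unit-cost edit path represents a long novel insertion or deletion as a
    co-optimal smear of 1-bp gaps and spurious mismatches broken only by
    short chance matches; coalescing reconstitutes the event, since inside
    random sequence a match run of ``min_match_sep`` bases is vanishingly
    unlikely.
    """
    runs = []
    p1 = p2 = 0
    for op, ln in path:
        if op == "M":                # split ambiguous M into =/X
            for k in range(ln):
                if a[p1 + k] == b[p2 + k]:
                    continue
                runs.append([p1 + k, p1 + k + 1, p2 + k, p2 + k + 1])
            p1 += ln
            p2 += ln
            continue
        if op == "=":
            p1 += ln
            p2 += ln
            continue
        a0, b0 = p1, p2
        if op == "X":
            p1 += ln
            p2 += ln
        elif op == "I":
            p2 += ln
        elif op == "D":
            p1 += ln
        else:
            raise ValueError(f"unexpected alignment op {op!r}")
        runs.append([a0, p1, b0, p2])
    merged: list[list[int]] = []
    for r in runs:
        if merged and r[0] - merged[-1][1] < min_match_sep:
            merged[-1][1] = r[1]
            merged[-1][3] = r[3]
        else:
            merged.append(list(r))
    return [tuple(r) for r in merged]


def _emit_region(a: str, b: str, region: tuple[int, int, int, int],
                 h1_lo: int, h2_lo: int, chrom, rows: list) -> None:
    a0, a1, b0, b1 = region
    sub_a, sub_b = a[a0:a1], b[b0:b1]
    la, lb = len(sub_a), len(sub_b)
    pre = 0
    while pre < min(la, lb) and sub_a[pre] == sub_b[pre]:
        pre += 1
    suf = 0
    while suf < min(la, lb) - pre and \
            sub_a[la - 1 - suf] == sub_b[lb - 1 - suf]:
        suf += 1
    ma, mb = sub_a[pre:la - suf], sub_b[pre:lb - suf]
    pa, pb = a0 + pre, b0 + pre      # 0-based start of the trimmed core

    def snp(off_a: int, off_b: int, ref: str, alt: str) -> None:
        rows.append({"class": "SNP", "kind": "SNP", "chrom": chrom,
                     "pos_h1": h1_lo + off_a, "pos_h2": h2_lo + off_b,
                     "ref": ref, "alt": alt, "length": 1})

    def indel(kind: str, off_a: int, off_b: int, gap_seq: str,
              host: str, host_off: int) -> None:
        ln = len(gap_seq)
        start0 = _left_normalize(host, host_off, ln)
        shift = host_off - start0
        gap = host[start0:start0 + ln]
        anchor_a = h1_lo + off_a - shift - 1
        anchor_b = h2_lo + off_b - shift - 1
        ref_base = a[anchor_a - h1_lo] if anchor_a >= h1_lo else "N"
        if kind == "INS":
            ref, alt = ref_base, ref_base + gap
        else:
            ref, alt = ref_base + gap, ref_base
        rows.append({"class": "indel" if ln < SV_MIN_LEN else "SV",
                     "kind": kind, "chrom": chrom,
                     "pos_h1": anchor_a, "pos_h2": anchor_b,
                     "ref": ref, "alt": alt, "length": ln})

    if not ma and not mb:
        return
    if not ma:                        # pure insertion in h2
        indel("INS", pa, pb, mb, b, pb)
        return
    if not mb:                        # pure deletion from h2
        indel("DEL", pa, pb, ma, a, pa)
        return
    if len(ma) == 1 and len(mb) == 1:
        snp(pa, pb, ma, mb)
        return
    # mixed core: affine realignment places the net gap correctly (the
    # unit-cost path that produced the region cannot)
    aln = _core_aligner().align(ma, mb)[0]
    tb, qb = aln.aligned
    prev_t, prev_q = 0, 0
    blocks = list(zip(tb, qb)) + [((len(ma), len(ma)), (len(mb), len(mb)))]
    for (ta, tz), (qa, qz) in blocks:
        if ta > prev_t:
            indel("DEL", pa + prev_t, pb + prev_q,
                  ma[prev_t:ta], a, pa + prev_t)
        if qa > prev_q:
            indel("INS", pa + ta, pb + prev_q,
                  mb[prev_q:qa], b, pb + prev_q)
        for k in range(tz - ta):
            if ma[ta + k] != mb[qa + k]:
                snp(pa + ta + k, pb + qa + k, ma[ta + k], mb[qa + k])
        prev_t, prev_q = tz, qz


def call_variants(block: SyntenyBlock, seq_h1: str, seq_h2: str,
                  genes: dict[str, AnnotatedGene],
                  max_align_len: int = 100_000,
                  min_match_sep: int = 10) -> tuple[pd.DataFrame, int]:
    """Variant calls for one block from inter-anchor segment alignments.

    Returns (variants, aligned_columns).  Sequences are the full haplotype
    chromosome sequences the block lives on.  Segments longer than
    ``max_align_len`` on either side are flagged unaligned and excluded
    from the aligned-length denominator.  Difference runs separated by fewer
    than ``min_match_sep`` matched bases are coalesced and canonicalised
    into SNPs plus one net left-aligned indel.
    """
    rows: list = []
    aligned_cols = 0
    if block.orientation == "-":
        logger.warning("block %d is inverted; base-level variant calling "
                       "covers collinear blocks only", block.block_id)
        empty = pd.DataFrame(columns=["class", "kind", "chrom", "pos_h1",
                                      "pos_h2", "ref", "alt", "length"])
        return empty, 0
    for h1_lo, h1_hi, h2_lo, h2_hi in _segments_from_anchors(block, genes):
        if (h1_hi - h1_lo + 1) > max_align_len or \
                (h2_hi - h2_lo + 1) > max_align_len:
            logger.warning("segment %s:%d-%d unaligned (too long)",
                           block.chrom, h1_lo, h1_hi)
            continue
        a = seq_h1[h1_lo - 1:h1_hi]
        b = seq_h2[h2_lo - 1:h2_hi]
        if not a or not b:
            continue
        path = align_segment(a, b)
        aligned_cols += sum(ln for _, ln in path)
        for region in _difference_regions(path, a, b, min_match_sep):
            _emit_region(a, b, region, h1_lo, h2_lo, block.chrom, rows)
    df = pd.DataFrame(rows, columns=["class", "kind", "chrom", "pos_h1",
                                     "pos_h2", "ref", "alt", "length"])
    if len(df):
        df = df.sort_values("pos_h1", kind="stable").reset_index(drop=True)
    return df, aligned_cols


def call_all_variants(blocks: list[SyntenyBlock],
                      seqs_h1: dict, seqs_h2: dict,
                      genes: dict[str, AnnotatedGene],
                      max_align_len: int = 100_000
                      ) -> tuple[pd.DataFrame, int]:
    frames, total_cols = [], 0
    for blk in blocks:
        df, cols = call_variants(blk, seqs_h1[blk.chrom], seqs_h2[blk.chrom],
                                 genes, max_align_len)
        frames.append(df)
        total_cols += cols
    if frames:
        allv = pd.concat(frames, ignore_index=True)
        allv = allv.sort_values(["chrom", "pos_h1"],
                                key=lambda s: s.astype(str)
                                if s.name == "chrom" else s,
                                kind="stable").reset_index(drop=True)
    else:
        allv = pd.DataFrame(columns=["class", "kind", "chrom", "pos_h1",
                                     "pos_h2", "ref", "alt", "length"])
    return allv, total_cols


def intragenomic_diversity(variants: pd.DataFrame, aligned_columns: int
                           ) -> float:
    """Percent divergence: (SNP count + indel/SV base count) / aligned
    columns * 100."""
    if aligned_columns <= 0:
        raise ValueError("diversity undefined: zero aligned bases")
    n_snp = int((variants["class"] == "SNP").sum())
    gap_bases = int(variants.loc[variants["class"] != "SNP", "length"].sum())
    return 100.0 * (n_snp + gap_bases) / aligned_columns


# ---------------------------------------------------------------------------
# CDS effect classification
# ---------------------------------------------------------------------------

@dataclass
class EffectAnnotation:
    effect: str
    residues_changed: int
    pseudogene_like: bool = False


def _translate(cds: str) -> str:
    usable = len(cds) // 3 * 3
    return str(Seq(cds[:usable]).translate())


def classify_cds_effect(cds_a: str, cds_b: str) -> EffectAnnotation:
    """Protein-level effect of allele b relative to allele a.

    Precedence: frameshift > premature_stop > inframe indel > missense >
    synonymous > identical.  An internal stop already present in allele a is
    flagged pseudogene-like; the effect is still reported.
    """
    if not cds_a or not cds_b:
        raise ValueError("both CDS must be non-empty")
    prot_a = _translate(cds_a)
    prot_b = _translate(cds_b)
    internal_a = prot_a[:-1].find("*")
    internal_b = prot_b[:-1].find("*")
    pseudo = internal_a >= 0

    net = len(cds_b) - len(cds_a)
    if net % 3 != 0:
        # residues from the first divergence to the end of the shorter protein
        div = _first_difference(prot_a, prot_b)
        residues = max(len(prot_a), len(prot_b)) - div
        return EffectAnnotation("frameshift", residues, pseudo)
    if internal_b >= 0 and internal_a < 0:
        truncated = len(prot_a) - internal_b - 1
        return EffectAnnotation("premature_stop", max(truncated, 0), pseudo)
    if net > 0:
        return EffectAnnotation("inframe_insertion", net // 3, pseudo)
    if net < 0:
        return EffectAnnotation("inframe_deletion", -net // 3, pseudo)
    diffs = sum(1 for x, y in zip(prot_a, prot_b) if x != y)
    if diffs:
        return EffectAnnotation("missense", diffs, pseudo)
    if cds_a != cds_b:
        return EffectAnnotation("synonymous", 0, pseudo)
    return EffectAnnotation("identical", 0, pseudo)


def _first_difference(a: str, b: str) -> int:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i
    return min(len(a), len(b))


def classify_pairs(pairs: pd.DataFrame, genes: dict[str, AnnotatedGene]
                   ) -> pd.DataFrame:
    rows = []
    for r in pairs.itertuples(index=False):
        ann = classify_cds_effect(genes[r.gene_h1].cds, genes[r.gene_h2].cds)
        rows.append({"gene_h1": r.gene_h1, "gene_h2": r.gene_h2,
                     "effect": ann.effect,
                     "residues_changed": ann.residues_changed,
                     "pseudogene_like": ann.pseudogene_like})
    return pd.DataFrame(rows, columns=["gene_h1", "gene_h2", "effect",
                                       "residues_changed", "pseudogene_like"])
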