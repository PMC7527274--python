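"""Differential methylation between haplotypes: DMP calling and DMR
collapsing.

Cytosines are paired across haplotypes through the synteny-block coordinate
map (exact when variant calls are available, anchor-interpolated otherwise).
A paired site is a DMP when, in EVERY replicate, both haplotypes have depth
>= 5, the methylation-level difference reaches the context threshold
(CG 0.4, CHG 0.2, CHH 0.1), the two-tailed Fisher exact test on the
(methylated, unmethylated) x haplotype table gives p < 0.01, and the
direction is consistent.  DMPs of the same context and hypermethylated
haplotype closer than 100 bp are collapsed; runs of >= 2 make a DMR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synteny import SyntenyBlock

DEFAULT_THRESHOLDS = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}


# ---------------------------------------------------------------------------
# Coordinate mapping and site pairing
# ---------------------------------------------------------------------------

class BlockPositionMap:
    """h1 -> h2 position map inside synteny blocks.

    With variant calls, indel offsets give an exact base-level map (sites in
    insertion/deletion gaps are unpaired); without them, positions are
    linearly interpolated between anchor coordinates.
    """

    def __init__(self, blocks: list[SyntenyBlock],
                 variants: pd.DataFrame | None = None):
        self._by_chrom: dict = {}
        for blk in blocks:
            entry = self._by_chrom.setdefault(
                blk.chrom, {"blocks": [], "pts": None})
            entry["blocks"].append(blk)
        if variants is not None and len(variants):
            for chrom, entry in self._by_chrom.items():
                v = variants[(variants.chrom == chrom)
                             & (variants["kind"] != "SNP")]
                pts, offs = [0], [0]
                del_iv = []
                for r in v.sort_values("pos_h1").itertuples(index=False):
                    base_off = r.pos_h2 - r.pos_h1
                    if r.kind == "INS":
                        pts.append(r.pos_h1 + 1)
                        offs.append(base_off + r.length)
                    else:
                        del_iv.append((r.pos_h1 + 1, r.pos_h1 + r.length))
                        pts.append(r.pos_h1 + r.length + 1)
                        offs.append(base_off - r.length)
                entry["pts"] = (np.array(pts), np.array(offs),
                                np.array([a for a, _ in del_iv]),
                                np.array([b for _, b in del_iv]))

    def _block_for(self, chrom, pos: int) -> SyntenyBlock | None:
        for blk in self._by_chrom.get(chrom, {}).get("blocks", []):
            if blk.h1_start <= pos <= blk.h1_end:
                return blk
        return None

    def to_h2(self, chrom, pos: int) -> int:
        """h2 position of an h1 site, or -1 if unpaired."""
        blk = self._block_for(chrom, pos)
        if blk is None:
            return -1
        entry = self._by_chrom[chrom]
        if entry["pts"] is not None:
            pts, offs, ds, de = entry["pts"]
            if len(ds):
                j = np.searchsorted(ds, pos, side="right") - 1
                if j >= 0 and pos <= de[j]:
                    return -1
            i = np.searchsorted(pts, pos, side="right") - 1
            return int(pos + offs[i])
        # anchor interpolation
        frac = (pos - blk.h1_start) / max(blk.h1_end - blk.h1_start, 1)
        if blk.orientation == "+":
            return int(round(blk.h2_start
                             + frac * (blk.h2_end - blk.h2_start)))
        return int(round(blk.h2_end - frac * (blk.h2_end - blk.h2_start)))


def _chrom_key(label) -> object:
    """Strip a trailing haplotype suffix chrN_1/chrN_2 -> chrN -> N."""
    s = str(label)
    if "_" in s:
        s = s.rsplit("_", 1)[0]
    if s.startswith("chr"):
        s = s[3:]
    return int(s) if s.isdigit() else s


def pair_sites(sites_h1: pd.DataFrame, sites_h2: pd.DataFrame,
               blocks: list[SyntenyBlock],
               variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pair cytosines of the two haplotypes through the block map.

    Input tables have columns chrom, pos, strand, context, replicate, meth,
    depth (one row per site per replicate).  Output: one row per paired site
    per replicate with both haplotypes' counts.
    """
    pmap = BlockPositionMap(blocks, variants)
    h1 = sites_h1.copy()
    h1["ckey"] = h1.chrom.map(_chrom_key)
    h2 = sites_h2.copy()
    h2["ckey"] = h2.chrom.map(_chrom_key)
    uniq = h1[["ckey", "pos"]].drop_duplicates()
    mapped = {(r.ckey, r.pos): pmap.to_h2(r.ckey, r.pos)
              for r in uniq.itertuples(index=False)}
    h1["pos_h2"] = [mapped[(r.ckey, r.pos)]
                    for r in h1.itertuples(index=False)]
    h1 = h1[h1.pos_h2 > 0]
    merged = h1.merge(
        h2.rename(columns={"pos": "pos_h2", "meth": "meth2",
                           "depth": "depth2"}),
        on=["ckey", "pos_h2", "context", "replicate"], how="inner",
        suffixes=("", "_h2"))
    merged = merged.rename(columns={"pos": "pos_h1", "meth": "meth1",
                                    "depth": "depth1"})
    return merged[["ckey", "pos_h1", "pos_h2", "strand", "context",
                   "replicate", "meth1", "depth1", "meth2", "depth2"]] \
        .rename(columns={"ckey": "chrom"})


# ---------------------------------------------------------------------------
# DMP calling
# ---------------------------------------------------------------------------

def fisher_two_sided(m1: int, d1: int, m2: int, d2: int) -> float:
    """Two-tailed Fisher exact test on the 2x2 table
    [[meth1, unmeth1], [meth2, unmeth2]]: the sum of hypergeometric
    probabilities of all tables no more likely than the observed one."""
    n = d1 + d2
    K = m1 + m2                       # total methylated
    rv = stats.hypergeom(n, K, d1)
    kmin = max(0, K - d2)
    kmax = min(K, d1)
    support = np.arange(kmin, kmax + 1)
    pmf = rv.pmf(support)
    observed = rv.pmf(m1)
    return float(min(1.0, pmf[pmf <= observed * (1 + 1e-7)].sum()))


def call_dmps(paired: pd.DataFrame,
              thresholds: dict[str, float] | None = None,
              min_depth: int = 5, max_p: float = 0.01) -> pd.DataFrame:
    """Screen paired sites: every replicate must pass depth, level-difference
    and Fisher-test gates with a consistent direction.

    Depth/difference/direction gates run vectorised; the Fisher test is only
    evaluated for the surviving sites.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    if paired.empty:
        return pd.DataFrame(columns=["chrom", "pos_h1", "pos_h2", "context",
                                     "hyper_haplotype", "mean_diff", "max_p"])
    df = paired.copy()
    df["thr"] = df.context.map(thresholds)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = (df.meth1 / df.depth1 - df.meth2 / df.depth2)
    df["diff"] = diff
    df["ok"] = ((df.depth1 >= min_depth) & (df.depth2 >= min_depth)
                & (diff.abs() >= df.thr))
    key = ["chrom", "pos_h1"]
    g = df.groupby(key, sort=True)
    all_ok = g["ok"].transform("all")
    sign = np.sign(df["diff"].fillna(0.0))
    consistent = g["diff"].transform(lambda s: (s > 0).all() or (s < 0).all())
    cand = df[all_ok & consistent]
    rows = []
    for (chrom, pos1), site in cand.groupby(key, sort=True):
        pvals = [fisher_two_sided(int(r.meth1), int(r.depth1),
                                  int(r.meth2), int(r.depth2))
                 for r in site.itertuples(index=False)]
        if max(pvals) >= max_p:
            continue
        rows.append({"chrom": chrom, "pos_h1": int(pos1),
                     "pos_h2": int(site.pos_h2.iloc[0]),
                     "context": site.context.iloc[0],
                     "hyper_haplotype": 1 if site["diff"].iloc[0] > 0 else 2,
                     "mean_diff": float(site["diff"].abs().mean()),
                     "max_p": float(max(pvals))})
    return pd.DataFrame(rows, columns=["chrom", "pos_h1", "pos_h2",
                                       "context", "hyper_haplotype",
                                       "mean_diff", "max_p"])


# ---------------------------------------------------------------------------
# DMR collapsing and gene annotation
# ---------------------------------------------------------------------------

def collapse_dmrs(dmps: pd.DataFrame, max_gap: int = 100,
                  min_sites: int = 2) -> pd.DataFrame:
    """Chain same-context, same-direction DMPs with gaps < ``max_gap`` bp;
    runs of >= ``min_sites`` become DMRs (interval = first to last DMP,
    h1 coordinates)."""
    rows = []
    if dmps.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "context",
                                     "hyper_haplotype", "n_dmps"])
    for (chrom, ctx, hyper), sub in dmps.groupby(
            ["chrom", "context", "hyper_haplotype"]):
        pos = np.sort(sub.pos_h1.to_numpy())
        run = [pos[0]]
        for p in pos[1:]:
            if p - run[-1] < max_gap:
                run.append(p)
            else:
                if len(run) >= min_sites:
                    rows.append({"chrom": chrom, "start": int(run[0]),
                                 "end": int(run[-1]), "context": ctx,
                                 "hyper_haplotype": hyper,
                                 "n_dmps": len(run)})
                run = [p]
        if len(run) >= min_sites:
            rows.append({"chrom": chrom, "start": int(run[0]),
                         "end": int(run[-1]), "context": ctx,
                         "hyper_haplotype": hyper, "n_dmps": len(run)})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                     "hyper_haplotype", "n_dmps"])
    return df.sort_values(["chrom", "start"],
                          key=lambda s: s.astype(str) if s.name == "chrom"
                          else s).reset_index(drop=True)


def annotate_gene_methylation(dmrs: pd.DataFrame, pairs: pd.DataFrame,
                              gene_coords: dict[str, tuple],
                              flank: int = 2_000) -> pd.DataFrame:
    """Flag allelic pairs with >= 1 DMR overlapping either allele's gene
    body +- ``flank`` (DMR coordinates are on haplotype 1; the h1 allele's
    coordinates are used for both-side proximity, the h2 allele's via its
    own coordinates when given in ``gene_coords``).

    ``gene_coords`` maps gene_id -> (chrom, start, end).
    """
    flagged = []
    for r in pairs.itertuples(index=False):
        hit = False
        for gid in (r.gene_h1, r.gene_h2):
            if gid not in gene_coords:
                continue
            chrom, gs, ge = gene_coords[gid]
            ck = _chrom_key(chrom)
            cand = dmrs[dmrs.chrom.map(_chrom_key) == ck] if len(dmrs) else dmrs
            if len(cand) and bool(((cand.start <= ge + flank)
                                   & (cand.end >= gs - flank)).any()):
                hit = True
                break
        flagged.append(hit)
    out = pairs.copy()
    out["differentially_methylated"] = flagged
    return out
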