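"""Linkage grouping, haplotype splitting, rescue and chimera breaking.

The phasing logic exploits two facts about a selfed F2 of a single
heterozygous parent: (i) dosage vectors of linked scaffolds are correlated
across progeny, with the correlation decaying with genetic distance, and
(ii) the two haplotypes of one locus are perfectly complementary
(d2 = 2 - d1), so scaffolds from opposite haplotypes of the same region
anti-correlate.  Grouping therefore uses |correlation| to join both
haplotypes of a chromosome into one linkage group, Ward clustering at k=2
splits the group into its two haplotypes, and unassigned scaffolds are
rescued when their top two correlations agree on one haplotype group.

Chimeric scaffolds (joins of the two haplotypes) betray themselves by a
contrary read distribution between adjacent windows: the per-window dosage
vectors anti-correlate across the junction, and the scaffold is broken at
the shared window boundary.

Haplotype labels are arbitrary per linkage group: an F2 of a single parent
carries no information linking "haplotype 1" of one chromosome to
"haplotype 1" of another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .genotyping import MISSING, GenotypeMatrix, call_dosage, normalize_counts
from .simulate import ProgenyCountMatrix, Scaffold

logger = logging.getLogger(__name__)

UNASSIGNED = 0


@dataclass
class PhaseAssignment:
    """Scaffold -> (linkage group, haplotype) table."""

    table: pd.DataFrame  # scaffold, group, haplotype, method, support

    def assigned(self) -> pd.DataFrame:
        return self.table[self.table.haplotype != UNASSIGNED]


@dataclass
class ChimeraReport:
    scaffold_id: str
    window_size: int
    window_edges: np.ndarray            # offsets within the scaffold
    breakpoints: list[int] = field(default_factory=list)  # scaffold offsets
    adjacent_correlations: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pairwise linkage
# ---------------------------------------------------------------------------

def masked_pearson(x: np.ndarray, y: np.ndarray | None = None,
                   min_overlap: int = 30) -> np.ndarray:
    """Pairwise-complete Pearson correlation between rows of ``x`` (and
    optionally rows of ``y``); NaN marks missing observations.

    Pairs sharing fewer than ``min_overlap`` observations, or with zero
    variance on the shared observations, get NaN (never propagated NaN from
    arithmetic).
    """
    symmetric = y is None
    if y is None:
        y = x
    mx = (~np.isnan(x)).astype(float)
    my = (~np.isnan(y)).astype(float)
    x0 = np.nan_to_num(x)
    y0 = np.nan_to_num(y)
    n = mx @ my.T
    sx = x0 @ my.T
    sy = mx @ y0.T
    sxx = (x0 * x0) @ my.T
    syy = mx @ (y0 * y0).T
    sxy = x0 @ y0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    bad = (n < min_overlap) | ~np.isfinite(r)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    if symmetric:
        np.fill_diagonal(r, 1.0)
    return r


def pairwise_linkage(g: GenotypeMatrix, min_overlap: int = 30) -> np.ndarray:
    """Correlation matrix of dosage vectors over informative scaffolds only;
    non-informative rows are all-NaN."""
    if int(g.informative.sum()) < 2:
        raise ValueError("need at least 2 informative scaffolds")
    X = g.dosage.astype(float)
    X[g.dosage == MISSING] = np.nan
    r = np.full((len(g.scaffold_ids),) * 2, np.nan)
    idx = np.flatnonzero(g.informative)
    r[np.ix_(idx, idx)] = masked_pearson(X[idx], min_overlap=min_overlap)
    return r


# ---------------------------------------------------------------------------
# Grouping and haplotype splitting
# ---------------------------------------------------------------------------

def build_linkage_groups(similarity: np.ndarray, threshold: float = 0.7,
                         min_group_size: int = 5,
                         expected_groups: int | None = None
                         ) -> list[np.ndarray]:
    """Connected components of the |correlation| >= threshold graph.

    Both haplotypes of a chromosome co-cluster (anti-correlated edges), so
    the expected component count equals the chromosome count.
    """
    adj = np.abs(np.nan_to_num(similarity)) >= threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = []
    for k in range(n_comp):
        members = np.flatnonzero(labels == k)
        if len(members) >= min_group_size:
            groups.append(members)
    groups.sort(key=lambda m: (-len(m), m[0]))
    if expected_groups is not None and len(groups) != expected_groups:
        logger.warning(
            "found %d linkage groups, expected %d (sizes: %s)",
            len(groups), expected_groups, [len(g) for g in groups])
    return groups


def split_haplotypes(members: np.ndarray, similarity: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Ward clustering at k=2 on distance d=(1-cor)/2 within one group.

    Returns (cluster-1 members, cluster-2 members, low_confidence flag).
    A group of size 1 returns a single cluster with the flag set.
    """
    if len(members) < 2:
        return members, np.array([], dtype=members.dtype), True
    sub = similarity[np.ix_(members, members)]
    d = (1.0 - np.nan_to_num(sub, nan=0.0)) / 2.0
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="ward")
    labels = fcluster(Z, t=2, criterion="maxclust")
    c1 = members[labels == 1]
    c2 = members[labels == 2]
    low_confidence = False
    if len(c1) == 0 or len(c2) == 0:
        # degenerate (e.g. identical vectors): force a two-way cut
        c1, c2 = members[:1], members[1:]
        low_confidence = True
    # complementarity check: cross-cluster correlation should be negative
    if len(c1) and len(c2):
        cross = similarity[np.ix_(c1, c2)]
        if np.nanmean(cross) > 0:
            low_confidence = True
    return c1, c2, low_confidence


def phase_scaffolds(g: GenotypeMatrix, similarity: np.ndarray | None = None,
                    threshold: float = 0.7, min_group_size: int = 5,
                    min_overlap: int = 30,
                    expected_groups: int | None = None) -> PhaseAssignment:
    """Grouping + haplotype splitting for all informative scaffolds."""
    if similarity is None:
        similarity = pairwise_linkage(g, min_overlap=min_overlap)
    groups = build_linkage_groups(similarity, threshold, min_group_size,
                                  expected_groups)
    n = len(g.scaffold_ids)
    group_col = np.zeros(n, dtype=int)
    hap_col = np.zeros(n, dtype=int)
    support = np.full(n, np.nan)
    method = np.array(["unassigned"] * n, dtype=object)
    for gi, members in enumerate(groups, start=1):
        c1, c2, low = split_haplotypes(members, similarity)
        for hap, cluster in ((1, c1), (2, c2)):
            group_col[cluster] = gi
            hap_col[cluster] = hap
            method[cluster] = "clustered" if not low else "clustered_lowconf"
            own = similarity[np.ix_(cluster, cluster)]
            support[cluster] = np.nanmean(own) if own.size > 1 else 1.0
    table = pd.DataFrame({
        "scaffold": g.scaffold_ids, "group": group_col,
        "haplotype": hap_col, "method": method, "support": support})
    return PhaseAssignment(table)


# ---------------------------------------------------------------------------
# Rescue
# ---------------------------------------------------------------------------

def rescue_unassigned(assignment: PhaseAssignment,
                      m: ProgenyCountMatrix,
                      threshold: float = 0.7,
                      min_overlap: int = 30) -> PhaseAssignment:
    """Assign leftover scaffolds by read-count correlation with phased ones.

    A query is assigned iff its top two correlations with target (already
    phased) scaffolds both exceed ``threshold`` AND those two targets share
    the same (linkage group, haplotype).  Already-phased scaffolds are never
    reassigned.
    """
    table = assignment.table.copy()
    sid_index = {s: i for i, s in enumerate(m.scaffold_ids)}
    phased = table[table.haplotype != UNASSIGNED]
    queries = table[table.haplotype == UNASSIGNED]
    if len(phased) < 2:
        logger.warning("rescue disabled: fewer than two phased targets")
        return PhaseAssignment(table)
    if len(queries) == 0:
        return PhaseAssignment(table)
    r = normalize_counts(m)
    tgt_idx = np.array([sid_index[s] for s in phased.scaffold])
    qry_idx = np.array([sid_index[s] for s in queries.scaffold])
    cor = masked_pearson(r[qry_idx], r[tgt_idx], min_overlap=min_overlap)
    tgt_group = phased.group.to_numpy()
    tgt_hap = phased.haplotype.to_numpy()
    for qi, row_pos in enumerate(queries.index):
        row = np.nan_to_num(cor[qi], nan=-np.inf)
        if len(row) < 2:
            continue
        top2 = np.argsort(row)[-2:][::-1]
        v1, v2 = row[top2[0]], row[top2[1]]
        if v2 <= threshold or v1 <= threshold:
            continue
        if (tgt_group[top2[0]] != tgt_group[top2[1]]
                or tgt_hap[top2[0]] != tgt_hap[top2[1]]):
            continue
        table.loc[row_pos, ["group", "haplotype"]] = (
            tgt_group[top2[0]], tgt_hap[top2[0]])
        table.loc[row_pos, "method"] = "rescued"
        table.loc[row_pos, "support"] = v2
    return PhaseAssignment(table)


# ---------------------------------------------------------------------------
# Chimera detection and breaking
# ---------------------------------------------------------------------------

def _window_genotype_matrix(edges: np.ndarray, wmat: np.ndarray,
                            m: ProgenyCountMatrix,
                            min_llr: float, min_lambda2: float
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Dosage-call each window of one scaffold; merge windows whose depth is
    uninformative (lambda_2 < min_lambda2) into their left neighbour."""
    lens = np.diff(edges)
    # merge uninformative windows leftward
    G = float(m.assembly_total_length)
    mean_T = float(m.progeny_totals.mean())
    while len(lens) > 1:
        lam2 = lens * mean_T / G
        weak = np.flatnonzero(lam2 < min_lambda2)
        if len(weak) == 0:
            break
        j = int(weak[0])
        k = j - 1 if j > 0 else 1
        lo, hi = min(j, k), max(j, k)
        lens = np.concatenate([lens[:lo], [lens[lo] + lens[hi]],
                               lens[hi + 1:]])
        wmat = np.vstack([wmat[:lo], wmat[lo] + wmat[hi], wmat[hi + 1:]])
    edges = np.concatenate([[edges[0]], edges[0] + np.cumsum(lens)])
    sub = ProgenyCountMatrix(
        scaffold_ids=[f"w{i}" for i in range(len(lens))],
        scaffold_lengths=lens,
        progeny_ids=list(m.progeny_ids),
        counts=wmat, progeny_totals=m.progeny_totals,
        assembly_total_length=m.assembly_total_length)
    gm = call_dosage(sub, min_llr=min_llr, min_lambda2=min_lambda2)
    X = gm.dosage.astype(float)
    X[gm.dosage == MISSING] = np.nan
    return edges, X


def detect_chimeras(m: ProgenyCountMatrix,
                    window_size: int = 200_000,
                    contrary_threshold: float = -0.5,
                    min_overlap: int = 30,
                    min_llr: float = np.log(3.0),
                    min_lambda2: float = 1.0) -> list[ChimeraReport]:
    """Windowed chimera scan over every scaffold with per-window counts.

    Adjacent windows whose dosage vectors correlate below
    ``contrary_threshold`` define a breakpoint at the shared boundary.
    """
    reports = []
    for sid, (edges, wmat) in m.window_counts.items():
        if len(edges) < 3:
            continue
        edges2, X = _window_genotype_matrix(
            edges, wmat, m, min_llr, min_lambda2)
        report = ChimeraReport(scaffold_id=sid, window_size=window_size,
                               window_edges=edges2)
        for i in range(len(X) - 1):
            c = masked_pearson(X[i:i + 1], X[i + 1:i + 2],
                               min_overlap=min_overlap)[0, 0]
            report.adjacent_correlations.append(float(c))
            if np.isfinite(c) and c < contrary_threshold:
                report.breakpoints.append(int(edges2[i + 1]))
        reports.append(report)
    return reports


def break_scaffolds(m: ProgenyCountMatrix, scaffolds: list[Scaffold],
                    reports: list[ChimeraReport]
                    ) -> tuple[ProgenyCountMatrix, list[Scaffold]]:
    """Split scaffolds at detected breakpoints; parts re-enter phasing as
    independent scaffolds with counts summed from their windows."""
    by_id = {r.scaffold_id: r for r in reports if r.breakpoints}
    scaffold_by_id = {s.scaffold_id: s for s in scaffolds}
    new_ids, new_lens, new_rows, new_scaffolds = [], [], [], []
    for i, sid in enumerate(m.scaffold_ids):
        rep = by_id.get(sid)
        if rep is None:
            new_ids.append(sid)
            new_lens.append(m.scaffold_lengths[i])
            new_rows.append(m.counts[i])
            if sid in scaffold_by_id:
                new_scaffolds.append(scaffold_by_id[sid])
            continue
        edges, wmat = m.window_counts[sid]
        cutpoints = [0] + rep.breakpoints + [int(edges[-1])]
        src = scaffold_by_id.get(sid)
        for k in range(len(cutpoints) - 1):
            lo, hi = cutpoints[k], cutpoints[k + 1]
            part_id = f"{sid}.{k+1}"
            sel = (edges[:-1] >= lo) & (edges[1:] <= hi)
            new_ids.append(part_id)
            new_lens.append(hi - lo)
            new_rows.append(wmat[sel].sum(axis=0))
            if src is not None:
                segs = _slice_segments(src, lo, hi)
                new_scaffolds.append(Scaffold(
                    part_id, segs, hi - lo,
                    is_chimeric=False, breakpoints=[]))
    pcm = ProgenyCountMatrix(
        scaffold_ids=new_ids,
        scaffold_lengths=np.array(new_lens),
        progeny_ids=list(m.progeny_ids),
        counts=np.vstack(new_rows).astype(np.int64),
        progeny_totals=m.progeny_totals,
        assembly_total_length=m.assembly_total_length)
    return pcm, new_scaffolds


def _slice_segments(s: Scaffold, lo: int, hi: int
                    ) -> list[tuple[int, int, int, int]]:
    out = []
    off = 0
    for c, h, a, b in s.segments:
        seg_len = b - a + 1
        plo, phi = max(lo, off), min(hi, off + seg_len)
        if phi > plo:
            out.append((c, h, a + (plo - off), a + (phi - off) - 1))
        off += seg_len
    return out


# ---------------------------------------------------------------------------
# Truth-aware accuracy (parameter-recovery metric)
# ---------------------------------------------------------------------------

def phasing_accuracy(assignment: PhaseAssignment,
                     scaffolds: list[Scaffold],
                     informative_ids: set[str] | None = None) -> float:
    """Fraction of informative scaffold length placed on its true
    (chromosome, haplotype), after per-group optimal label matching.

    The denominator is the total length of the scaffolds considered
    (restricted to ``informative_ids`` when given): unassigned length counts
    as not recovered, and the minority part of a chimeric scaffold counts as
    misassigned until the scaffold is broken.  Labels within each linkage
    group are arbitrary, so for every group the better of the two label
    orientations is taken.
    """
    considered = [s for s in scaffolds
                  if informative_ids is None
                  or s.scaffold_id in informative_ids]
    total = sum(s.length for s in considered)
    if total == 0:
        return 0.0
    by_id = {s.scaffold_id: s for s in considered}
    rows = []
    for r in assignment.assigned().itertuples(index=False):
        s = by_id.get(r.scaffold)
        if s is None:
            continue
        for c, h, a, b in s.segments:
            rows.append({"group": r.group, "called_hap": r.haplotype,
                         "true_chrom": c, "true_hap": h,
                         "length": b - a + 1})
    df = pd.DataFrame(rows)
    if df.empty:
        return 0.0
    correct = 0
    for _, sub in df.groupby("group"):
        # group maps to its majority chromosome
        chrom = sub.groupby("true_chrom").length.sum().idxmax()
        on = sub[sub.true_chrom == chrom]
        same = on[on.called_hap == on.true_hap].length.sum()
        flipped = on[on.called_hap == (3 - on.true_hap)].length.sum()
        correct += max(same, flipped)
    return float(correct) / float(total)
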