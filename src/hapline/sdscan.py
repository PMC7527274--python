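"""Windowed segregation-distortion scan and recessive-exclusion screening.

In a selfed F2, every locus is expected to segregate 1:2:1
(hom : het : hom).  Regions under zygotic selection — above all recessive
lethals — deviate; in the extreme, one homozygote class is absent
altogether.  The scan genotypes fixed windows along each chromosome as
markers (length-weighted majority over member scaffolds, relative to one
fixed haplotype per group), applies a chi-square test against 1:2:1, and
flags candidate lethal-locus intervals as maximal runs of distorted windows
whose minor-homozygote class is (nearly) empty.

The chi-square statistic is invariant to the haplotype label swap
(n0 <-> n2), so the per-group arbitrariness of labels does not affect it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import MISSING, GenotypeMatrix
from .phasing import PhaseAssignment
from .simulate import Scaffold


@dataclass
class SDScanResult:
    windows: pd.DataFrame
    # columns: chrom_label, window_start, window_end, n0, n1, n2, n,
    #          chi2, p, distorted, testable, recessive_excluded

    def distorted_fraction(self) -> float:
        t = self.windows[self.windows.testable]
        return float(t.distorted.mean()) if len(t) else float("nan")


def window_genotypes(g: GenotypeMatrix, assignment: PhaseAssignment,
                     scaffolds: list[Scaffold],
                     window: int = 300_000,
                     min_progeny: int = 20) -> pd.DataFrame:
    """Per-window, per-progeny consensus dosage and genotype tallies.

    Scaffold coordinates come from the scaffold records (simulation truth
    order or user-provided order).  Member calls from haplotype-2 scaffolds
    are flipped (2-d) so every window is counted relative to haplotype 1 of
    its group.  Consensus is the length-weighted majority; ties are missing.
    """
    by_id = {s.scaffold_id: s for s in scaffolds}
    sid_row = {s: i for i, s in enumerate(g.scaffold_ids)}
    rows = []
    assigned = assignment.assigned()
    for r in assigned.itertuples(index=False):
        s = by_id.get(r.scaffold)
        if s is None or r.scaffold not in sid_row:
            continue
        # place by the dominant segment
        c, h, a, b = max(s.segments, key=lambda seg: seg[3] - seg[2])
        rows.append({"scaffold": r.scaffold, "row": sid_row[r.scaffold],
                     "chrom": c, "seg_hap": h, "start": a, "end": b,
                     "called_hap": r.haplotype, "group": r.group,
                     "length": s.length})
    members = pd.DataFrame(rows)
    if members.empty:
        return pd.DataFrame(columns=[
            "chrom_label", "window_start", "window_end", "n0", "n1", "n2",
            "n", "testable"])
    P = g.dosage.shape[1]
    out = []
    for (grp, c), sub in members.groupby(["group", "chrom"]):
        hi = int(sub.end.max())
        edges = np.arange(0, hi + window, window)
        for wi in range(len(edges) - 1):
            lo, up = int(edges[wi]) + 1, int(edges[wi + 1])
            mid = (sub.start + sub.end) // 2
            inside = sub[(mid >= lo) & (mid <= up)]
            weight = np.zeros((P, 3))
            for mrow in inside.itertuples(index=False):
                d = g.dosage[mrow.row].astype(int)
                if mrow.called_hap == 2:
                    d = np.where(d == MISSING, MISSING, 2 - d)
                ok = d != MISSING
                weight[np.arange(P)[ok], d[ok]] += mrow.length
            top = weight.argmax(axis=1)
            best = weight.max(axis=1)
            second = np.sort(weight, axis=1)[:, -2]
            called = (best > 0) & (best > second)
            n_counts = [int(((top == k) & called).sum()) for k in range(3)]
            n = sum(n_counts)
            out.append({"group": grp, "chrom_label": f"g{grp}_chr{c}",
                        "window_start": lo, "window_end": up,
                        "n0": n_counts[0], "n1": n_counts[1],
                        "n2": n_counts[2], "n": n,
                        "testable": n >= min_progeny})
    return pd.DataFrame(out)


def chi2_sd_test(n0: int, n1: int, n2: int, alpha: float = 0.001,
                 min_n: int = 20) -> tuple[float, float, bool, bool]:
    """Chi-square test of (n0, n1, n2) against the F2 expectation 1:2:1.

    Returns (chi2, p, distorted, testable); df=2.
    """
    n = n0 + n1 + n2
    if n < min_n:
        return float("nan"), float("nan"), False, False
    exp = np.array([n / 4.0, n / 2.0, n / 4.0])
    chi2, p = stats.chisquare([n0, n1, n2], f_exp=exp)
    return float(chi2), float(p), bool(p < alpha), True


def scan_sd(window_table: pd.DataFrame, alpha: float = 0.001,
            min_n: int = 20, exclusion_eps: float = 0.01,
            window_morgans: float = 0.0) -> SDScanResult:
    """Apply the chi-square test to every window and flag recessive
    exclusion: distorted windows whose minor-homozygote count is at most
    a tolerance fraction of n.

    The tolerance is ``exclusion_eps`` (genotyping error at ~1x coverage)
    plus a recombination allowance when the window's genetic width w (in
    Morgans) is known: a lethal locus sits anywhere inside its window, so
    the window consensus is separated from it by up to half the window,
    and a surviving heterozygote (frequency 2/3) recombines into an
    apparent carrier homozygote there with probability up to the Haldane
    fraction r(w/2) = (1 - e^{-w})/2.  The allowance (2/3) r(w/2) bounds
    the expected minority-homozygote fraction and vanishes on dense maps
    (window << 1 cM).  It stays far below the ~25% a neutral 1:2:1 window
    shows, so it cannot create false exclusion flags.
    """
    df = window_table.copy()
    res = [chi2_sd_test(r.n0, r.n1, r.n2, alpha, min_n)
           for r in df.itertuples(index=False)]
    df["chi2"] = [r[0] for r in res]
    df["p"] = [r[1] for r in res]
    df["distorted"] = [r[2] for r in res]
    df["testable"] = [r[3] for r in res]
    r_half = (1.0 - np.exp(-window_morgans)) / 2.0
    eps_eff = exclusion_eps + (2.0 / 3.0) * r_half
    minor_hom = df[["n0", "n2"]].min(axis=1)
    df["recessive_excluded"] = (df.distorted
                                & (minor_hom <= eps_eff * df.n + 1e-9))
    return SDScanResult(df)


def exclusion_runs(result: SDScanResult) -> pd.DataFrame:
    """Maximal runs of recessive-excluded windows: candidate lethal loci."""
    out = []
    df = result.windows
    for label, sub in df.groupby("chrom_label", sort=True):
        sub = sub.sort_values("window_start")
        flags = sub.recessive_excluded.to_numpy()
        starts = sub.window_start.to_numpy()
        ends = sub.window_end.to_numpy()
        i = 0
        while i < len(flags):
            if flags[i]:
                j = i
                while j + 1 < len(flags) and flags[j + 1]:
                    j += 1
                out.append({"chrom_label": label, "start": int(starts[i]),
                            "end": int(ends[j]), "n_windows": j - i + 1})
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(out, columns=["chrom_label", "start", "end",
                                      "n_windows"])
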