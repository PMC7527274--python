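"""Differential allelic expression (DEL) calling.

Per-allele quantifications (TPM + estimated fragment counts over tissues and
replicates) are filtered for replicate consistency (coefficient of variation
< 30%) and expression (summed mean TPM > 1 across tissues), then each
allelic pair is tested per tissue with an exact two-sided binomial test at
p = 0.5 on the rounded summed counts of the two alleles.  Pairs significant
in at least one tissue after Benjamini-Hochberg adjustment are DEL.

The binomial test is applied to estimated counts, not TPM: only counts carry
a sampling model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = {"pair_id", "haplotype", "tissue", "replicate",
                    "est_count", "tpm"}


def _check(m: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(m.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")


def replicate_consistency_filter(m: pd.DataFrame, max_cv: float = 0.30
                                 ) -> pd.DataFrame:
    """Keep allele x tissue cells whose TPM coefficient of variation across
    replicates is below ``max_cv``; zero-mean cells are dropped too.

    Requires >= 2 replicates; with a single replicate the filter is not
    applicable and raises.
    """
    _check(m)
    n_reps = m.groupby(["pair_id", "haplotype", "tissue"])["replicate"].nunique()
    if (n_reps < 2).any():
        raise ValueError("replicate-consistency filter needs >=2 replicates")
    g = m.groupby(["pair_id", "haplotype", "tissue"])["tpm"]
    mean = g.transform("mean")
    sd = g.transform("std")
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    return m[(cv < max_cv) & (mean > 0)].copy()


def expressed_filter(m: pd.DataFrame, min_summed_tpm: float = 1.0
                     ) -> set[tuple[int, int]]:
    """(pair_id, haplotype) keys whose summed-over-tissues mean TPM exceeds
    ``min_summed_tpm`` (strict)."""
    _check(m)
    per_tissue = m.groupby(["pair_id", "haplotype", "tissue"])["tpm"].mean()
    summed = per_tissue.groupby(["pair_id", "haplotype"]).sum()
    return set(summed[summed > min_summed_tpm].index)


def binom_two_sided(x: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p-value: the sum of all outcome
    probabilities not exceeding P(x)."""
    if n == 0:
        raise ValueError("untestable: n = 0")
    return float(stats.binomtest(x, n, p, alternative="two-sided").pvalue)


def del_test(m: pd.DataFrame, max_cv: float = 0.30,
             min_summed_tpm: float = 1.0, fdr: float = 0.05,
             fdr_method: str = "bh") -> pd.DataFrame:
    """Per-tissue exact binomial tests + pair-level DEL aggregation.

    Returns one row per (pair, tissue) that passed the filters on both
    alleles, with columns x1, x2, p, q, significant, direction, plus a
    pair-level ``is_del`` flag (significant in >= 1 tissue).
    """
    filtered = replicate_consistency_filter(m, max_cv)
    expressed = expressed_filter(m, min_summed_tpm)
    keep = filtered[[ (r.pair_id, r.haplotype) in expressed
                      for r in filtered.itertuples(index=False)]]
    counts = keep.groupby(["pair_id", "tissue", "haplotype"])["est_count"] \
                 .sum().round().astype(int).unstack("haplotype")
    rows = []
    for (pair_id, tissue), r in counts.iterrows():
        if 1 not in counts.columns or 2 not in counts.columns:
            continue
        x1, x2 = r.get(1), r.get(2)
        if pd.isna(x1) or pd.isna(x2):
            continue                    # one allele failed the filters
        n = int(x1) + int(x2)
        if n == 0:
            continue                    # untestable
        p = binom_two_sided(int(x1), n)
        rows.append({"pair_id": pair_id, "tissue": tissue,
                     "x1": int(x1), "x2": int(x2), "p": p,
                     "direction": 1 if x1 > x2 else (2 if x2 > x1 else 0)})
    res = pd.DataFrame(rows, columns=["pair_id", "tissue", "x1", "x2", "p",
                                      "direction"])
    if res.empty:
        res["q"] = []
        res["significant"] = []
        res["is_del"] = []
        return res
    if fdr_method == "bh":
        res["q"] = np.nan
        for tissue, sub in res.groupby("tissue"):
            res.loc[sub.index, "q"] = stats.false_discovery_control(
                sub.p.to_numpy(), method="bh")
    elif fdr_method == "none":
        res["q"] = res["p"]
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    res["significant"] = res.q < fdr
    del_pairs = set(res.loc[res.significant, "pair_id"])
    res["is_del"] = res.pair_id.isin(del_pairs)
    return res


def del_summary(res: pd.DataFrame) -> pd.DataFrame:
    """One row per pair: is_del and the direction of the strongest tissue."""
    if res.empty:
        return pd.DataFrame(columns=["pair_id", "is_del", "direction"])
    rows = []
    for pair_id, sub in res.groupby("pair_id"):
        top = sub.loc[sub.p.idxmin()]
        rows.append({"pair_id": pair_id, "is_del": bool(sub.is_del.any()),
                     "direction": int(top.direction)})
    return pd.DataFrame(rows)
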