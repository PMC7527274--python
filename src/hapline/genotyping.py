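"""Dosage genotyping from per-progeny scaffold read counts.

At ~1x coverage each progeny contributes too few reads for SNP-level calls,
but the *number* of reads a haplotype-specific scaffold attracts scales with
how many copies (0/1/2) of that haplotype segment the progeny carries.  Raw
counts are normalised by scaffold length, total assembled length and the
progeny's total mapped reads; a Poisson maximum-likelihood caller then turns
the counts into discrete dosages with a likelihood-ratio confidence gate.
Missing data is encoded explicitly (dosage -1), never as dosage 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ProgenyCountMatrix

MISSING = -1
DEFAULT_MIN_LLR = math.log(3.0)


@dataclass
class GenotypeMatrix:
    scaffold_ids: list[str]
    progeny_ids: list[str]
    dosage: np.ndarray         # int8, scaffold x progeny, -1 = missing
    confidence: np.ndarray     # best-vs-second log-likelihood ratio
    informative: np.ndarray = field(default=None)  # bool per scaffold

    def __post_init__(self):
        if self.informative is None:
            self.informative = np.ones(len(self.scaffold_ids), dtype=bool)

    def missing_fraction(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, index=self.scaffold_ids,
                          columns=self.progeny_ids).astype(object)
        df = df.where(df != MISSING, "NA")
        df.insert(0, "informative", self.informative)
        return df


def normalize_counts(m: ProgenyCountMatrix) -> np.ndarray:
    """r_{s,p} = (counts / L_s) / (T_p / G).

    For a haplotype-specific scaffold carried at dosage d in a diploid,
    r is approximately d/2.  Progeny with zero total reads get NaN.
    """
    if (m.scaffold_lengths <= 0).any():
        raise ValueError("scaffold lengths must be positive")
    L = m.scaffold_lengths.astype(float)[:, None]
    T = m.progeny_totals.astype(float)[None, :]
    G = float(m.assembly_total_length)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (m.counts / L) / (T / G)
    r[:, m.progeny_totals <= 0] = np.nan
    return r


def _poisson_loglik(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log P(counts | lam) up to the count-only constant; lam=0 allowed."""
    out = np.full(counts.shape, -np.inf)
    pos = lam > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pos, counts * np.log(np.where(pos, lam, 1.0)) - lam,
                       np.where(counts == 0, 0.0, -np.inf))
    return out


def call_dosage(m: ProgenyCountMatrix,
                min_llr: float = DEFAULT_MIN_LLR,
                min_lambda2: float = 1.0) -> GenotypeMatrix:
    """Maximum-likelihood dosage in {0,1,2} under counts ~ Poisson(lambda_d),
    lambda_d = d/2 * L_s * T_p / G.

    A cell is missing when the best-vs-second log-likelihood ratio is below
    ``min_llr`` (default ln 3) or when lambda_2 < ``min_lambda2`` (the scaffold
    is too short / the library too shallow to be informative).
    """
    L = m.scaffold_lengths.astype(float)[:, None]
    T = m.progeny_totals.astype(float)[None, :]
    G = float(m.assembly_total_length)
    lam2 = L * T / G
    counts = m.counts
    ll = np.stack([_poisson_loglik(counts, d / 2.0 * lam2)
                   for d in (0, 1, 2)])
    order = np.argsort(ll, axis=0)
    best = order[-1]
    llr = (np.take_along_axis(ll, order[-1][None], axis=0)
           - np.take_along_axis(ll, order[-2][None], axis=0))[0]
    dosage = best.astype(np.int8)
    missing = (llr < min_llr) | (lam2 < min_lambda2) | (T <= 0)
    dosage[missing] = MISSING
    llr = np.where(missing, 0.0, llr)
    return GenotypeMatrix(scaffold_ids=list(m.scaffold_ids),
                          progeny_ids=list(m.progeny_ids),
                          dosage=dosage, confidence=llr)


def filter_markers(g: GenotypeMatrix, max_missing: float = 0.4,
                   min_variance: float = 0.0) -> GenotypeMatrix:
    """Flag scaffolds uninformative when missingness exceeds ``max_missing``
    or the non-missing dosages do not segregate (zero variance).

    Raises if nothing survives — an empty marker set is an explicit error,
    not an empty result downstream.
    """
    dm = np.ma.masked_equal(g.dosage, MISSING)
    miss_frac = (g.dosage == MISSING).mean(axis=1)
    var = np.asarray(dm.var(axis=1).filled(0.0))
    informative = (miss_frac <= max_missing) & (var > min_variance)
    if not informative.any():
        raise ValueError("all scaffolds filtered out: no informative markers")
    return GenotypeMatrix(scaffold_ids=g.scaffold_ids,
                          progeny_ids=g.progeny_ids,
                          dosage=g.dosage, confidence=g.confidence,
                          informative=informative)
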