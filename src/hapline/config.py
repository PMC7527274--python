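"""Configuration objects for the simulator and the pipeline.

All tunable thresholds live here so that every stage receives an explicit,
validated parameter set and the run log / output headers can echo it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Literal

SelectionMode = Literal["lethal", "vigor"]


@dataclass(frozen=True)
class LethalLocus:
    """A recessive locus under zygotic selection in the selfing population.

    ``carrier_haplotype`` is the haplotype (1 or 2) carrying the deleterious
    recessive allele.  ``mode='lethal'`` kills every recessive homozygote;
    ``mode='vigor'`` lets recessive homozygotes survive with probability
    ``viability``.
    """

    chrom: int
    pos: int
    carrier_haplotype: int = 1
    mode: SelectionMode = "lethal"
    viability: float = 0.3

    def __post_init__(self) -> None:
        if self.carrier_haplotype not in (1, 2):
            raise ValueError("carrier_haplotype must be 1 or 2")
        if self.mode not in ("lethal", "vigor"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if not 0.0 <= self.viability <= 1.0:
            raise ValueError("viability must be in [0, 1]")


@dataclass
class SimConfig:
    """Parameters of the synthetic diploid genome + selfing population.

    Defaults emulate the study design this package targets: a highly
    heterozygous diploid (~2% sequence divergence between haplotypes) selfed
    to produce an F2 population genotyped at ~1x coverage per progeny.
    Genome size is scaled to desk scale (2 chromosome pairs of 2 Mb).
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    snp_rate: float = 0.015
    indel_rate: float = 0.0017
    # per chromosome; together with snp_rate and indel_rate this puts the
    # planted divergence at ~2.1% of aligned bases
    sv_count: int = 3
    pav_gene_fraction: float = 0.025
    genes_per_chromosome: int = 100
    # population
    n_progeny: int = 200
    map_length_morgans: float = 1.0   # per chromosome
    lethal_loci: list[LethalLocus] = field(default_factory=list)
    # sequencing
    coverage: float = 1.0             # mean fold coverage per progeny
    read_length: int = 150
    library_size_cv: float = 0.1      # lognormal spread of per-progeny totals
    # scaffolding
    scaffold_n50: int = 12_000
    chimera_rate: float = 0.0
    window_size: int = 200_000        # chimera-detection window; junction grid
    # expression
    del_fraction: float = 0.166
    del_fold_change: float = 4.0
    n_tissues: int = 3
    n_replicates: int = 3
    expr_mean: float = 200.0          # mean per-allele fragment count
    # NB size parameter; large = near-Poisson counts, the regime in which
    # count-level allelic tests are calibrated
    expr_dispersion: float = 5000.0
    # methylation
    dmr_count: int = 30               # planted DMRs, genome wide
    dmr_length: int = 300
    meth_sites_per_chromosome: int = 2_000
    meth_depth: float = 30.0

    def validate(self) -> None:
        for name in ("snp_rate", "indel_rate", "pav_gene_fraction",
                     "chimera_rate", "del_fraction", "library_size_cv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in ("n_chromosomes", "chrom_length", "n_progeny",
                     "genes_per_chromosome", "scaffold_n50", "window_size",
                     "read_length", "n_tissues", "n_replicates"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name}={v} must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.sv_count < 0 or self.dmr_count < 0:
            raise ValueError("counts must be nonnegative")
        # genes must fit: reserve ~2 kb per gene plus spacing
        if self.genes_per_chromosome * 4_000 > self.chrom_length:
            raise ValueError(
                "gene placement impossible: genes_per_chromosome too high "
                f"for chrom_length={self.chrom_length}")
        expected_var_per_bp = self.snp_rate + self.indel_rate * 60
        if expected_var_per_bp > 0.5:
            raise ValueError("variant density too high for gene placement")
        for locus in self.lethal_loci:
            if not 1 <= locus.chrom <= self.n_chromosomes:
                raise ValueError(f"lethal locus on unknown chromosome {locus.chrom}")
            if not 0 <= locus.pos < self.chrom_length:
                raise ValueError(f"lethal locus position {locus.pos} out of range")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lethal_loci"] = [dataclasses.asdict(l) for l in self.lethal_loci]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        loci = [LethalLocus(**l) if isinstance(l, dict) else l
                for l in d.pop("lethal_loci", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(lethal_loci=loci, **d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineConfig:
    """Parameters of the analysis stages (thresholds, windows, gates)."""

    # genotyping
    min_llr: float = math.log(3.0)
    min_lambda2: float = 1.0
    max_missing: float = 0.4
    # phasing
    corr_threshold: float = 0.7
    min_overlap: int = 30
    min_group_size: int = 5
    rescue_threshold: float = 0.7
    contrary_threshold: float = -0.5
    window_size: int = 200_000
    # SD scan
    sd_window: int = 300_000
    sd_alpha: float = 0.001
    sd_min_n: int = 20
    exclusion_eps: float = 0.01
    # synteny / variants
    homolog_min_coverage: float = 0.75
    homolog_min_identity: float = 0.75
    min_anchors: int = 5
    max_anchor_gap: int = 25
    max_length_ratio: float = 3.0
    min_block_coverage: float = 0.5
    max_align_len: int = 100_000
    match_score: float = 1.0
    mismatch_score: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    # expression
    max_cv: float = 0.30
    min_summed_tpm: float = 1.0
    fdr: float = 0.05
    fdr_method: str = "bh"            # "bh" or "none"
    # methylation
    meth_min_depth: int = 5
    meth_thresholds: dict = field(default_factory=lambda: {
        "CG": 0.4, "CHG": 0.2, "CHH": 0.1})
    meth_p: float = 0.01
    dmr_max_gap: int = 100
    dmr_min_sites: int = 2
    gene_flank: int = 2_000

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
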