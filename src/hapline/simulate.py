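"""Synthetic diploid genome + selfed-F2 population generator.

The generator emulates the study design the pipeline targets: a heterozygous
diploid parent whose two haplotypes differ by ~2% (SNPs, 1-50 bp indels,
>50 bp SVs and presence/absence genes), selfed to give an F2 population in
which every locus segregates 1:2:1 unless a planted recessive lethal or
low-vigor locus distorts it.  Each progeny is "sequenced" as Poisson read
counts per haplotype-specific scaffold at ~1x coverage.  Per-allele
expression and per-cytosine methylation tables with planted differential
effects complete the inputs for the downstream analyses.

Everything is driven by a single integer seed through
:class:`numpy.random.Generator`; identical configs give byte-identical
outputs.  Coordinates in all public records are 1-based inclusive.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)
                 if "".join(c) not in _STOPS]


def encode_seq(s: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def decode_seq(arr: np.ndarray) -> str:
    return bytes(_BASES[arr]).decode()


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    chrom: int
    haplotype: int
    start: int            # 1-based inclusive
    end: int
    strand: str
    pair_id: int          # genes sharing pair_id are true alleles
    is_pav: bool = False

    def cds(self, truth: "TruthSet") -> str:
        seq = truth.seqs[(self.chrom, self.haplotype)]
        return decode_seq(seq[self.start - 1:self.end])


class CoordMap:
    """Monotone position map from haplotype 1 to haplotype 2 of one chromosome.

    Built from the edit script (insertions/deletions in h1 coordinates).
    ``to_h2`` returns -1 for h1 positions deleted from h2; h1 positions have
    no image inside h2-only insertions, so the map is injective elsewhere.
    """

    def __init__(self, edits: list[tuple[str, int, int]], h1_len: int):
        # edits: (kind 'INS'|'DEL', pos_h1 (1-based anchor), length)
        pts, offs = [0], [0]
        del_iv = []
        off = 0
        for kind, pos, length in sorted(edits, key=lambda e: e[1]):
            if kind == "INS":          # inserted into h2 after h1 pos
                off += length
                pts.append(pos + 1)
                offs.append(off)
            else:                      # deleted from h2: h1 [pos+1, pos+length]
                del_iv.append((pos + 1, pos + length))
                off -= length
                pts.append(pos + length + 1)
                offs.append(off)
        self._pts = np.array(pts)
        self._offs = np.array(offs)
        self._del_starts = np.array([a for a, _ in del_iv])
        self._del_ends = np.array([b for _, b in del_iv])
        self.h1_len = h1_len
        self.h2_len = h1_len + off

    def to_h2(self, pos: np.ndarray | int) -> np.ndarray | int:
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        idx = np.searchsorted(self._pts, pos_arr, side="right") - 1
        out = pos_arr + self._offs[idx]
        if len(self._del_starts):
            j = np.searchsorted(self._del_starts, pos_arr, side="right") - 1
            deleted = (j >= 0) & (pos_arr <= self._del_ends[np.maximum(j, 0)])
            out[deleted] = -1
        return out if np.ndim(pos) else int(out[0])


@dataclass
class Scaffold:
    scaffold_id: str
    # list of (chrom, haplotype, start, end) 1-based inclusive source segments
    segments: list[tuple[int, int, int, int]]
    length: int
    is_chimeric: bool = False
    breakpoints: list[int] = field(default_factory=list)  # offsets in scaffold


@dataclass
class ProgenyCountMatrix:
    scaffold_ids: list[str]
    scaffold_lengths: np.ndarray
    progeny_ids: list[str]
    counts: np.ndarray                # scaffold x progeny, int
    progeny_totals: np.ndarray
    assembly_total_length: int
    # scaffold_id -> (window boundaries within scaffold, windows x progeny counts)
    window_counts: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.scaffold_ids,
                          columns=self.progeny_ids)
        df.insert(0, "length", self.scaffold_lengths)
        return df


@dataclass
class TruthSet:
    config: SimConfig
    seqs: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)
    variants: pd.DataFrame | None = None
    coord_maps: dict[int, CoordMap] = field(default_factory=dict)
    # population: per chromosome, start haplotypes (progeny x 2 gametes, 0/1)
    # and ragged crossover position lists
    gamete_starts: dict[int, np.ndarray] = field(default_factory=dict)
    gamete_xos: dict[int, list[list[np.ndarray]]] = field(default_factory=dict)
    scaffolds: list[Scaffold] = field(default_factory=list)
    del_truth: pd.DataFrame | None = None
    dmr_truth: pd.DataFrame | None = None

    @property
    def n_progeny(self) -> int:
        starts = next(iter(self.gamete_starts.values()))
        return starts.shape[0]

    def haplotype_name(self, chrom: int, hap: int) -> str:
        return f"chr{chrom}_{hap}"

    def total_length(self) -> int:
        return sum(len(s) for s in self.seqs.values())

    def dosage_h1(self, chrom: int, positions: np.ndarray) -> np.ndarray:
        """Dosage of haplotype 1 at given positions: progeny x positions."""
        positions = np.asarray(positions)
        starts = self.gamete_starts[chrom]
        xos = self.gamete_xos[chrom]
        n = starts.shape[0]
        out = np.zeros((n, len(positions)), dtype=np.int8)
        for p in range(n):
            for gam in range(2):
                hap = starts[p, gam] ^ (
                    np.searchsorted(xos[p][gam], positions) & 1)
                out[p] += (hap == 0)
        return out

    def scaffold_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scaffolds:
            for i, (c, h, a, b) in enumerate(s.segments):
                rows.append({"scaffold": s.scaffold_id, "part": i,
                             "chrom": c, "haplotype": h, "start": a, "end": b,
                             "is_chimeric": s.is_chimeric})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _place_genes(rng, chrom_length, n_genes):
    spacing = chrom_length // (n_genes + 1)
    positions = []
    for i in range(n_genes):
        center = (i + 1) * spacing + int(rng.integers(-spacing // 4,
                                                      spacing // 4 + 1))
        n_codons = int(rng.integers(100, 401))
        length = 3 * n_codons
        start = max(1, center - length // 2)
        positions.append((start, start + length - 1, n_codons))
    return positions


def simulate_diploid_genome(config: SimConfig) -> TruthSet:
    """Generate two ~2%-divergent haplotypes with genes, PAVs and SVs."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.Generator(np.random.PCG64(s))
            for s in root.spawn(config.n_chromosomes + 1)]
    truth = TruthSet(config=config)
    var_rows = []
    pair_counter = 0
    L = config.chrom_length

    for c in range(1, config.n_chromosomes + 1):
        rng = rngs[c - 1]
        h1 = rng.integers(0, 4, size=L).astype(np.uint8)  # ACGT codes 0-3

        # -- genes on h1 ----------------------------------------------------
        gene_iv = _place_genes(rng, L, config.genes_per_chromosome)
        gene_mask = np.zeros(L, dtype=bool)     # True = no indel/SV here
        chrom_genes = []
        for start, end, n_codons in gene_iv:
            cds = _random_cds(rng, n_codons)
            h1[start - 1:end] = encode_seq(cds)
            gene_mask[max(0, start - 51):min(L, end + 50)] = True
            pair_counter += 1
            chrom_genes.append(GeneModel(
                gene_id=f"g{c}_{pair_counter:05d}_h1", chrom=c, haplotype=1,
                start=start, end=end, strand="+", pair_id=pair_counter))

        # -- PAV choices ----------------------------------------------------
        n_pav = int(round(config.pav_gene_fraction * len(chrom_genes)))
        pav_idx = rng.choice(len(chrom_genes), size=n_pav, replace=False) \
            if n_pav else np.array([], dtype=int)
        pav_lost_hap = rng.integers(1, 3, size=n_pav)   # hap that LACKS it

        # -- edit list (h1 -> h2), 1-based anchors --------------------------
        edits = []          # (sort_pos, kind, pos, length, payload, vclass)
        snp_pos = np.flatnonzero(rng.random(L) < config.snp_rate) + 1
        snp_shift = rng.integers(1, 4, size=len(snp_pos))

        cand = np.flatnonzero(rng.random(L) < config.indel_rate) + 1
        cand = cand[(cand > 100) & (cand < L - 200)]
        cand = cand[~gene_mask[cand - 1]]
        ind_len = np.minimum(rng.geometric(0.4, size=len(cand)), 50)
        ind_ins = rng.random(len(cand)) < 0.5
        for pos, ln, is_ins in zip(cand, ind_len, ind_ins):
            vclass = "indel" if ln <= 50 else "SV"
            if is_ins:
                payload = decode_seq(rng.integers(0, 4, size=ln).astype(np.uint8))
                edits.append((pos, "INS", int(pos), int(ln), payload, vclass))
            else:
                if gene_mask[pos:pos + ln].any():
                    continue
                edits.append((pos, "DEL", int(pos), int(ln), None, vclass))

        sv_pos = rng.integers(1000, L - 5000, size=config.sv_count)
        sv_len = rng.integers(51, 2001, size=config.sv_count)
        sv_ins = rng.random(config.sv_count) < 0.5
        for pos, ln, is_ins in zip(sv_pos, sv_len, sv_ins):
            if is_ins:
                payload = decode_seq(rng.integers(0, 4, size=ln).astype(np.uint8))
                edits.append((int(pos), "INS", int(pos), int(ln), payload, "SV"))
            else:
                if gene_mask[pos:pos + ln].any():
                    continue
                edits.append((int(pos), "DEL", int(pos), int(ln), None, "SV"))

        # PAV edits: gene lost on h2 -> DEL of its body; lost on h1 -> an
        # extra gene inserted into h2 at an intergenic point.
        h2_only_genes = []
        for gi, lost in zip(pav_idx, pav_lost_hap):
            g = chrom_genes[gi]
            if g.start < 2:
                continue
            if lost == 2:
                g.is_pav = True
                ln = g.end - g.start + 1
                edits.append((g.start - 1, "DEL", g.start - 1, ln, None, "PAV"))
            else:
                # replace the h1 gene with a fresh h2-only gene elsewhere
                n_codons = int(rng.integers(100, 401))
                cds = _random_cds(rng, n_codons)
                anchor = int(rng.integers(500, L - 500))
                while gene_mask[anchor - 1:anchor + 1].any():
                    anchor = int(rng.integers(500, L - 500))
                pair_counter += 1
                edits.append((anchor, "INS", anchor, len(cds), cds, "PAV"))
                h2_only_genes.append((anchor, len(cds), pair_counter))

        # resolve overlaps: keep earlier edit, drop overlapping later ones
        edits.sort(key=lambda e: e[0])
        kept, last_end = [], -1
        for e in edits:
            pos, kind, _, ln, _, _ = e
            span_start = pos
            span_end = pos + (ln if kind == "DEL" else 1)
            if span_start <= last_end:
                continue
            kept.append(e)
            last_end = span_end
        # drop SNPs falling inside deleted spans or on edit anchors
        del_spans = [(e[2] + 1, e[2] + e[3]) for e in kept if e[1] == "DEL"]
        if del_spans:
            ds = np.array([a for a, _ in del_spans])
            de = np.array([b for _, b in del_spans])
            j = np.searchsorted(ds, snp_pos, side="right") - 1
            in_del = (j >= 0) & (snp_pos <= de[np.maximum(j, 0)])
            snp_pos, snp_shift = snp_pos[~in_del], snp_shift[~in_del]

        # -- build h2 -------------------------------------------------------
        h2_with_snps = h1.copy()
        h2_with_snps[snp_pos - 1] = (h2_with_snps[snp_pos - 1]
                                     + snp_shift) % 4
        pieces, cursor = [], 0          # cursor: 0-based in h1
        cmap_edits = []
        for pos, kind, _, ln, payload, vclass in kept:
            if kind == "INS":
                pieces.append(h2_with_snps[cursor:pos])
                pieces.append(encode_seq(payload))
                cursor = pos
                cmap_edits.append(("INS", pos, ln))
                ref = decode_seq(h1[pos - 1:pos])
                var_rows.append({"class": vclass, "kind": "INS", "chrom": c,
                                 "pos_h1": pos, "length": ln,
                                 "ref": ref, "alt": ref + payload})
            else:
                pieces.append(h2_with_snps[cursor:pos])
                cursor = pos + ln
                cmap_edits.append(("DEL", pos, ln))
                ref = decode_seq(h1[pos - 1:pos + ln])
                var_rows.append({"class": vclass, "kind": "DEL", "chrom": c,
                                 "pos_h1": pos, "length": ln,
                                 "ref": ref, "alt": ref[0]})
        pieces.append(h2_with_snps[cursor:])
        h2 = np.concatenate(pieces)
        cmap = CoordMap(cmap_edits, L)
        assert cmap.h2_len == len(h2)
        truth.coord_maps[c] = cmap

        for pos, shift in zip(snp_pos, snp_shift):
            var_rows.append({"class": "SNP", "kind": "SNP", "chrom": c,
                             "pos_h1": int(pos), "length": 1,
                             "ref": decode_seq(h1[pos - 1:pos]),
                             "alt": decode_seq(np.array(
                                 [(h1[pos - 1] + shift) % 4], dtype=np.uint8))})

        truth.seqs[(c, 1)] = h1
        truth.seqs[(c, 2)] = h2

        # -- gene models on h2 ---------------------------------------------
        for g in chrom_genes:
            truth.genes.append(g)
            if g.is_pav:
                continue
            s2 = cmap.to_h2(g.start)
            e2 = cmap.to_h2(g.end)
            if s2 < 0 or e2 < 0 or e2 - s2 != g.end - g.start:
                g.is_pav = True     # clobbered by an overlapping edit
                continue
            truth.genes.append(GeneModel(
                gene_id=g.gene_id[:-3] + "_h2", chrom=c, haplotype=2,
                start=int(s2), end=int(e2), strand="+", pair_id=g.pair_id))
        for anchor, ln, pid in h2_only_genes:
            s2 = cmap.to_h2(anchor)
            if s2 < 0:
                continue
            truth.genes.append(GeneModel(
                gene_id=f"g{c}_{pid:05d}_h2", chrom=c, haplotype=2,
                start=int(s2) + 1, end=int(s2) + ln, strand="+",
                pair_id=pid, is_pav=True))

    variants = pd.DataFrame(var_rows)
    if len(variants):
        variants = variants.sort_values(["chrom", "pos_h1"],
                                        kind="stable").reset_index(drop=True)
        pos_h2 = np.concatenate([
            truth.coord_maps[c].to_h2(
                variants.loc[variants.chrom == c, "pos_h1"].to_numpy())
            for c in sorted(variants.chrom.unique())])
        variants["pos_h2"] = pos_h2
    truth.variants = variants
    return truth


def true_diversity_percent(truth: TruthSet) -> float:
    """Planted divergence: (SNPs + indel/SV bases) / aligned h1 bases * 100."""
    v = truth.variants
    n_snp = int((v["class"] == "SNP").sum())
    gap_bases = int(v.loc[v["class"] != "SNP", "length"].sum())
    aligned = sum(len(truth.seqs[(c, 1)])
                  for c in range(1, truth.config.n_chromosomes + 1))
    return 100.0 * (n_snp + gap_bases) / aligned


# ---------------------------------------------------------------------------
# Selfing population
# ---------------------------------------------------------------------------

def _draw_gamete(rng, L, map_len):
    n_xo = rng.poisson(map_len)
    xos = np.sort(rng.uniform(0, L, size=n_xo)) if n_xo else np.empty(0)
    return int(rng.integers(0, 2)), xos


def simulate_selfing_population(truth: TruthSet, config: SimConfig) -> TruthSet:
    """Draw the selfed F2: two independent gametes per progeny, with
    rejection at recessive-lethal loci and downweighting at vigor loci."""
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed).spawn(
            config.n_chromosomes + 1)[-1]))
    chroms = range(1, config.n_chromosomes + 1)
    starts = {c: [] for c in chroms}
    xos = {c: [] for c in chroms}
    n_accepted, attempts = 0, 0
    max_attempts = max(10_000, 500 * config.n_progeny)
    loci_by_chrom: dict[int, list] = {}
    for locus in config.lethal_loci:
        loci_by_chrom.setdefault(locus.chrom, []).append(locus)

    while n_accepted < config.n_progeny:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "selfing population unattainable under the configured "
                "lethal loci (acceptance rate too low)")
        cand = {c: [_draw_gamete(rng, config.chrom_length,
                                 config.map_length_morgans),
                    _draw_gamete(rng, config.chrom_length,
                                 config.map_length_morgans)]
                for c in chroms}
        survive = True
        for c, loci in loci_by_chrom.items():
            for locus in loci:
                d1 = 0
                for s, x in cand[c]:
                    hap = s ^ (int(np.searchsorted(x, locus.pos)) & 1)
                    d1 += (hap == 0)
                carrier_dosage = d1 if locus.carrier_haplotype == 1 else 2 - d1
                if carrier_dosage == 2:
                    if locus.mode == "lethal":
                        survive = False
                    elif rng.random() >= locus.viability:
                        survive = False
            if not survive:
                break
        if not survive:
            continue
        for c in chroms:
            starts[c].append([cand[c][0][0], cand[c][1][0]])
            xos[c].append([cand[c][0][1], cand[c][1][1]])
        n_accepted += 1

    for c in chroms:
        truth.gamete_starts[c] = np.array(starts[c], dtype=np.int8)
        truth.gamete_xos[c] = xos[c]
    return truth


# ---------------------------------------------------------------------------
# Scaffolding
# ---------------------------------------------------------------------------

def _cut_positions(rng, L, n50):
    sigma = 0.7
    mu = np.log(n50) - sigma ** 2
    cuts, pos = [0], 0
    while pos < L:
        pos += max(1_000, int(rng.lognormal(mu, sigma)))
        cuts.append(min(pos, L))
    if len(cuts) > 2 and cuts[-1] - cuts[-2] < 1_000:
        del cuts[-2]
    return np.array(cuts)


def fragment_into_scaffolds(truth: TruthSet, config: SimConfig) -> list[Scaffold]:
    """Cut each haplotype into scaffolds; optionally cross-join a fraction of
    homologous interval pairs into chimeric scaffolds.

    Cuts are placed jointly on the homolog pair (h2 positions via the
    coordinate map) so that a chimeric scaffold switches haplotype at a
    homologous junction — the assembly failure mode the phasing stage breaks.
    Junctions sit on the scaffold's ``window_size`` grid.
    """
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed).spawn(
            config.n_chromosomes + 2)[-1]))
    scaffolds = []
    sid = 0
    w = config.window_size
    for c in range(1, config.n_chromosomes + 1):
        L = config.chrom_length
        cmap = truth.coord_maps[c]
        cuts1 = _cut_positions(rng, L, config.scaffold_n50)
        cuts2 = np.array([0] + [max(int(cmap.to_h2(int(x))), 1)
                                for x in cuts1[1:-1]] + [cmap.h2_len])
        cuts2 = np.maximum.accumulate(cuts2)
        for i in range(len(cuts1) - 1):
            a1, b1 = int(cuts1[i]) + 1, int(cuts1[i + 1])     # 1-based incl
            a2, b2 = int(cuts2[i]) + 1, int(cuts2[i + 1])
            len1, len2 = b1 - a1 + 1, b2 - a2 + 1
            eligible = min(len1, len2) >= 2 * w
            if eligible and config.chimera_rate > 0 and \
                    rng.random() < config.chimera_rate:
                kmax = min(len1, len2) // w - 1
                k = int(rng.integers(1, kmax + 1))
                m1 = a1 + k * w       # first pos of the right part on h1
                m2 = a2 + k * w
                sid += 1
                sA = Scaffold(f"scf{sid:05d}",
                              [(c, 1, a1, m1 - 1), (c, 2, m2, b2)],
                              (m1 - a1) + (b2 - m2 + 1),
                              is_chimeric=True, breakpoints=[k * w])
                sid += 1
                sB = Scaffold(f"scf{sid:05d}",
                              [(c, 2, a2, m2 - 1), (c, 1, m1, b1)],
                              (m2 - a2) + (b1 - m1 + 1),
                              is_chimeric=True, breakpoints=[k * w])
                scaffolds.extend([sA, sB])
            else:
                for hap, (a, b) in ((1, (a1, b1)), (2, (a2, b2))):
                    if b < a:
                        continue
                    sid += 1
                    scaffolds.append(Scaffold(
                        f"scf{sid:05d}", [(c, hap, a, b)], b - a + 1))
    truth.scaffolds = scaffolds
    return scaffolds


def scaffold_sequence(truth: TruthSet, scaffold: Scaffold) -> str:
    parts = [decode_seq(truth.seqs[(c, h)][a - 1:b])
             for c, h, a, b in scaffold.segments]
    return "".join(parts)


# ---------------------------------------------------------------------------
# Progeny read counts
# ---------------------------------------------------------------------------

def simulate_progeny_counts(scaffolds: list[Scaffold], truth: TruthSet,
                            config: SimConfig,
                            window_size: int | None = None) -> ProgenyCountMatrix:
    """Poisson read counts per scaffold per progeny.

    count ~ Poisson(T_p * sum_parts len_part * d_part / (2 G)) where T_p is
    the progeny's library size in reads, G the total diploid length and
    d_part the progeny's dosage of the part's haplotype at its midpoint.
    Scaffolds at least two windows long additionally get per-window counts
    (the scaffold count is their sum), the substrate for chimera detection.
    """
    if window_size is None:
        window_size = config.window_size
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed).spawn(
            config.n_chromosomes + 3)[-1]))
    G = truth.total_length()
    P = truth.n_progeny
    mean_reads = config.coverage * G / config.read_length
    cv = config.library_size_cv
    factors = rng.lognormal(-0.5 * cv ** 2, cv, size=P) if cv > 0 \
        else np.ones(P)
    totals = np.maximum(1, np.round(mean_reads * factors)).astype(np.int64)

    # chunk every scaffold; record (scaffold idx, window idx, chrom, hap,
    # part-length, midpoint) then batch dosage lookups per chromosome
    chunk_rows = []
    for si, s in enumerate(scaffolds):
        if s.length >= 2 * window_size:
            edges = list(range(0, s.length, window_size))
            if s.length - edges[-1] < window_size // 2 and len(edges) > 1:
                edges.pop()
            edges.append(s.length)
        else:
            edges = [0, s.length]
        seg_bounds = np.cumsum([0] + [b - a + 1 for _, _, a, b in s.segments])
        for wi in range(len(edges) - 1):
            lo, hi = edges[wi], edges[wi + 1]
            for pi, (c, h, a, b) in enumerate(s.segments):
                plo, phi = max(lo, seg_bounds[pi]), min(hi, seg_bounds[pi + 1])
                if phi <= plo:
                    continue
                gen_lo = a + (plo - seg_bounds[pi])
                gen_hi = a + (phi - seg_bounds[pi]) - 1
                mid = (gen_lo + gen_hi) // 2
                chunk_rows.append((si, wi, c, h, phi - plo, mid,
                                   len(edges) - 1))
    chunks = pd.DataFrame(chunk_rows, columns=[
        "scaffold", "window", "chrom", "hap", "plen", "mid", "n_windows"])

    lam = np.zeros((len(chunks), P))
    for c in sorted(chunks.chrom.unique()):
        sel = chunks.chrom == c
        dos1 = truth.dosage_h1(c, chunks.loc[sel, "mid"].to_numpy())  # P x k
        hap = chunks.loc[sel, "hap"].to_numpy()
        d = np.where(hap[None, :] == 1, dos1, 2 - dos1).T               # k x P
        lam[sel.to_numpy()] = (chunks.loc[sel, "plen"].to_numpy()[:, None]
                               * d * totals[None, :] / (2.0 * G))
    chunk_counts = rng.poisson(lam)

    S = len(scaffolds)
    counts = np.zeros((S, P), dtype=np.int64)
    win_counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped = chunks.groupby("scaffold", sort=True)
    for si, idx in grouped.groups.items():
        idx = np.asarray(idx)
        sub = chunks.loc[idx]
        counts[si] = chunk_counts[idx].sum(axis=0)
        nw = int(sub.n_windows.iloc[0])
        if nw > 1:
            s = scaffolds[si]
            edges = list(range(0, s.length, window_size))
            if s.length - edges[-1] < window_size // 2 and len(edges) > 1:
                edges.pop()
            edges.append(s.length)
            wmat = np.zeros((nw, P), dtype=np.int64)
            for wi in range(nw):
                widx = idx[sub.window.to_numpy() == wi]
                wmat[wi] = chunk_counts[widx].sum(axis=0)
            win_counts[s.scaffold_id] = (np.array(edges), wmat)

    return ProgenyCountMatrix(
        scaffold_ids=[s.scaffold_id for s in scaffolds],
        scaffold_lengths=np.array([s.length for s in scaffolds]),
        progeny_ids=[f"p{j:04d}" for j in range(P)],
        counts=counts, progeny_totals=totals,
        assembly_total_length=G, window_counts=win_counts)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def allelic_pairs_truth(truth: TruthSet) -> pd.DataFrame:
    """True allele pairs (both haplotypes present)."""
    by_pair: dict[int, dict[int, GeneModel]] = {}
    for g in truth.genes:
        by_pair.setdefault(g.pair_id, {})[g.haplotype] = g
    rows = []
    for pid, d in sorted(by_pair.items()):
        if 1 in d and 2 in d:
            rows.append({"pair_id": pid, "gene_h1": d[1].gene_id,
                         "gene_h2": d[2].gene_id, "chrom": d[1].chrom})
    return pd.DataFrame(rows)


def simulate_expression(truth: TruthSet, config: SimConfig
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial per-allele counts over tissues and replicates,
    with a ``del_fraction`` subset of pairs given a true fold-change; TPM
    computed from counts and transcript lengths."""
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed).spawn(
            config.n_chromosomes + 4)[-1]))
    pairs = allelic_pairs_truth(truth)
    genes = {g.gene_id: g for g in truth.genes}
    n_pairs = len(pairs)
    base_mean = rng.lognormal(np.log(config.expr_mean), 0.6, size=n_pairs)
    tissue_factor = rng.lognormal(0.0, 0.4,
                                  size=(n_pairs, config.n_tissues))
    is_del = rng.random(n_pairs) < config.del_fraction
    higher_hap = rng.integers(1, 3, size=n_pairs)
    size = config.expr_dispersion

    rows = []
    del_rows = []
    for i, pr in enumerate(pairs.itertuples(index=False)):
        for hap, gid in ((1, pr.gene_h1), (2, pr.gene_h2)):
            g = genes[gid]
            tlen = g.end - g.start + 1
            fold = 1.0
            if is_del[i]:
                fold = (config.del_fold_change if hap == higher_hap[i]
                        else 1.0)
            for t in range(config.n_tissues):
                m = base_mean[i] * tissue_factor[i, t] * fold
                p_nb = size / (size + m)
                cnt = rng.negative_binomial(size, p_nb,
                                            size=config.n_replicates)
                for r in range(config.n_replicates):
                    rows.append({"pair_id": pr.pair_id, "gene": gid,
                                 "haplotype": hap, "tissue": f"t{t+1}",
                                 "replicate": r + 1,
                                 "est_count": int(cnt[r]), "tlen": tlen})
        if is_del[i]:
            del_rows.append({"pair_id": pr.pair_id,
                             "higher_haplotype": int(higher_hap[i]),
                             "fold_change": config.del_fold_change})
    expr = pd.DataFrame(rows)
    # TPM per (tissue, replicate) library
    expr["rate"] = expr.est_count / expr.tlen
    denom = expr.groupby(["tissue", "replicate"])["rate"].transform("sum")
    expr["tpm"] = np.where(denom > 0, expr.rate / denom * 1e6, 0.0)
    expr = expr.drop(columns=["rate"])
    return expr, pd.DataFrame(del_rows)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

_CTX_BASE_PI = {"CG": 0.85, "CHG": 0.55, "CHH": 0.10}
_DMR_PI = {"CG": (0.90, 0.10), "CHG": (0.85, 0.10), "CHH": (0.50, 0.05)}


def _cytosine_context(seq: np.ndarray, pos0: int) -> tuple[str, str] | None:
    """(strand, context) of a 0-based position, or None if not a cytosine."""
    b = seq[pos0]
    L = len(seq)
    if b == 1:                                  # C on + strand
        if pos0 + 1 < L and seq[pos0 + 1] == 2:
            return "+", "CG"
        if pos0 + 2 < L and seq[pos0 + 2] == 2:
            return "+", "CHG"
        return "+", "CHH"
    if b == 2:                                  # G -> C on - strand
        if pos0 - 1 >= 0 and seq[pos0 - 1] == 1:
            return "-", "CG"
        if pos0 - 2 >= 0 and seq[pos0 - 2] == 1:
            return "-", "CHG"
        return "-", "CHH"
    return None


def simulate_methylation(truth: TruthSet, config: SimConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Binomial methylation counts per cytosine for both haplotypes, with
    ``dmr_count`` planted differentially methylated regions centred on genes.

    Returns (sites_h1, sites_h2, dmr_truth).  Sites are a random sample of
    cytosines per chromosome plus every cytosine inside planted DMRs.
    """
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(config.seed).spawn(
            config.n_chromosomes + 5)[-1]))
    pairs = allelic_pairs_truth(truth)
    genes = {g.gene_id: g for g in truth.genes}

    # plant DMRs on randomly chosen paired genes, round-robin chromosomes
    dmr_rows = []
    if config.dmr_count and len(pairs):
        chosen = rng.choice(len(pairs), size=min(config.dmr_count, len(pairs)),
                            replace=False)
        for k, idx in enumerate(sorted(chosen)):
            pr = pairs.iloc[idx]
            g1 = genes[pr.gene_h1]
            start = max(1, g1.start - config.dmr_length // 3)
            end = min(len(truth.seqs[(g1.chrom, 1)]),
                      start + config.dmr_length - 1)
            dmr_rows.append({"dmr_id": f"dmr{k+1:03d}", "chrom": g1.chrom,
                             "start": start, "end": end,
                             "hyper_haplotype": int(rng.integers(1, 3)),
                             "pair_id": int(pr.pair_id)})
    dmr_truth = pd.DataFrame(dmr_rows)

    rows1, rows2 = [], []
    for c in range(1, config.n_chromosomes + 1):
        seq1 = truth.seqs[(c, 1)]
        seq2 = truth.seqs[(c, 2)]
        cmap = truth.coord_maps[c]
        cg_pos = np.flatnonzero((seq1 == 1) | (seq1 == 2))        # 0-based
        n_sample = min(config.meth_sites_per_chromosome, len(cg_pos))
        sampled = rng.choice(cg_pos, size=n_sample, replace=False)
        dmrs_c = dmr_truth[dmr_truth.chrom == c] if len(dmr_truth) else None
        extra = []
        if dmrs_c is not None:
            for d in dmrs_c.itertuples(index=False):
                iv = cg_pos[(cg_pos >= d.start - 1) & (cg_pos <= d.end - 1)]
                extra.append(iv)
        pos0 = np.unique(np.concatenate([sampled] + extra)) if extra \
            else np.unique(sampled)

        for p0 in pos0:
            sc = _cytosine_context(seq1, int(p0))
            if sc is None:
                continue
            strand, ctx = sc
            pos1 = int(p0) + 1
            pi = float(np.clip(_CTX_BASE_PI[ctx] + rng.normal(0, 0.03),
                               0.01, 0.99))
            pi1 = pi2 = pi
            in_dmr = None
            if dmrs_c is not None and len(dmrs_c):
                hit = dmrs_c[(dmrs_c.start <= pos1) & (pos1 <= dmrs_c.end)]
                if len(hit):
                    in_dmr = hit.iloc[0]
            if in_dmr is not None:
                hi, lo = _DMR_PI[ctx]
                if in_dmr.hyper_haplotype == 1:
                    pi1, pi2 = hi, lo
                else:
                    pi1, pi2 = lo, hi
            # paired position on h2, if it survives the edit script
            p2 = cmap.to_h2(pos1)
            has_h2 = p2 > 0 and p2 <= len(seq2) and seq2[p2 - 1] == seq1[p0]
            for rep in range(1, config.n_replicates + 1):
                d1 = int(rng.poisson(config.meth_depth))
                m1 = int(rng.binomial(d1, pi1)) if d1 else 0
                rows1.append((f"chr{c}_1", pos1, strand, ctx, rep, m1, d1))
                if has_h2:
                    d2 = int(rng.poisson(config.meth_depth))
                    m2 = int(rng.binomial(d2, pi2)) if d2 else 0
                    rows2.append((f"chr{c}_2", int(p2), strand, ctx, rep,
                                  m2, d2))
    cols = ["chrom", "pos", "strand", "context", "replicate", "meth", "depth"]
    return (pd.DataFrame(rows1, columns=cols),
            pd.DataFrame(rows2, columns=cols), dmr_truth)


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig) -> tuple[TruthSet, ProgenyCountMatrix]:
    """Genome -> population -> scaffolds -> counts, in one call."""
    truth = simulate_diploid_genome(config)
    simulate_selfing_population(truth, config)
    scaffolds = fragment_into_scaffolds(truth, config)
    pcm = simulate_progeny_counts(scaffolds, truth, config)
    return truth, pcm
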