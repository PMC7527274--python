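"""File-format readers and writers.

Conventions used throughout the package:

* GFF3, VCF, AGP and the internal TSV tables are 1-based, inclusive.
* BED output is 0-based, half-open; the conversion happens here and only here.
* Every file written by the pipeline starts with comment lines recording the
  package version, a config hash and the seed, so a result can always be tied
  back to the exact run that produced it.

Malformed input lines raise :class:`FormatError` with file/line context;
nothing is skipped silently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


class FormatError(ValueError):
    """Raised on malformed input with file and line context."""


def header_lines(seed: int | None = None, config_hash: str | None = None,
                 comment: str = "#") -> list[str]:
    parts = [f"hapline v{__version__}"]
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return [f"{comment} " + "; ".join(parts)]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seq_records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (1-based, inclusive)
# ---------------------------------------------------------------------------

@dataclass
class Gff3Record:
    seqid: str
    source: str
    type: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    score: str = "."
    strand: str = "+"
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def attr_string(self) -> str:
        return ";".join(f"{k}={v}" for k, v in self.attributes.items())


def write_gff3(path: str | Path, records: Iterable[Gff3Record],
               seed: int | None = None, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        for r in records:
            fh.write("\t".join([
                r.seqid, r.source, r.type, str(r.start), str(r.end),
                r.score, r.strand, r.phase, r.attr_string()]) + "\n")


def read_gff3(path: str | Path) -> list[Gff3Record]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, "
                                  f"got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from e
            attrs = {}
            if fields[8] not in (".", ""):
                for item in fields[8].split(";"):
                    if not item:
                        continue
                    if "=" not in item:
                        raise FormatError(
                            f"{path}:{lineno}: malformed attribute {item!r}")
                    k, v = item.split("=", 1)
                    attrs[k] = v
            records.append(Gff3Record(fields[0], fields[1], fields[2],
                                      start, end, fields[5], fields[6],
                                      fields[7], attrs))
    return records


# ---------------------------------------------------------------------------
# BED (0-based, half-open on disk; API takes 1-based inclusive)
# ---------------------------------------------------------------------------

def write_bed(path: str | Path,
              intervals: Iterable[tuple],
              seed: int | None = None, config_hash: str | None = None) -> None:
    """Write 1-based inclusive (chrom, start, end, *extra) intervals as BED."""
    with open(path, "w") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        for iv in intervals:
            chrom, start, end, *extra = iv
            fh.write("\t".join([str(chrom), str(int(start) - 1), str(int(end))]
                               + [str(x) for x in extra]) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED; returns 1-based inclusive (chrom, start, end, *extra)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from e
            out.append((fields[0], start0 + 1, end0, *fields[3:]))
    return out


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

def write_vcf(path: str | Path, variants: pd.DataFrame, reference: str,
              contigs: dict[str, int] | None = None,
              seed: int | None = None, config_hash: str | None = None) -> None:
    """Write variant calls as VCF 4.2 against one haplotype reference.

    ``variants`` needs columns chrom, pos (1-based), ref, alt, type, length.
    SVs (>50 bp) carry SVLEN/SVTYPE INFO fields.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_lines(seed, config_hash, comment="##"):
            fh.write(line.replace("## ", "##source=", 1) + "\n")
        fh.write(f"##reference={reference}\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant class">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in variants.itertuples(index=False):
            info = f"VT={r.type}"
            if r.type == "SV":
                svtype = "INS" if len(r.alt) > len(r.ref) else "DEL"
                svlen = len(r.alt) - len(r.ref)
                info += f";SVLEN={svlen};SVTYPE={svtype}"
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


def read_vcf(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: fewer than 8 VCF columns")
            info = dict(item.split("=", 1) if "=" in item else (item, True)
                        for item in fields[7].split(";"))
            rows.append({"chrom": fields[0], "pos": int(fields[1]),
                         "ref": fields[3], "alt": fields[4],
                         "type": info.get("VT", "."),
                         "svlen": int(info["SVLEN"]) if "SVLEN" in info else None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AGP v2.1 (1-based, inclusive)
# ---------------------------------------------------------------------------

@dataclass
class AgpRow:
    object: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str          # 'W' component, 'U'/'N' gap
    component_id: str            # or gap length for gaps
    component_beg: int | str
    component_end: int | str
    orientation: str = "+"       # or gap_type fields for gaps


def write_agp(path: str | Path, rows: Iterable[AgpRow],
              seed: int | None = None, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in [
                r.object, r.object_beg, r.object_end, r.part_number,
                r.component_type, r.component_id, r.component_beg,
                r.component_end, r.orientation]) + "\n")


def read_agp(path: str | Path) -> list[AgpRow]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: fewer than 9 AGP columns")
            beg: int | str
            end: int | str
            if f[4] in ("N", "U"):
                beg, end = f[6], f[7]
            else:
                beg, end = int(f[6]), int(f[7])
            rows.append(AgpRow(f[0], int(f[1]), int(f[2]), int(f[3]),
                               f[4], f[5], beg, end, f[8]))
    return rows


# ---------------------------------------------------------------------------
# TSV tables (pandas, '#' comment headers)
# ---------------------------------------------------------------------------

def write_tsv(path: str | Path, df: pd.DataFrame,
              seed: int | None = None, config_hash: str | None = None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval [start, end]."""
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return end - start + 1
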