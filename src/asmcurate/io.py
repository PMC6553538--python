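"""Readers/writers for FASTA, PAF, VCF, BED and GFF3 with one coordinate convention.

Everything inside the package uses 0-based half-open coordinates.  The two
places 1-based inclusive coordinates appear are the VCF ``POS`` column and
human-facing ``Chr:start-end`` region strings; conversions happen only here,
at the I/O boundary.  PAF negative-strand records follow the minimap2
dialect: query coordinates are reported on the original (forward) query
strand regardless of the alignment strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

_VALID_BASES = frozenset("ACGTN")

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    name: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class AlignmentRecord:
    """One pairwise local alignment in PAF semantics.

    Coordinates are 0-based half-open on both query and target; for strand
    "-" the query interval is given on the original query strand.  ``tags``
    holds optional SAM-style PAF tags (notably ``cg`` with a CIGAR string
    over M/I/D, I = query-only bases).
    """

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int = 60
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r}")
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(
                f"invalid query interval {self.qstart}-{self.qend} (qlen {self.qlen})"
            )
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(
                f"invalid target interval {self.tstart}-{self.tend} (tlen {self.tlen})"
            )
        if self.nmatch > self.blocklen:
            raise ValueError("nmatch exceeds block length")


@dataclass
class VariantRecord:
    """A small variant with per-sample genotype calls.

    ``pos`` is 1-based (VCF convention); genotypes are normalized to one of
    ``hom-ref``, ``het``, ``hom-alt`` or ``missing``.  Multi-allelic VCF
    lines are split into one record per ALT by the reader.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: list[str]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref == alt")


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, with an optional class label."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_from_1based(chrom: str, start1: int, end1: int, label: str | None = None) -> Interval:
    """Build an Interval from 1-based inclusive coordinates (e.g. Chr2:172,624,657-172,626,416)."""
    return Interval(chrom, start1 - 1, end1, label)


def region_string(iv: Interval) -> str:
    """1-based inclusive ``chrom:start-end`` display string."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


def parse_region_string(s: str) -> Interval:
    m = re.fullmatch(r"(.+):([\d,]+)-([\d,]+)", s)
    if m is None:
        raise ValueError(f"malformed region string {s!r}")
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    return interval_from_1based(m.group(1), start1, end1)


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; case-fold to uppercase and reject non-ACGTN characters."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seen.add(rec.id)
        bases = str(rec.seq).upper()
        if not bases:
            raise ValueError(f"empty sequence {rec.id!r}")
        bad = set(bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"invalid character {sorted(bad)[0]!r} in sequence {rec.id!r}"
            )
        records.append(SequenceRecord(rec.id, bases))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")


# --------------------------------------------------------------------------
# PAF
# --------------------------------------------------------------------------


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Read PAF (>=12 tab-separated columns); optional tags are preserved."""
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"PAF line {lineno}: {len(cols)} columns (< 12)")
            tags = {}
            for tag in cols[12:]:
                key, typ, val = tag.split(":", 2)
                tags[key] = int(val) if typ == "i" else (float(val) if typ == "f" else val)
            out.append(
                AlignmentRecord(
                    qname=cols[0],
                    qlen=int(cols[1]),
                    qstart=int(cols[2]),
                    qend=int(cols[3]),
                    strand=cols[4],
                    tname=cols[5],
                    tlen=int(cols[6]),
                    tstart=int(cols[7]),
                    tend=int(cols[8]),
                    nmatch=int(cols[9]),
                    blocklen=int(cols[10]),
                    mapq=int(cols[11]),
                    tags=tags,
                )
            )
    return out


def _tag_str(key: str, val) -> str:
    if isinstance(val, int):
        return f"{key}:i:{val}"
    if isinstance(val, float):
        return f"{key}:f:{val}"
    return f"{key}:Z:{val}"


def write_paf(alignments: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            cols = [
                a.qname, str(a.qlen), str(a.qstart), str(a.qend), a.strand,
                a.tname, str(a.tlen), str(a.tstart), str(a.tend),
                str(a.nmatch), str(a.blocklen), str(a.mapq),
            ]
            cols.extend(_tag_str(k, v) for k, v in sorted(a.tags.items()))
            fh.write("\t".join(cols) + "\n")


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

_GT_NAMES = {0: "hom-ref", 1: "het", 2: "hom-alt"}


def read_vcf_multisample(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample VCF; returns (records, sample names).

    Only GT is parsed.  Multi-allelic lines are split into one record per
    ALT; a sample's genotype is classified relative to that ALT by counting
    how many of its called alleles equal the ALT index (2 -> hom-alt,
    1 -> het, 0 -> hom-ref; any uncalled allele -> missing).
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if "GT" not in vf.header.formats:
            raise ValueError("VCF has no GT FORMAT field")
        for rec in vf:
            if rec.alts is None:
                continue
            gts = []
            for s in samples:
                if "GT" not in rec.samples[s]:
                    raise ValueError(f"missing GT at {rec.chrom}:{rec.pos}")
                gts.append(rec.samples[s]["GT"])
            for ai, alt in enumerate(rec.alts, start=1):
                genos = []
                for gt in gts:
                    if gt is None or any(a is None for a in gt):
                        genos.append("missing")
                    else:
                        genos.append(_GT_NAMES[sum(1 for a in gt if a == ai)])
                out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt, genos))
    return out, samples


_GT_FIELD = {"hom-ref": "0/0", "het": "0/1", "hom-alt": "1/1", "missing": "./."}


def write_vcf(
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: dict[str, int] | None = None,
    extra_header: Sequence[str] = (),
) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt)):
            gt = "\t".join(_GT_FIELD[g] for g in v.genotypes)
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n")


# --------------------------------------------------------------------------
# BED / GFF3
# --------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6; column 4 (name), when present, becomes the label."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            label = cols[3] if len(cols) >= 4 else None
            out.append(Interval(cols[0], int(cols[1]), int(cols[2]), label))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_gff_intervals(path: str | Path, feature: str = "gene") -> list[Interval]:
    """Extract intervals of one feature type from GFF3 (gene-overlap use only).

    The label is taken from the ``Name`` or ``ID`` attribute.  GFF is
    1-based inclusive; output is converted to 0-based half-open.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            label = attrs.get("Name", attrs.get("ID"))
            out.append(Interval(cols[0], int(cols[3]) - 1, int(cols[4]), label))
    return out
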