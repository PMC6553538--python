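"""Consensus calling between two structural-variant callsets and summaries.

Merging follows the common integration convention (as in SURVIVOR): two
calls merge when their SV class matches and both breakpoints lie within a
maximum distance (1,000 bp by default, inclusive).  Matching is greedy
1-to-1 in ascending breakpoint distance with a deterministic tie-break, and
the consensus record takes the mean breakpoints and lists its supporting
callers.  The summary reports per-class counts, lower-median sizes and the
number of consensus calls overlapping at least one gene interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam

from .io import Interval

SV_CLASSES = ("DEL", "DUP", "INV", "INS", "TRA")


@dataclass
class SVRecord:
    """One SV call; 0-based half-open.  For INS, ``end == start`` and
    ``size`` is the inserted length; for TRA, ``chrom2/end`` hold the
    second breakend locus."""

    chrom: str
    start: int
    end: int
    svtype: str
    size: int
    caller: str = ""
    chrom2: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_CLASSES:
            raise ValueError(f"unknown SV class {self.svtype!r}")
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.svtype not in ("INS", "TRA") and self.size != self.end - self.start:
            raise ValueError("size must equal end - start for DEL/DUP/INV")


@dataclass
class ConsensusSV:
    chrom: str
    start: int
    end: int
    svtype: str
    size: int
    callers: list[str] = field(default_factory=list)
    members: tuple[SVRecord, ...] = ()

    @property
    def support(self) -> int:
        return len(self.callers)


def _compatible(a: SVRecord, b: SVRecord, max_dist: int, require_type: bool) -> bool:
    if require_type and a.svtype != b.svtype:
        return False
    if a.chrom != b.chrom:
        return False
    if a.svtype == "TRA" or b.svtype == "TRA":
        if a.chrom2 != b.chrom2:
            return False
    return abs(a.start - b.start) <= max_dist and abs(a.end - b.end) <= max_dist


def _distance(a: SVRecord, b: SVRecord) -> int:
    return max(abs(a.start - b.start), abs(a.end - b.end))


def merge_callsets(
    set_a: list[SVRecord],
    set_b: list[SVRecord],
    max_breakpoint_dist: int = 1000,
    require_type_match: bool = True,
) -> list[ConsensusSV]:
    """Greedy 1-to-1 merge; returns support-2 consensus records only.

    Pairs are considered in ascending breakpoint distance (the larger of
    the two per-breakpoint offsets), ties broken by (chrom, start, caller
    tag) so the output is deterministic.
    """
    pairs = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if _compatible(a, b, max_breakpoint_dist, require_type_match):
                pairs.append((_distance(a, b), a.chrom, a.start, a.caller, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[ConsensusSV] = []
    for _, _, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = set_a[i], set_b[j]
        start = (a.start + b.start) // 2
        end = (a.end + b.end) // 2
        size = (a.size + b.size) // 2 if a.svtype == "INS" else max(end - start, 1)
        if a.svtype == "INS":
            end = start
        out.append(ConsensusSV(a.chrom, start, end, a.svtype, size,
                               [a.caller, b.caller], (a, b)))
    out.sort(key=lambda c: (c.chrom, c.start, c.svtype))
    return out


def _lower_median(values: list[int]) -> int | None:
    if not values:
        return None
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def summarize_sv(
    consensus: list[ConsensusSV] | list[SVRecord],
    genes: list[Interval] | None = None,
) -> dict:
    """Per-class counts, lower-median sizes (NA for empty classes) and the
    count of records overlapping >= 1 gene interval (any overlap >= 1 bp)."""
    by_class: dict[str, list] = {c: [] for c in SV_CLASSES}
    for rec in consensus:
        by_class[rec.svtype].append(rec)
    report: dict = {}
    for cls in SV_CLASSES:
        recs = by_class[cls]
        sizes = [r.size for r in recs]
        gene_hits = 0
        if genes:
            for r in recs:
                iv = Interval(r.chrom, r.start, max(r.end, r.start + 1))
                if any(iv.overlaps(g) for g in genes):
                    gene_hits += 1
        report[cls] = {
            "count": len(recs),
            "median_size": _lower_median(sizes),
            "gene_overlap": gene_hits if genes else None,
        }
    return report


# --------------------------------------------------------------------------
# I/O: SV VCF (SVTYPE/END/SVLEN) and 6-column TSV
# --------------------------------------------------------------------------


def read_sv_vcf(path: str, caller: str = "") -> list[SVRecord]:
    out: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            end = rec.stop  # pysam resolves INFO/END
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            start = rec.pos - 1
            if svtype == "INS":
                size = abs(int(svlen)) if svlen is not None else 1
                out.append(SVRecord(rec.chrom, start, start, "INS", size, caller))
            else:
                size = end - start
                out.append(SVRecord(rec.chrom, start, end, svtype, size, caller))
    return out


def read_sv_tsv(path: str, caller: str = "") -> list[SVRecord]:
    """chrom, start, end, svtype, size, caller (caller column optional)."""
    out: list[SVRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            out.append(SVRecord(
                cols[0], int(cols[1]), int(cols[2]), cols[3], int(cols[4]),
                cols[5] if len(cols) > 5 else caller,
            ))
    return out


def write_sv_tsv(records, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsvtype\tsize\tcaller\n")
        for r in records:
            caller = getattr(r, "caller", None) or ",".join(getattr(r, "callers", []))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.svtype}\t{r.size}\t{caller}\n")
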