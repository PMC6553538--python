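"""Recurring-variant selection and resolution against a new assembly.

A *recurring* variant is one called at the same site across a large
fraction (>= 75% by default) of independently sequenced strains of one
inbred line — a signature of an error in the shared reference rather than
of biology.  Such a variant is *resolved* when the ALT allele matches the
allele the new assembly carries at the lifted position: the new assembly
agrees with the strains against the old reference.  Also includes the
CDS-indel frameshift classification used when evaluating transcript
placements on an assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import percent, revcomp
from .io import Interval, SequenceRecord, VariantRecord
from .liftover import ChainSet, map_position


@dataclass
class RecurringVariant:
    variant: VariantRecord
    recurrence: float          # hom-alt fraction among non-missing samples
    homozygous_in_all: bool    # no het calls among non-missing samples


@dataclass
class ResolutionCall:
    variant: VariantRecord
    status: str                         # resolved | unresolved | unmappable
    lifted_chrom: str | None = None
    lifted_pos: int | None = None
    strand: str | None = None
    assembly_allele: str | None = None
    reason: str | None = None


# --------------------------------------------------------------------------
# selection
# --------------------------------------------------------------------------


def select_recurring(
    variants: list[VariantRecord],
    min_frac: float = 0.75,
    homozygous_only: bool = True,
) -> list[RecurringVariant]:
    """Keep sites whose hom-alt fraction among non-missing samples reaches
    ``min_frac`` (inclusive); with ``homozygous_only``, any het call among
    the non-missing samples excludes the site."""
    out: list[RecurringVariant] = []
    for v in variants:
        if not v.genotypes:
            raise ValueError("variant with zero samples")
        called = [g for g in v.genotypes if g != "missing"]
        if not called:
            continue
        hom_alt = sum(1 for g in called if g == "hom-alt")
        het = sum(1 for g in called if g == "het")
        frac = hom_alt / len(called)
        if frac < min_frac:
            continue
        if homozygous_only and het > 0:
            continue
        out.append(RecurringVariant(v, frac, het == 0))
    return out


# --------------------------------------------------------------------------
# resolution
# --------------------------------------------------------------------------


def classify_resolved(
    variants: list[RecurringVariant] | list[VariantRecord],
    chainset: ChainSet,
    new_assembly: list[SequenceRecord],
) -> list[ResolutionCall]:
    """Lift each variant onto the new assembly and compare alleles.

    SNVs: lift the position, fetch one base, reverse-complement the ALT on
    "-" chains, compare.  Indels (experimental): lift the flanking anchor
    bases and compare the spanned assembly sequence to the ALT haplotype.
    Unliftable sites are ``unmappable`` with a reason, never an error.
    """
    seqs = {r.name: r.bases for r in new_assembly}
    out: list[ResolutionCall] = []
    for rv in variants:
        v = rv.variant if isinstance(rv, RecurringVariant) else rv
        if len(v.ref) == 1 and len(v.alt) == 1:
            out.append(_classify_snv(v, chainset, seqs))
        else:
            out.append(_classify_indel(v, chainset, seqs))
    return out


def _classify_snv(
    v: VariantRecord, chainset: ChainSet, seqs: dict[str, str]
) -> ResolutionCall:
    try:
        m = map_position(chainset, v.chrom, v.pos - 1)
    except (KeyError, ValueError) as exc:
        return ResolutionCall(v, "unmappable", reason=str(exc))
    if not m.mapped:
        return ResolutionCall(v, "unmappable", reason=m.reason)
    seq = seqs.get(m.chrom)
    if seq is None or not (0 <= m.pos < len(seq)):
        return ResolutionCall(v, "unmappable", reason="outside assembly")
    allele = seq[m.pos]
    want = v.alt if m.strand == "+" else revcomp(v.alt)
    status = "resolved" if allele == want else "unresolved"
    return ResolutionCall(v, status, m.chrom, m.pos, m.strand, allele)


def _classify_indel(
    v: VariantRecord, chainset: ChainSet, seqs: dict[str, str]
) -> ResolutionCall:
    left_anchor = v.pos - 1 - 1          # 0-based base before the REF allele
    right_anchor = v.pos - 1 + len(v.ref)  # 0-based base after the REF allele
    try:
        a = map_position(chainset, v.chrom, left_anchor)
        b = map_position(chainset, v.chrom, right_anchor)
    except (KeyError, ValueError) as exc:
        return ResolutionCall(v, "unmappable", reason=str(exc))
    if not a.mapped or not b.mapped:
        return ResolutionCall(
            v, "unmappable",
            reason=(a.reason if not a.mapped else b.reason))
    if a.chain is not b.chain:
        return ResolutionCall(v, "unmappable", reason="anchors split")
    seq = seqs[a.chrom]
    if a.strand == "+":
        spanned = seq[a.pos + 1 : b.pos]
        want = v.alt[1:] if v.alt.startswith(v.ref[0]) else v.alt
    else:
        spanned = revcomp(seq[b.pos + 1 : a.pos])
        want = v.alt[1:] if v.alt.startswith(v.ref[0]) else v.alt
    status = "resolved" if spanned == want else "unresolved"
    return ResolutionCall(v, status, a.chrom, a.pos, a.strand, spanned)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def summarize_resolution(
    calls: list[ResolutionCall],
    total_considered: int | None = None,
    denominator: str = "all",
) -> dict:
    """Counts and the resolved percentage (half-up, one decimal).

    ``denominator="all"`` divides by ``total_considered`` (default: the
    number of calls); ``"net"`` divides by the remappable calls only.
    """
    counts = {"resolved": 0, "unresolved": 0, "unmappable": 0}
    for c in calls:
        counts[c.status] += 1
    assert sum(counts.values()) == len(calls)
    if total_considered is None:
        total_considered = len(calls)
    if denominator == "net":
        denom = counts["resolved"] + counts["unresolved"]
    elif denominator == "all":
        denom = total_considered
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return {
        **counts,
        "total": total_considered,
        "denominator": denom,
        "resolved_pct": percent(counts["resolved"], denom),
    }


# --------------------------------------------------------------------------
# CDS indel frameshift classification
# --------------------------------------------------------------------------


@dataclass
class TranscriptPlacement:
    """One transcript alignment: its CDS intervals and alignment gaps.

    ``gaps`` is a list of (location, length) pairs; the location is a
    genomic interval (a point interval for insertions) and the length the
    number of inserted/deleted bases.
    """

    name: str
    cds: list[Interval]
    gaps: list[tuple[Interval, int]] = field(default_factory=list)


def classify_placement(placement: TranscriptPlacement) -> str:
    """"FS" if any CDS-overlapping gap has length % 3 != 0 (a single
    frameshifting gap dominates), "NFS" if CDS gaps exist but all are
    in-frame, "none" if no gap touches the CDS."""
    cds_gaps = [
        length
        for loc, length in placement.gaps
        if any(loc.overlaps(c) for c in placement.cds)
    ]
    if not cds_gaps:
        return "none"
    if any(length % 3 != 0 for length in cds_gaps):
        return "FS"
    return "NFS"


def classify_cds_indels(
    placements: list[TranscriptPlacement],
) -> tuple[int, int]:
    """(frameshifting, non-frameshifting) placement counts."""
    fs = nfs = 0
    for p in placements:
        status = classify_placement(p)
        if status == "FS":
            fs += 1
        elif status == "NFS":
            nfs += 1
    return fs, nfs
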