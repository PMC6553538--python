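"""Reference gap-fill discovery: detect N-run gaps, pad with flanks, filter
candidate assembly scaffolds, reciprocally confirm, and extract the fill
sequence with its size discrepancy.

The procedure mirrors same-species assembly curation practice: each gap is
padded with flanking sequence (50 kb at genome scale, 5 kb at desk scale);
assembly scaffolds are aligned to the padded regions; a (region, scaffold)
pair survives filtering if (a) it is a reciprocal best hit by total aligned
bases, (b) the total aligned bases reach a minimum (80 kb genome scale /
8 kb desk scale), and (c) the scaffold places uniquely in whole-assembly
alignments.  The reciprocal alignment (padded region against the scaffold)
must then show the mirror-image insertion/deletion pattern around the gap,
and the fill sequence is read out of the scaffold between the inner ends of
the two flank alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._util import revcomp
from .align import align_all
from .io import AlignmentRecord, Interval, SequenceRecord, region_string
from .liftover import ChainSet, build_chains, query_chain_coverage

_N_RUN = re.compile("N+")


@dataclass
class GapRecord:
    """A maximal N-run in a reference chromosome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    padded: Interval | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def region(self) -> str:
        """1-based inclusive display string, e.g. chr2:172624657-172626416."""
        return region_string(self.interval)


@dataclass
class FillCandidate:
    gap: GapRecord
    scaffold: str | None = None
    strand: str | None = None
    total_aln: int = 0
    fill: str | None = None
    discrepancy: int | None = None
    confirmed: bool = False
    reason: str | None = None
    flank_alignments: tuple[AlignmentRecord, AlignmentRecord] | None = field(
        default=None, repr=False
    )


# --------------------------------------------------------------------------
# gap detection and padding
# --------------------------------------------------------------------------


def find_gaps(
    reference: list[SequenceRecord],
    min_gap_len: int = 10,
    exclude: list[Interval] | None = None,
) -> list[GapRecord]:
    """Maximal N-runs >= min_gap_len, minus any overlapping exclude mask
    (e.g. centromere/telomere intervals)."""
    out: list[GapRecord] = []
    for rec in reference:
        for m in _N_RUN.finditer(rec.bases):
            if m.end() - m.start() < min_gap_len:
                continue
            gap = GapRecord(rec.name, m.start(), m.end())
            if exclude and any(gap.interval.overlaps(iv) for iv in exclude):
                continue
            out.append(gap)
    return out


def pad_gaps(
    gaps: list[GapRecord],
    flank: int = 50_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[Interval]:
    """Pad each gap with ``flank`` bp both sides, clipped to chromosome
    bounds; the padded interval is also stored on the GapRecord."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    out: list[Interval] = []
    for gap in gaps:
        start = max(0, gap.start - flank)
        end = gap.end + flank
        if chrom_lengths is not None:
            end = min(end, chrom_lengths[gap.chrom])
        gap.padded = Interval(gap.chrom, start, end)
        out.append(gap.padded)
    return out


def extract_padded_regions(
    reference: list[SequenceRecord], gaps: list[GapRecord]
) -> list[SequenceRecord]:
    """Cut the padded regions out of the reference; the record name is the
    1-based region string of the padded interval."""
    seqs = {r.name: r.bases for r in reference}
    out = []
    for gap in gaps:
        if gap.padded is None:
            raise ValueError("gaps must be padded first")
        iv = gap.padded
        out.append(SequenceRecord(region_string(iv), seqs[iv.chrom][iv.start:iv.end]))
    return out


# --------------------------------------------------------------------------
# candidate filtering
# --------------------------------------------------------------------------


def scaffold_uniqueness(
    whole_chainset: ChainSet, min_frac: float = 0.9
) -> dict[str, bool]:
    """Criterion (c): a scaffold is "unique" when >= min_frac of its netted
    aligned bases fall in a single chain locus of the whole-assembly net."""
    out: dict[str, bool] = {}
    for qname, per_chain in query_chain_coverage(whole_chainset).items():
        total = sum(per_chain.values())
        out[qname] = total > 0 and max(per_chain.values()) / total >= min_frac
    return out


def _pair_totals(alignments: list[AlignmentRecord]) -> dict[tuple[str, str], int]:
    """Sum of aligned (matching) bases per (query, target) pair."""
    totals: dict[tuple[str, str], int] = {}
    for a in alignments:
        key = (a.qname, a.tname)
        totals[key] = totals.get(key, 0) + a.nmatch
    return totals


def _pair_counts(alignments: list[AlignmentRecord]) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for a in alignments:
        key = (a.qname, a.tname)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _best_partner(
    totals: dict[tuple[str, str], int],
    counts: dict[tuple[str, str], int],
    by_query: bool,
) -> dict[str, str]:
    """Best-hit map; ties broken toward fewer alignments (more contiguous),
    then lexicographic partner name."""
    best: dict[str, tuple] = {}
    for (q, t), total in totals.items():
        me, partner = (q, t) if by_query else (t, q)
        key = (-total, counts[(q, t)], partner)
        if me not in best or key < best[me]:
            best[me] = key
    return {me: key[2] for me, key in best.items()}


def filter_candidates(
    gaps: list[GapRecord],
    region_alignments: list[AlignmentRecord],
    min_total_aln: int = 80_000,
    uniqueness: dict[str, bool] | None = None,
) -> list[FillCandidate]:
    """Apply criteria (a) reciprocal best hit, (b) total aligned bases >=
    min_total_aln (inclusive), (c) unique whole-assembly placement.

    ``region_alignments`` are scaffold-vs-padded-region alignments (query =
    scaffold, target = padded region string).  Gaps with no surviving pair
    are returned with a reason, not dropped.
    """
    totals = _pair_totals(region_alignments)
    counts = _pair_counts(region_alignments)
    best_of_scaffold = _best_partner(totals, counts, by_query=True)
    best_of_region = _best_partner(totals, counts, by_query=False)
    out: list[FillCandidate] = []
    for gap in gaps:
        region = region_string(gap.padded) if gap.padded else None
        cand = FillCandidate(gap)
        if region is None or region not in best_of_region:
            cand.reason = "no candidate"
            out.append(cand)
            continue
        scaffold = best_of_region[region]
        total = totals[(scaffold, region)]
        if best_of_scaffold.get(scaffold) != region:
            cand.reason = "not reciprocal best hit"
        elif total < min_total_aln:
            cand.reason = f"total alignment {total} < {min_total_aln}"
        elif uniqueness is not None and not uniqueness.get(scaffold, False):
            cand.reason = "scaffold placement not unique"
        else:
            cand.scaffold = scaffold
            cand.total_aln = total
        out.append(cand)
    return out


# --------------------------------------------------------------------------
# reciprocal confirmation and fill extraction
# --------------------------------------------------------------------------


def _flank_pair(
    alignments: list[AlignmentRecord],
    gap_qstart: int,
    gap_qend: int,
    slack: int = 50,
) -> tuple[AlignmentRecord, AlignmentRecord] | None:
    """Pick the left/right flank alignment pair around a query-side gap.

    Returns (left, right) in *query* order, same strand and target
    co-linear, maximizing summed matches; None if no valid pair exists.
    """
    best = None
    for strand in ("+", "-"):
        lefts = [a for a in alignments
                 if a.strand == strand and a.qend <= gap_qstart + slack]
        rights = [a for a in alignments
                  if a.strand == strand and a.qstart >= gap_qend - slack]
        for left in lefts:
            for right in rights:
                first, second = (left, right) if strand == "+" else (right, left)
                if first.tend > second.tstart:  # not co-linear on target
                    continue
                score = left.nmatch + right.nmatch
                if best is None or score > best[0]:
                    best = (score, left, right)
    if best is None:
        return None
    return best[1], best[2]


def _between_spans(
    left: AlignmentRecord,
    right: AlignmentRecord,
    gap_qstart: int,
    gap_qend: int,
) -> tuple[int, int]:
    """(query span, target span) between the inner flank ends, where the
    query span is anchored on the gap edges."""
    strand = left.strand
    if strand == "+":
        q_between = right.qstart - left.qend
        t_between = right.tstart - left.tend
    else:
        q_between = right.qstart - left.qend
        t_between = left.tstart - right.tend
    return q_between, t_between


def confirm_and_extract(
    candidate: FillCandidate,
    forward_alignments: list[AlignmentRecord],
    reciprocal_alignments: list[AlignmentRecord],
    assembly: dict[str, str],
    tolerance: int = 10,
) -> FillCandidate:
    """Confirm a filtered candidate and extract its fill sequence.

    ``forward_alignments``: padded region as query vs scaffold as target
    (the direction in which the fill is read out of the scaffold);
    ``reciprocal_alignments``: scaffold as query vs padded region as target.
    Confirmation requires the signed inter-flank length difference in one
    direction to equal the negation of the other within ``tolerance``.
    """
    gap, scaffold = candidate.gap, candidate.scaffold
    if scaffold is None:
        return candidate
    region = region_string(gap.padded)
    gap_r_start = gap.start - gap.padded.start  # gap coords within the region
    gap_r_end = gap.end - gap.padded.start

    fwd = [a for a in forward_alignments
           if a.qname == region and a.tname == scaffold]
    pair = _flank_pair(fwd, gap_r_start, gap_r_end)
    if pair is None:
        candidate.reason = "flank alignments discordant"
        return candidate
    left, right = pair
    candidate.strand = left.strand
    candidate.flank_alignments = (left, right)

    # fill sequence between the inner flank ends, clipped to supported bounds
    seq = assembly[scaffold]
    if left.strand == "+":
        adj_l = gap_r_start - left.qend
        adj_r = right.qstart - gap_r_end
        fill_start = left.tend + adj_l
        fill_end = right.tstart - adj_r
        fill = seq[max(0, fill_start) : max(0, fill_end)] if fill_end > fill_start else ""
    else:
        adj_r = right.qstart - gap_r_end  # right flank sits first on the target
        adj_l = gap_r_start - left.qend
        fill_start = right.tend + adj_r
        fill_end = left.tstart - adj_l
        fwd_piece = seq[max(0, fill_start) : max(0, fill_end)] if fill_end > fill_start else ""
        fill = revcomp(fwd_piece)
    candidate.fill = fill
    candidate.discrepancy = len(fill) - gap.length

    # inter-flank length differences must mirror between the two directions
    q_fwd, t_fwd = _between_spans(left, right, gap_r_start, gap_r_end)
    diff_fwd = t_fwd - q_fwd  # fill length - gap length

    rec = [a for a in reciprocal_alignments
           if a.qname == scaffold and a.tname == region]
    rpair = _flank_pair_target_gap(rec, gap_r_start, gap_r_end)
    if rpair is None:
        candidate.reason = "no reciprocal flank pair"
        return candidate
    rleft, rright = rpair
    q_rec, t_rec = _between_spans(rleft, rright, gap_r_start, gap_r_end)
    diff_rec = t_rec - q_rec  # gap length - fill length
    if abs(diff_fwd + diff_rec) <= tolerance:
        candidate.confirmed = True
    else:
        candidate.reason = (
            f"discrepancy not mirrored ({diff_fwd:+d} vs {diff_rec:+d})"
        )
    return candidate


def _flank_pair_target_gap(
    alignments: list[AlignmentRecord],
    gap_tstart: int,
    gap_tend: int,
    slack: int = 50,
) -> tuple[AlignmentRecord, AlignmentRecord] | None:
    """Flank pair when the gap lies on the *target* side; returned in query
    order so that :func:`_between_spans` applies unchanged."""
    best = None
    for strand in ("+", "-"):
        firsts = [a for a in alignments
                  if a.strand == strand and a.tend <= gap_tstart + slack]
        seconds = [a for a in alignments
                   if a.strand == strand and a.tstart >= gap_tend - slack]
        for first in firsts:
            for second in seconds:
                left, right = (first, second) if strand == "+" else (second, first)
                if left.qend > right.qstart:
                    continue
                score = first.nmatch + second.nmatch
                if best is None or score > best[0]:
                    best = (score, left, right)
    if best is None:
        return None
    return best[1], best[2]


# --------------------------------------------------------------------------
# end-to-end driver
# --------------------------------------------------------------------------


def fill_gaps(
    reference: list[SequenceRecord],
    assembly: list[SequenceRecord],
    flank: int = 50_000,
    min_total_aln: int = 80_000,
    min_gap_len: int = 10,
    exclude: list[Interval] | None = None,
    k: int = 15,
    max_gap: int = 2000,
    min_chain_score: int = 100,
    whole_chainset: ChainSet | None = None,
    uniqueness_min_frac: float = 0.9,
    tolerance: int = 10,
) -> list[FillCandidate]:
    """Run the whole gap-fill procedure with the built-in micro-aligner.

    ``whole_chainset`` (assembly-vs-reference chains) may be passed in to
    reuse existing whole-genome alignments for the uniqueness criterion;
    otherwise it is computed here.
    """
    chrom_lengths = {r.name: len(r) for r in reference}
    gaps = find_gaps(reference, min_gap_len=min_gap_len, exclude=exclude)
    pad_gaps(gaps, flank=flank, chrom_lengths=chrom_lengths)
    if not gaps:
        return []
    regions = extract_padded_regions(reference, gaps)
    aln_kw = dict(k=k, max_gap=max_gap, min_chain_score=min_chain_score)
    s2r = align_all(assembly, regions, **aln_kw)   # scaffold query, region target
    r2s = align_all(regions, assembly, **aln_kw)   # region query, scaffold target
    if whole_chainset is None:
        whole_chainset = build_chains(align_all(assembly, reference, **aln_kw))
    uniq = scaffold_uniqueness(whole_chainset, min_frac=uniqueness_min_frac)
    candidates = filter_candidates(gaps, s2r, min_total_aln=min_total_aln,
                                   uniqueness=uniq)
    asm_seqs = {r.name: r.bases for r in assembly}
    return [
        confirm_and_extract(c, r2s, s2r, asm_seqs, tolerance=tolerance)
        for c in candidates
    ]
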