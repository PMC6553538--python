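"""Consensus unaligned regions and repeat-class composition / enrichment.

Scaffold sequence that several independent alignment methods all fail to
place on the reference is enriched for repeats — especially tandem repeat
classes whose copy number drifts rapidly between individuals.  This module
intersects >= 2 unaligned-interval sets into a consensus, tabulates
repeat-class composition of a region set against an annotation, and tests
per-class enrichment between two genomes with a 2x2 Pearson chi-square
(no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import chi2 as _chi2_dist

from ._util import percent
from .io import Interval


def _merge(intervals: list[Interval]) -> dict[str, list[tuple[int, int]]]:
    """Per-chrom sorted, merged (start, end) lists."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        merged = [rows[0]]
        for s, e in rows[1:]:
            if s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = merged
    return out


def _intersect_two(
    a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in set(a) & set(b):
        rows = []
        i = j = 0
        ra, rb = a[chrom], b[chrom]
        while i < len(ra) and j < len(rb):
            s = max(ra[i][0], rb[j][0])
            e = min(ra[i][1], rb[j][1])
            if s < e:
                rows.append((s, e))
            if ra[i][1] < rb[j][1]:
                i += 1
            else:
                j += 1
        if rows:
            out[chrom] = rows
    return out


def consensus_unaligned(
    sets: list[list[Interval]],
    sequence_names: set[str] | None = None,
) -> list[Interval]:
    """Per-base intersection of all interval sets, as maximal merged
    intervals.  With ``sequence_names`` given, any interval on an unknown
    sequence is an error."""
    if len(sets) < 2:
        raise ValueError("need at least 2 interval sets")
    if sequence_names is not None:
        for intervals in sets:
            for iv in intervals:
                if iv.chrom not in sequence_names:
                    raise ValueError(f"unknown sequence {iv.chrom!r}")
    acc = _merge(sets[0])
    for s in sets[1:]:
        acc = _intersect_two(acc, _merge(s))
    out = [
        Interval(chrom, s, e)
        for chrom, rows in sorted(acc.items())
        for s, e in rows
    ]
    return out


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------


@dataclass
class CompositionTable:
    region_bp: int
    class_bp: dict[str, int] = field(default_factory=dict)
    class_pct: dict[str, float] = field(default_factory=dict)

    @property
    def repeat_bp(self) -> int:
        return sum(self.class_bp.values())

    def repeat_pct(self, decimals: int = 1) -> float:
        return percent(self.repeat_bp, self.region_bp, decimals)


def repeat_composition(
    region: list[Interval],
    repeats: list[Interval],
    decimals: int = 2,
) -> CompositionTable:
    """Per-class repeat bp inside ``region`` and percentages of the region
    total (half-up at ``decimals``).

    Where repeat annotations of different classes overlap each other, the
    first-listed class after sorting by (start, class) claims the shared
    bases, so the per-class counts never double-count a position.
    """
    region_merged = _merge(region)
    total = sum(e - s for rows in region_merged.values() for s, e in rows)
    if total == 0:
        raise ValueError("zero-length region")
    class_bp: dict[str, int] = {}
    by_chrom: dict[str, list[Interval]] = {}
    for iv in repeats:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, anns in by_chrom.items():
        if chrom not in region_merged:
            continue
        anns.sort(key=lambda iv: (iv.start, iv.label or ""))
        claimed_to = 0  # earlier-listed annotation wins overlaps
        for iv in anns:
            s = max(iv.start, claimed_to)
            if s >= iv.end:
                continue
            claimed_to = iv.end
            bp = _overlap_bp(s, iv.end, region_merged[chrom])
            if bp:
                label = iv.label or "unclassified"
                class_bp[label] = class_bp.get(label, 0) + bp
    table = CompositionTable(region_bp=total, class_bp=class_bp)
    for label, bp in sorted(class_bp.items()):
        table.class_pct[label] = percent(bp, total, decimals)
    return table


def _overlap_bp(start: int, end: int, rows: list[tuple[int, int]]) -> int:
    bp = 0
    for s, e in rows:
        lo, hi = max(start, s), min(end, e)
        if lo < hi:
            bp += hi - lo
    return bp


# --------------------------------------------------------------------------
# enrichment
# --------------------------------------------------------------------------


def class_enrichment(
    class_bp_a: int, total_a: int, class_bp_b: int, total_b: int
) -> tuple[float, float, bool]:
    """Pearson chi-square on [[in_a, out_a], [in_b, out_b]], 1 df, no
    continuity correction; returns (chi2, p, reliable).

    ``reliable`` is False when any expected cell is < 5 (the asymptotic
    test is then questionable); this is a flag, not an error.
    """
    if min(class_bp_a, class_bp_b) < 0 or min(total_a, total_b) <= 0:
        raise ValueError("counts must be nonnegative with positive totals")
    obs = [
        [class_bp_a, total_a - class_bp_a],
        [class_bp_b, total_b - class_bp_b],
    ]
    n = total_a + total_b
    col = [obs[0][0] + obs[1][0], obs[0][1] + obs[1][1]]
    row = [total_a, total_b]
    stat = 0.0
    reliable = True
    for i in range(2):
        for j in range(2):
            expected = row[i] * col[j] / n
            if expected < 5:
                reliable = False
            if expected > 0:
                stat += (obs[i][j] - expected) ** 2 / expected
    p = float(_chi2_dist.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p, reliable
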