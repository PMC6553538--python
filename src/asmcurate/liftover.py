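r"""Chain/net construction from pairwise alignments and coordinate liftover.

A *chain* is an ordered set of gap-free alignment blocks between a query
assembly and a target assembly, strictly monotone on both genomes (query
descending as target ascends for "-" chains).  *Netting* assigns each
target base to at most one chain, greedily in descending chain score
(score = aligned bases), truncating lower-scoring chains to the remaining
unowned target space.  Coordinate mapping then walks the net: a position
inside an owned block maps by linear offset (reflectively on "-" chains);
a position falling between the blocks of its owning chain is reported as
``deleted`` (the query lacks those bases); anywhere else is ``unaligned``.

On "-" chains a single base maps to the coordinate of the aligned base
itself.  E.g. a full-length reverse chain over a 1 kb sequence sends
target position 0 to query position 999::

    target  0 1 2 ... 999
             \ ... X ... /     (reverse complement)
    query  999 ...    ... 0
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass, field

from .io import AlignmentRecord, Interval


@dataclass
class ChainBlock:
    """One gap-free block; query coords are on the original query strand."""

    tstart: int
    tend: int
    qstart: int
    qend: int

    def __post_init__(self) -> None:
        if self.tend - self.tstart != self.qend - self.qstart:
            raise ValueError("chain block is not gap-free")


@dataclass
class Chain:
    """Ordered gap-free blocks between one query and one target sequence."""

    qname: str
    qlen: int
    tname: str
    tlen: int
    strand: str
    blocks: list[ChainBlock]
    chain_id: int = 0

    @property
    def score(self) -> int:
        return sum(b.tend - b.tstart for b in self.blocks)

    @property
    def tstart(self) -> int:
        return self.blocks[0].tstart

    @property
    def tend(self) -> int:
        return self.blocks[-1].tend

    @property
    def span(self) -> int:
        return self.tend - self.tstart

    def map_in_block(self, block: ChainBlock, tpos: int) -> int:
        if self.strand == "+":
            return block.qstart + (tpos - block.tstart)
        return block.qend - 1 - (tpos - block.tstart)


@dataclass
class ChainSet:
    """Chains plus the net: per-target-base at most one owning chain."""

    chains: list[Chain] = field(default_factory=list)
    netted: list[Chain] = field(default_factory=list)
    tlens: dict[str, int] = field(default_factory=dict)
    qlens: dict[str, int] = field(default_factory=dict)
    # per-target sorted (tstart, tend, netted chain, block)
    _index: dict[str, list[tuple[int, int, Chain, ChainBlock]]] = field(
        default_factory=dict, repr=False
    )

    def _build_index(self) -> None:
        self._index = {}
        for chain in self.netted:
            rows = self._index.setdefault(chain.tname, [])
            for b in chain.blocks:
                rows.append((b.tstart, b.tend, chain, b))
        for rows in self._index.values():
            rows.sort(key=lambda r: r[0])


@dataclass
class PositionMapping:
    mapped: bool
    chrom: str | None = None
    pos: int | None = None
    strand: str | None = None
    reason: str | None = None  # "deleted" | "unaligned" when unmapped
    chain: Chain | None = None


@dataclass
class IntervalMapping:
    mapped: bool
    interval: Interval | None = None
    strand: str | None = None
    reason: str | None = None  # "deleted" | "unaligned" | "split" | "length"


# --------------------------------------------------------------------------
# chain construction
# --------------------------------------------------------------------------

_CIGAR_OPS = frozenset("MID")


def _parse_cigar(cg: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cg:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            ops.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"unsupported CIGAR op {ch!r}")
    if num:
        raise ValueError("trailing digits in CIGAR")
    return ops


def alignment_to_blocks(aln: AlignmentRecord) -> list[ChainBlock]:
    """Decompose a PAF record into gap-free blocks (target-sorted).

    Requires a ``cg`` CIGAR tag when the query and target spans differ.
    The CIGAR walks the target ascending; on "-" records the query walks
    from ``qend`` down to ``qstart`` on the original strand.
    """
    cg = aln.tags.get("cg")
    if cg is None:
        if aln.qend - aln.qstart != aln.tend - aln.tstart:
            raise ValueError("alignment with unequal spans needs a cg tag")
        return [ChainBlock(aln.tstart, aln.tend, aln.qstart, aln.qend)]
    blocks: list[ChainBlock] = []
    t = aln.tstart
    q = aln.qstart if aln.strand == "+" else aln.qend
    for op, ln in _parse_cigar(cg):
        if op == "M":
            if aln.strand == "+":
                blocks.append(ChainBlock(t, t + ln, q, q + ln))
                q += ln
            else:
                blocks.append(ChainBlock(t, t + ln, q - ln, q))
                q -= ln
            t += ln
        elif op == "I":
            q += ln if aln.strand == "+" else -ln
        else:  # D
            t += ln
    if t != aln.tend:
        raise ValueError("CIGAR does not span the target interval")
    return blocks


def _chain_q_extent(chain: Chain) -> tuple[int, int]:
    return min(b.qstart for b in chain.blocks), max(b.qend for b in chain.blocks)


def _merge_into(prev: Chain, cand: Chain) -> bool:
    """Append ``cand``'s blocks to ``prev`` if co-linear, trimming a leading
    overlap (alignment end extension can make otherwise co-linear records
    overlap slightly across anchor-free sequence).  Returns True on merge.
    """
    p_lo, p_hi = _chain_q_extent(prev)
    new_blocks: list[ChainBlock] = []
    for b in cand.blocks:
        ts, te, qs, qe = b.tstart, b.tend, b.qstart, b.qend
        cut = prev.tend - ts
        if cut > 0:  # trim target overlap
            if cut >= te - ts:
                continue
            ts += cut
            if prev.strand == "+":
                qs += cut
            else:
                qe -= cut
        # after the target-side trim any residual query overlap should be a
        # few bp of diagonal slippage; a large one means the candidate is a
        # second placement of the same query sequence, not a continuation
        cut = (p_hi - qs) if prev.strand == "+" else (qe - p_lo)
        if cut > 0:
            if cut > 50 or cut >= qe - qs:
                return False
            if prev.strand == "+":
                qs += cut
            else:
                qe -= cut
            ts += cut
        new_blocks.append(ChainBlock(ts, te, qs, qe))
    if not new_blocks:
        return True  # cand entirely redundant with prev
    # verify strict monotonicity of the extended chain
    merged = prev.blocks + new_blocks
    for a, b in zip(merged, merged[1:]):
        if b.tstart < a.tend:
            return False
        if prev.strand == "+" and b.qstart < a.qend:
            return False
        if prev.strand == "-" and b.qend > a.qstart:
            return False
    prev.blocks.extend(new_blocks)
    return True


def build_chains(alignments: list[AlignmentRecord], merge: bool = True) -> ChainSet:
    """Chain and net pairwise alignments.

    Co-linear alignments of one (query, target, strand) group are merged
    into single chains; the net is then a greedy assignment of target space
    in descending score, ties broken toward the longer target span, then
    lexicographic query name.
    """
    cs = ChainSet()
    if not alignments:
        return cs
    chains: list[Chain] = []
    keyfn = lambda a: (a.qname, a.tname, a.strand)
    for (qname, tname, strand), group in itertools.groupby(
        sorted(alignments, key=lambda a: (keyfn(a), a.tstart)), key=keyfn
    ):
        pending: list[Chain] = []
        for aln in group:
            cs.tlens[tname] = aln.tlen
            cs.qlens[qname] = aln.qlen
            cand = Chain(qname, aln.qlen, tname, aln.tlen, strand,
                         alignment_to_blocks(aln))
            merged = False
            if merge:
                for p in pending:
                    if _merge_into(p, cand):
                        merged = True
                        break
            if not merged:
                pending.append(cand)
        chains.extend(pending)
    for i, c in enumerate(chains):
        c.chain_id = i
    cs.chains = chains

    # netting: greedy target-space ownership in descending score
    owned: dict[str, list[tuple[int, int]]] = {}
    order = sorted(chains, key=lambda c: (-c.score, -c.span, c.qname, c.tname, c.tstart))
    for chain in order:
        taken = owned.setdefault(chain.tname, [])
        new_blocks: list[ChainBlock] = []
        for b in chain.blocks:
            for s, e in _subtract(b.tstart, b.tend, taken):
                if chain.strand == "+":
                    nb = ChainBlock(s, e, b.qstart + (s - b.tstart), b.qstart + (e - b.tstart))
                else:
                    nb = ChainBlock(s, e, b.qend - (e - b.tstart), b.qend - (s - b.tstart))
                new_blocks.append(nb)
        if not new_blocks:
            continue
        for nb in new_blocks:
            taken.append((nb.tstart, nb.tend))
        taken.sort()
        netted = Chain(chain.qname, chain.qlen, chain.tname, chain.tlen,
                       chain.strand, new_blocks, chain_id=chain.chain_id)
        cs.netted.append(netted)
    cs._build_index()
    return cs


def _subtract(start: int, end: int, taken: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of [start, end) not covered by the sorted interval list."""
    out: list[tuple[int, int]] = []
    cur = start
    for s, e in taken:
        if e <= cur:
            continue
        if s >= end:
            break
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
        if cur >= end:
            break
    if cur < end:
        out.append((cur, end))
    return out


# --------------------------------------------------------------------------
# mapping
# --------------------------------------------------------------------------


def map_position(chainset: ChainSet, chrom: str, pos: int) -> PositionMapping:
    """Map one target position through the net to query coordinates."""
    if chrom not in chainset.tlens:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not (0 <= pos < chainset.tlens[chrom]):
        raise ValueError(f"position {pos} outside {chrom}")
    rows = chainset._index.get(chrom, [])
    i = bisect_right(rows, pos, key=lambda r: r[0]) - 1
    if i >= 0:
        tstart, tend, chain, block = rows[i]
        if pos < tend:
            return PositionMapping(
                True, chain.qname, chain.map_in_block(block, pos),
                chain.strand, chain=chain,
            )
    # between netted blocks of some chain -> deleted in the query
    best: Chain | None = None
    for chain in chainset.netted:
        if chain.tname == chrom and chain.tstart <= pos < chain.tend:
            if best is None or chain.score > best.score:
                best = chain
    if best is not None:
        return PositionMapping(False, reason="deleted", chain=best)
    return PositionMapping(False, reason="unaligned")


def map_interval(
    chainset: ChainSet, iv: Interval, max_len_ratio: float = 2.0
) -> IntervalMapping:
    """Map an interval by its endpoints.

    Fails (``split``) if the endpoints land on different chains or strands,
    and (``length``) if the mapped length differs from the source length by
    more than ``max_len_ratio`` in either direction.
    """
    a = map_position(chainset, iv.chrom, iv.start)
    b = map_position(chainset, iv.chrom, iv.end - 1)
    if not a.mapped or not b.mapped:
        return IntervalMapping(False, reason=(a.reason if not a.mapped else b.reason))
    if a.chain is not b.chain:
        return IntervalMapping(False, reason="split")
    if a.strand == "+":
        start, end = a.pos, b.pos + 1
    else:
        start, end = b.pos, a.pos + 1
    if end <= start:
        return IntervalMapping(False, reason="split")
    ratio = (end - start) / len(iv)
    if ratio > max_len_ratio or ratio < 1.0 / max_len_ratio:
        return IntervalMapping(False, reason="length")
    return IntervalMapping(
        True, Interval(a.chrom, start, end, iv.label), a.strand
    )


def owned_intervals(chainset: ChainSet) -> dict[str, list[tuple[int, int, int]]]:
    """Per target sequence, sorted (start, end, chain_id) of net ownership."""
    out: dict[str, list[tuple[int, int, int]]] = {}
    for chain in chainset.netted:
        rows = out.setdefault(chain.tname, [])
        for b in chain.blocks:
            rows.append((b.tstart, b.tend, chain.chain_id))
    for rows in out.values():
        rows.sort()
    return out


def query_chain_coverage(chainset: ChainSet) -> dict[str, dict[int, int]]:
    """Per query sequence, netted-owned bp attributed to each chain."""
    out: dict[str, dict[int, int]] = {}
    for chain in chainset.netted:
        per = out.setdefault(chain.qname, {})
        per[chain.chain_id] = per.get(chain.chain_id, 0) + chain.score
    return out
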