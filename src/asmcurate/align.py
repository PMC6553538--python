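"""Minimal exact-k-mer seed-and-chain pairwise aligner emitting PAF records.

Designed for low-divergence same-species genome pairs at desk scale.  The
algorithm is:

1. anchor on k-mers that occur exactly once in the query against target
   occurrences of bounded multiplicity (k-mers containing N never anchor);
2. compress anchors into maximal exact-match segments (runs of anchors on
   one diagonal);
3. chain segments co-linearly with gap penalty ``|dq - dt|``; chains never
   cross an N-run on either sequence, so a gapped reference splits into
   per-contig alignments;
4. emit one PAF record per chain with a ``cg`` CIGAR (M/I/D; I = query-only
   bases) built by gap-free extension between segments, and ``nmatch`` =
   exactly matching bases over all M stretches.

There is no base-level affine-gap alignment between anchors: the bases
between two chained segments are compared gap-free, with any length
difference placed as a single indel at the segment boundary.  This is a
documented limitation, adequate for the low-divergence use case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import encode_seq, revcomp
from .io import AlignmentRecord, SequenceRecord

MIN_K = 11


@dataclass
class _Segment:
    """Maximal run of co-diagonal exact k-mer anchors: an exact match block."""

    qs: int
    ts: int
    length: int

    @property
    def qe(self) -> int:
        return self.qs + self.length

    @property
    def te(self) -> int:
        return self.ts + self.length


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes and a validity mask (False where any N)."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        window = arr[j : j + n]
        codes = codes * 4 + np.where(window == 4, 0, window).astype(np.int64)
        invalid |= window == 4
    return codes, ~invalid


class _SeqIndex:
    """Cached per-sequence data: encoding, N prefix sums, and all valid
    k-mers sorted by code with per-entry multiplicity."""

    def __init__(self, bases: str, k: int):
        self.arr = encode_seq(bases)
        self.ncum = np.concatenate(([0], np.cumsum(self.arr == 4)))
        codes, valid = _kmer_codes(self.arr, k)
        pos = np.flatnonzero(valid)
        c = codes[pos]
        order = np.argsort(c, kind="stable")
        self.codes = c[order]
        self.pos = pos[order]
        if len(self.codes):
            first = np.empty(len(self.codes), dtype=bool)
            first[0] = True
            first[1:] = self.codes[1:] != self.codes[:-1]
            starts = np.flatnonzero(first)
            counts = np.diff(np.append(starts, len(self.codes)))
            self.mult = np.repeat(counts, counts)
        else:
            self.mult = np.empty(0, dtype=np.int64)

    @property
    def unique_mask(self) -> np.ndarray:
        return self.mult == 1


def _anchors(
    qidx: _SeqIndex, tidx: _SeqIndex, max_occ: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor positions: k-mers unique in the query matched against target
    occurrences of multiplicity <= max_occ (so duplicated target loci still
    anchor, once per copy, while high-copy repeats never do)."""
    qmask = qidx.unique_mask
    qc, qp = qidx.codes[qmask], qidx.pos[qmask]
    tmask = tidx.mult <= max_occ
    tc, tp = tidx.codes[tmask], tidx.pos[tmask]
    if len(qc) == 0 or len(tc) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    left = np.searchsorted(tc, qc, side="left")
    right = np.searchsorted(tc, qc, side="right")
    counts = right - left
    hit = counts > 0
    qp, left, counts = qp[hit], left[hit], counts[hit]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    offsets = np.cumsum(counts) - counts
    t_idx = np.repeat(left, counts) + np.arange(total) - np.repeat(offsets, counts)
    return np.repeat(qp, counts), tp[t_idx]


def _segments(qpos: np.ndarray, tpos: np.ndarray, k: int) -> list[_Segment]:
    if len(qpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((qpos, diag))
    q, d = qpos[order], diag[order]
    t = tpos[order]
    breaks = np.flatnonzero((d[1:] != d[:-1]) | (q[1:] != q[:-1] + 1))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(q) - 1]))
    segs = [
        _Segment(int(q[a]), int(t[a]), int(q[b] - q[a]) + k)
        for a, b in zip(starts, ends)
    ]
    segs.sort(key=lambda s: (s.qs, s.ts))
    return segs


def _chain_segments(
    segs: list[_Segment],
    max_gap: int,
    q_ncum: np.ndarray,
    t_ncum: np.ndarray,
    lookback: int = 64,
) -> list[list[_Segment]]:
    """Co-linear chaining DP; returns disjoint chains, best score first."""
    n = len(segs)
    if n == 0:
        return []
    score = [float(s.length) for s in segs]
    parent = [-1] * n
    for i in range(1, n):
        si = segs[i]
        for j in range(max(0, i - lookback), i):
            sj = segs[j]
            dq = si.qs - sj.qe
            dt = si.ts - sj.te
            if si.qs <= sj.qs or si.ts <= sj.ts:
                continue
            # allow slight overlap from adjacent diagonals; trimmed at output
            if dq < -(si.length - 1) or dt < -(si.length - 1):
                continue
            if max(dq, dt) > max_gap:
                continue
            # never chain across an N-run on either sequence
            if dq > 0 and q_ncum[si.qs] - q_ncum[sj.qe] > 0:
                continue
            if dt > 0 and t_ncum[si.ts] - t_ncum[sj.te] > 0:
                continue
            cand = score[j] + si.length - abs(dq - dt)
            if cand > score[i]:
                score[i] = cand
                parent[i] = j
    used = [False] * n
    chains: list[list[_Segment]] = []
    for i in sorted(range(n), key=lambda i: -score[i]):
        if used[i]:
            continue
        chain_idx: list[int] = []
        j = i
        while j != -1 and not used[j]:
            chain_idx.append(j)
            used[j] = True
            j = parent[j]
        chain_idx.reverse()
        chains.append([segs[j] for j in chain_idx])
    return chains


def _trim_overlaps(chain: list[_Segment]) -> list[_Segment]:
    out: list[_Segment] = []
    for seg in chain:
        if out:
            trim = max(out[-1].qe - seg.qs, out[-1].te - seg.ts, 0)
            if trim >= seg.length:
                continue
            seg = _Segment(seg.qs + trim, seg.ts + trim, seg.length - trim)
        out.append(seg)
    return out


def _chain_score(chain: list[_Segment]) -> int:
    s = sum(seg.length for seg in chain)
    for a, b in zip(chain, chain[1:]):
        s -= abs((b.qs - a.qe) - (b.ts - a.te))
    return s


def _extend(
    qarr: np.ndarray,
    tarr: np.ndarray,
    q: int,
    t: int,
    step: int,
    xdrop: int = 10,
    max_ext: int = 2000,
) -> int:
    """Gap-free X-drop extension length outward from (q, t) exclusive.

    Match +1, mismatch -1; stops at the first N, at sequence bounds, when
    the running score falls ``xdrop`` below its best, or at ``max_ext``.
    Returns the best-scoring extension length.
    """
    if step > 0:
        n = min(len(qarr) - q - 1, len(tarr) - t - 1, max_ext)
        if n <= 0:
            return 0
        qw = qarr[q + 1 : q + 1 + n]
        tw = tarr[t + 1 : t + 1 + n]
    else:
        n = min(q, t, max_ext)
        if n <= 0:
            return 0
        qw = qarr[q - n : q][::-1]
        tw = tarr[t - n : t][::-1]
    invalid = (qw == 4) | (tw == 4)
    bad = np.flatnonzero(invalid)
    if len(bad):
        n = int(bad[0])
        if n == 0:
            return 0
        qw, tw = qw[:n], tw[:n]
    gains = np.cumsum(np.where(qw == tw, 1, -1))
    run_max = np.maximum.accumulate(gains)
    dropped = np.flatnonzero(gains < run_max - xdrop)
    if len(dropped):
        gains = gains[: int(dropped[0])]
    if len(gains) == 0 or gains.max() <= 0:
        return 0
    return int(np.argmax(gains)) + 1


def _build_record(
    chain: list[_Segment],
    qarr: np.ndarray,
    tarr: np.ndarray,
    qname: str,
    tname: str,
    qlen: int,
    tlen: int,
    strand: str,
) -> AlignmentRecord:
    """Build a PAF record (with cg CIGAR) from a trimmed chain.

    Terminal segments are extended gap-free past the outermost anchors with
    an X-drop rule (match +1, mismatch -1, stop 10 below the running best,
    never across an N), so chain endpoints track the DP-optimal local
    alignment even when mismatches cluster near the sequence ends.
    Coordinates here are in aligner orientation (query possibly
    reverse-complemented); the caller flips query coordinates for "-".
    """
    ext_start = _extend(qarr, tarr, chain[0].qs, chain[0].ts, -1)
    ext_end = _extend(qarr, tarr, chain[-1].qe - 1, chain[-1].te - 1, +1)
    ops: list[tuple[str, int]] = []

    def push(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + ln)
        else:
            ops.append((op, ln))

    prev = chain[0]
    push("M", ext_start + prev.length)
    for seg in chain[1:]:
        dq = seg.qs - prev.qe
        dt = seg.ts - prev.te
        m = min(dq, dt)
        push("M", m)
        if dq > dt:
            push("I", dq - dt)
        elif dt > dq:
            push("D", dt - dq)
        push("M", seg.length)
        prev = seg
    push("M", ext_end)
    qs, ts = chain[0].qs - ext_start, chain[0].ts - ext_start
    q, t = qs, ts
    nmatch = 0
    blocklen = 0
    for op, ln in ops:
        blocklen += ln
        if op == "M":
            qw = qarr[q : q + ln]
            tw = tarr[t : t + ln]
            nmatch += int(np.count_nonzero((qw == tw) & (qw < 4)))
            q += ln
            t += ln
        elif op == "I":
            q += ln
        else:
            t += ln
    cg = "".join(f"{ln}{op}" for op, ln in ops)
    return AlignmentRecord(
        qname=qname, qlen=qlen, qstart=qs, qend=q, strand=strand,
        tname=tname, tlen=tlen, tstart=ts, tend=t,
        nmatch=nmatch, blocklen=blocklen, tags={"cg": cg},
    )


def align(
    query: SequenceRecord,
    target: SequenceRecord,
    k: int = 15,
    max_gap: int = 2000,
    min_chain_score: int = 100,
    max_occ: int = 4,
) -> list[AlignmentRecord]:
    """Align ``query`` against ``target`` on both strands.

    Returns PAF-style records sorted by target coordinate, with
    below-threshold chains dropped.  For "-" records the query interval is
    reported on the original query strand (minimap2 PAF convention) and the
    ``cg`` CIGAR walks the target ascending while the query descends.
    """
    if k < MIN_K:
        raise ValueError(f"k must be >= {MIN_K}")
    if k > min(len(query), len(target)):
        raise ValueError("k exceeds sequence length")
    tidx = _SeqIndex(target.bases, k)
    qidx_fwd = _SeqIndex(query.bases, k)
    qidx_rev = _SeqIndex(revcomp(query.bases), k)
    return _align_indexed(
        query.name, qidx_fwd, qidx_rev, target.name, tidx,
        max_gap=max_gap, min_chain_score=min_chain_score, k=k, max_occ=max_occ,
    )


def _align_indexed(
    qname: str,
    qidx_fwd: _SeqIndex,
    qidx_rev: _SeqIndex,
    tname: str,
    tidx: _SeqIndex,
    max_gap: int,
    min_chain_score: int,
    k: int,
    max_occ: int = 4,
) -> list[AlignmentRecord]:
    qlen, tlen = len(qidx_fwd.arr), len(tidx.arr)
    out: list[AlignmentRecord] = []
    for strand, qidx in (("+", qidx_fwd), ("-", qidx_rev)):
        qpos, tpos = _anchors(qidx, tidx, max_occ=max_occ)
        segs = _segments(qpos, tpos, k)
        for chain in _chain_segments(segs, max_gap, qidx.ncum, tidx.ncum):
            chain = _trim_overlaps(chain)
            if not chain or _chain_score(chain) < min_chain_score:
                continue
            rec = _build_record(
                chain, qidx.arr, tidx.arr, qname, tname, qlen, tlen, strand
            )
            if strand == "-":
                rec.qstart, rec.qend = qlen - rec.qend, qlen - rec.qstart
            out.append(rec)
    out.sort(key=lambda a: (a.tname, a.tstart, a.tend, a.qname))
    return out


def align_all(
    queries: list[SequenceRecord],
    targets: list[SequenceRecord],
    k: int = 15,
    max_gap: int = 2000,
    min_chain_score: int = 100,
    max_occ: int = 4,
) -> list[AlignmentRecord]:
    """Align every query against every target; concatenated, target-sorted.

    Sequences are indexed once each, so all-vs-all runs cost one index build
    per sequence plus one sorted-array intersection per pair.
    """
    if k < MIN_K:
        raise ValueError(f"k must be >= {MIN_K}")
    t_indexes = [(t, _SeqIndex(t.bases, k)) for t in targets if len(t) >= k]
    out: list[AlignmentRecord] = []
    for q in queries:
        if len(q) < k:
            continue
        qidx_fwd = _SeqIndex(q.bases, k)
        qidx_rev = _SeqIndex(revcomp(q.bases), k)
        for t, tidx in t_indexes:
            out.extend(_align_indexed(
                q.name, qidx_fwd, qidx_rev, t.name, tidx,
                max_gap=max_gap, min_chain_score=min_chain_score, k=k,
                max_occ=max_occ,
            ))
    out.sort(key=lambda a: (a.tname, a.tstart, a.tend, a.qname))
    return out
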