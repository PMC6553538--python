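"""Assembly quality metrics: scaffold splitting, Nxx statistics, k-mer completeness.

The subset of QUAST-style measures needed to compare a reference and a new
assembly: contig reconstruction by breaking scaffolds at N-runs of length
>= 10, N50/Nxx and improvement ratios, and canonical-k-mer completeness of
a reference against an assembly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._util import encode_seq, round_half_up
from .io import SequenceRecord


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    n50: int
    longest: int
    shortest: int


def split_scaffolds(
    records: list[SequenceRecord], min_n_run: int = 10
) -> list[SequenceRecord]:
    """Break scaffolds into contigs at maximal N-runs of length >= min_n_run.

    Shorter N-runs stay inside contigs.  Contigs are named parent.1,
    parent.2, ... in scaffold order; an all-N scaffold yields no contigs.
    """
    out: list[SequenceRecord] = []
    breaker = re.compile(f"N{{{min_n_run},}}")
    for rec in records:
        parts = [p for p in breaker.split(rec.bases) if p]
        for i, part in enumerate(parts, start=1):
            out.append(SequenceRecord(f"{rec.name}.{i}", part))
    return out


def nxx(lengths: list[int], x: float = 50) -> int:
    """Smallest length L such that sequences >= L cover >= x% of the total."""
    if not lengths:
        raise ValueError("empty length list")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc * 100 >= x * total:
            return length
    return min(lengths)  # unreachable


def assembly_stats(records: list[SequenceRecord]) -> AssemblyStats:
    lengths = [len(r) for r in records]
    return AssemblyStats(
        n_sequences=len(records),
        total_bp=sum(lengths),
        n50=nxx(lengths, 50),
        longest=max(lengths),
        shortest=min(lengths),
    )


def improvement_ratio(new_value: float, old_value: float, decimals: int = 1) -> float:
    """new/old ratio, half-up rounded (e.g. N50 1,290,032 / 401,294 -> 3.2)."""
    if old_value == 0:
        raise ValueError("zero baseline value")
    return round_half_up(new_value / old_value, decimals)


def _canonical_kmer_set(records: list[SequenceRecord], k: int) -> np.ndarray:
    """Distinct canonical (min of forward/revcomp code) k-mers, N-free."""
    parts: list[np.ndarray] = []
    for rec in records:
        arr = encode_seq(rec.bases)
        n = len(arr) - k + 1
        if n <= 0:
            continue
        fwd = np.zeros(n, dtype=np.int64)
        rev = np.zeros(n, dtype=np.int64)
        invalid = np.zeros(n, dtype=bool)
        for j in range(k):
            w = arr[j : j + n]
            invalid |= w == 4
            b = np.where(w == 4, 0, w).astype(np.int64)
            fwd = fwd * 4 + b
            rev += (3 - b) << (2 * j)
        canon = np.minimum(fwd, rev)[~invalid]
        parts.append(canon)
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def kmer_completeness(
    reference: list[SequenceRecord], assembly: list[SequenceRecord], k: int = 21
) -> float:
    """Fraction of distinct canonical reference k-mers present in the assembly.

    k-mers containing N are excluded on both sides.  k=21 is ample at desk
    scale; for 2-bit packing k must be <= 31.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 31:
        raise ValueError("k must be <= 31 (2-bit packed)")
    ref_kmers = _canonical_kmer_set(reference, k)
    if len(ref_kmers) == 0:
        raise ValueError("reference has no valid k-mers")
    asm_kmers = _canonical_kmer_set(assembly, k)
    present = np.isin(ref_kmers, asm_kmers, assume_unique=True)
    return float(np.count_nonzero(present) / len(ref_kmers))
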