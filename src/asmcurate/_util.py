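"""Small shared helpers: rounding, percentages, sequence encoding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A=0 C=1 G=2 T=3; anything else (N) = 4 and is treated as invalid in k-mers
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode DNA into uint8 codes A=0 C=1 G=2 T=3, other=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero upward (not banker's rounding).

    All user-facing percentages and ratios in this package use this rule so
    that reported figures are reproducible from the raw counts.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding; raises on a zero denominator."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
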