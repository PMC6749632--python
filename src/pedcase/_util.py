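"""Small shared helpers: decimal rounding and DNA sequence utilities."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables in this field do.

    Python's built-in round() is banker's rounding; half-up is what
    reproduces printed one-decimal means like 47.7 from 47.666...
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]
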