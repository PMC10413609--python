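"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return _COMPLEMENT[ord(base)] if ord(base) < 128 and base in "ACGTN" else "N"


def min_rotation(s: str) -> str:
    """Lexicographically minimal rotation of ``s`` (Booth-style, small inputs)."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def smallest_period(s: str) -> int:
    """Smallest p such that s is a whole number of repeats of s[:p]."""
    n = len(s)
    for p in range(1, n + 1):
        if n % p == 0 and s == s[:p] * (n // p):
            return p
    return n
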