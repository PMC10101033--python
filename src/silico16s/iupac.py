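"""IUPAC nucleotide alphabet utilities.

Degenerate primers and ambiguous genome positions both use the 15-letter
IUPAC nucleotide code. A degenerate primer matches a plain A/C/G/T string
exactly when, at every position, the target base is a member of the primer
letter's expansion set (zero-mismatch policy).
"""

from __future__ import annotations

import re
from functools import lru_cache

#: Expansion set of every IUPAC nucleotide letter.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

AMBIGUOUS = frozenset(IUPAC_SETS) - frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class InvalidNucleotideError(ValueError):
    """A character outside the IUPAC nucleotide alphabet."""


def validate(seq: str, *, context: str = "sequence") -> str:
    """Uppercase ``seq`` and raise :class:`InvalidNucleotideError` naming the
    first offending position if any character is not an IUPAC nucleotide."""
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise InvalidNucleotideError(
                f"invalid nucleotide {ch!r} at position {i} in {context}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, ...)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def degeneracy(primer: str) -> int:
    """Number of plain-ACGT strings a degenerate primer expands to."""
    primer = validate(primer, context="primer")
    n = 1
    for ch in primer:
        n *= len(IUPAC_SETS[ch])
    return n


@lru_cache(maxsize=512)
def iupac_pattern(primer: str) -> re.Pattern[str]:
    """Compile a degenerate primer into a regex over plain A/C/G/T strings.

    The pattern accepts exactly the Cartesian product of the per-position
    expansion sets, i.e. exact degenerate matching with zero mismatches.
    """
    primer = validate(primer, context="primer")
    parts = []
    for ch in primer:
        bases = IUPAC_SETS[ch]
        if len(bases) == 1:
            parts.append(next(iter(bases)))
        else:
            parts.append("[" + "".join(sorted(bases)) + "]")
    return re.compile("".join(parts))


def find_matches(primer: str, target: str) -> list[tuple[int, int]]:
    """All (start, end) half-open match intervals of ``primer`` in ``target``,
    including overlapping occurrences."""
    pat = iupac_pattern(primer)
    out: list[tuple[int, int]] = []
    pos = 0
    n = len(primer)
    while True:
        m = pat.search(target, pos)
        if m is None:
            return out
        out.append((m.start(), m.start() + n))
        pos = m.start() + 1


def matches_at(primer: str, target: str, offset: int) -> bool:
    """Positional set-membership check; the brute-force primitive behind
    :func:`find_matches` used as an independent oracle in tests."""
    if offset < 0 or offset + len(primer) > len(target):
        return False
    return all(
        target[offset + i] in IUPAC_SETS[ch] for i, ch in enumerate(primer.upper())
    )
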