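"""IUPAC nucleotide-ambiguity algebra.

Every ambiguity code denotes a non-empty subset of {A, C, G, T}; a
degenerate oligonucleotide therefore denotes the Cartesian product of its
per-position base sets ("expansions").  Matching a degenerate primer
against a database sequence reduces to set operations on these per-position
subsets, which this module represents as 4-bit masks (A=1, C=2, G=4, T=8)
so that whole windows can be compared with vectorised bitwise arithmetic.

Input is case-insensitive and ``U`` is accepted as a synonym for ``T``
(rRNA-gene databases mix DNA and RNA conventions).
"""

from __future__ import annotations

import itertools
from functools import reduce

import numpy as np

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "InvalidAlphabetError",
    "normalize",
    "base_set",
    "complement_code",
    "reverse_complement",
    "degeneracy",
    "expand_degenerate",
    "base_match",
    "seq_to_masks",
    "complement_masks",
]

#: code -> subset of {A, C, G, T} it denotes
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

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: code -> 4-bit occupancy mask
MASKS: dict[str, int] = {
    code: reduce(lambda acc, b: acc | _BASE_BIT[b], bases, 0)
    for code, bases in IUPAC_SETS.items()
}

_MASK_TO_CODE = {mask: code for code, mask in MASKS.items()}

#: complement pairs extend from A<->T, C<->G to the ambiguity codes by
#: complementing the underlying sets (so V={A,C,G} <-> B={C,G,T})
_COMP_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}
IUPAC_COMPLEMENT: dict[str, str] = {
    code: _MASK_TO_CODE[
        reduce(lambda acc, b: acc | _BASE_BIT[_COMP_BASE[b]], bases, 0)
    ]
    for code, bases in IUPAC_SETS.items()
}


class InvalidAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid IUPAC character {char!r} at position {position}"
        )


def normalize(seq: str) -> str:
    """Upper-case ``seq``, map U->T, and validate every character.

    Raises
    ------
    InvalidAlphabetError
        naming the first offending position (0-based).
    """
    out = seq.upper().replace("U", "T")
    for i, c in enumerate(out):
        if c not in IUPAC_SETS:
            raise InvalidAlphabetError(c, i)
    return out


def base_set(code: str) -> frozenset[str]:
    """The subset of {A,C,G,T} denoted by a single IUPAC code."""
    c = code.upper().replace("U", "T")
    if c not in IUPAC_SETS:
        raise InvalidAlphabetError(code, 0)
    return IUPAC_SETS[c]


def complement_code(code: str) -> str:
    c = code.upper().replace("U", "T")
    if c not in IUPAC_COMPLEMENT:
        raise InvalidAlphabetError(code, 0)
    return IUPAC_COMPLEMENT[c]


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string; an involution on valid input."""
    s = normalize(seq)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(s))


def degeneracy(seq: str) -> int:
    """Product of per-position base-set sizes (number of expansions)."""
    s = normalize(seq)
    d = 1
    for c in s:
        d *= len(IUPAC_SETS[c])
    return d


def expand_degenerate(seq: str, max_expansions: int = 1_000_000) -> set[str]:
    """All concrete A/C/G/T strings a degenerate sequence denotes.

    The result has exactly ``degeneracy(seq)`` elements.  ``max_expansions``
    guards against accidental combinatorial blow-up (e.g. a long poly-N).
    """
    s = normalize(seq)
    d = degeneracy(s)
    if d > max_expansions:
        raise ValueError(
            f"degeneracy {d} exceeds max_expansions={max_expansions}"
        )
    choices = [sorted(IUPAC_SETS[c]) for c in s]
    return {"".join(p) for p in itertools.product(*choices)}


def base_match(primer_base: str, target_base: str, mode: str = "intersection") -> bool:
    """Whether a primer position accepts a target base (no mismatch).

    ``subset`` mode requires the target's base set to be contained in the
    primer's (an ambiguous target base only matches if every base it could
    be is accepted); ``intersection`` mode requires only a non-empty
    overlap (an N in the target never counts as a mismatch).  Subset is
    strictly stronger.
    """
    p = MASKS[normalize(primer_base)]
    t = MASKS[normalize(target_base)]
    if mode == "subset":
        return (t & ~p) == 0
    if mode == "intersection":
        return (t & p) != 0
    raise ValueError(f"unknown match mode: {mode!r}")


def seq_to_masks(seq: str) -> np.ndarray:
    """Encode a (normalized) IUPAC string as a uint8 array of 4-bit masks."""
    s = normalize(seq)
    return np.frombuffer(
        bytes(MASKS[c] for c in s), dtype=np.uint8
    ).copy()


def complement_masks(masks: np.ndarray) -> np.ndarray:
    """Complement an array of 4-bit masks (swap A<->T and C<->G bits)."""
    m = masks.astype(np.uint8)
    return (
        ((m & 1) << 3) | ((m & 8) >> 3) | ((m & 2) << 1) | ((m & 4) >> 1)
    ).astype(np.uint8)
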