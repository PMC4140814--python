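"""Ungapped degenerate-primer placement under a mismatch budget.

This is the in-silico analogue of a database probe-match search: every
ungapped placement of a primer against a reference sequence is scored by
the number of positions at which the target base is not accepted by the
primer's ambiguity set, and placements within a configured budget
(``k_max``, default 1) are reported.  Indels are not modelled — primer
annealing tolerance is positional, so Hamming distance is the right
contract.

Two conventions for ambiguity codes in the *target* are supported:
``intersection`` (default; an N in a database sequence never counts as a
mismatch, since it reflects sequencing uncertainty, not primer-template
incompatibility) and ``subset`` (the target base must be unambiguously
accepted).  The primer's degeneracy is authoritative in both.

Both strands are searched by default because public 16S deposits occur in
either orientation.  Coordinates are 0-based half-open on the plus strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import iupac
from .primers import DegeneratePrimer, PrimerSet
from .seqio import ReferenceRecord

__all__ = [
    "MatchResult",
    "PrimerSetHit",
    "count_mismatches",
    "find_matches",
    "best_match",
    "match_primer_set",
]

log = logging.getLogger(__name__)

DEFAULT_K_MAX = 1
DEFAULT_AMPLICON_BOUNDS = (100, 2000)


@dataclass(frozen=True)
class MatchResult:
    """Best placement of one oligo: 0-based half-open plus-strand coords."""

    ref_id: str
    strand: str  # "+" | "-"
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class PrimerSetHit:
    """Productive forward/reverse placement pair delimiting an amplicon.

    The amplicon spans both priming sites inclusive; on a minus-strand hit
    the coordinates are still reported on the plus strand.
    """

    ref_id: str
    strand: str
    forward: MatchResult
    reverse: MatchResult
    amplicon_start: int
    amplicon_end: int

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start

    @property
    def total_mismatches(self) -> int:
        return self.forward.mismatches + self.reverse.mismatches


def _window_mismatch_counts(
    primer_masks: np.ndarray, seq_masks: np.ndarray, mode: str
) -> np.ndarray:
    """Mismatch count of the primer at every offset of the sequence."""
    L = len(primer_masks)
    windows = sliding_window_view(seq_masks, L)
    if mode == "intersection":
        ok = (windows & primer_masks) != 0
    elif mode == "subset":
        ok = (windows & ~primer_masks) == 0
    else:
        raise ValueError(f"unknown match mode: {mode!r}")
    return (L - ok.sum(axis=1)).astype(np.int64)


def count_mismatches(
    primer: DegeneratePrimer | str, window: str, mode: str = "intersection"
) -> int:
    """Number of primer positions that reject the aligned target base.

    The comparison is ungapped and positional; the primer's ambiguity sets
    are authoritative (the operation is not symmetric in its arguments).
    """
    pseq = primer.sequence if isinstance(primer, DegeneratePrimer) else iupac.normalize(primer)
    w = iupac.normalize(window)
    if len(w) != len(pseq):
        raise ValueError(
            f"window length {len(w)} != primer length {len(pseq)}"
        )
    pm = iupac.seq_to_masks(pseq)
    wm = iupac.seq_to_masks(w)
    return int(_window_mismatch_counts(pm, wm, mode)[0]) if len(pseq) else 0


def find_matches(
    primer: DegeneratePrimer,
    record: ReferenceRecord,
    k_max: int = DEFAULT_K_MAX,
    mode: str = "intersection",
    search_minus_strand: bool = True,
) -> list[MatchResult]:
    """All placements of ``primer`` with at most ``k_max`` mismatches.

    Minus-strand placements are found by scanning the reverse complement of
    the primer along the plus strand (complementation preserves the
    ambiguity-set structure, so mismatch counts are strand-invariant).
    Results are sorted by (mismatches, strand with plus first, start).
    """
    seq_masks = iupac.seq_to_masks(record.seq)
    pm = iupac.seq_to_masks(primer.sequence)
    L = len(pm)
    if L > len(seq_masks):
        log.debug(
            "primer %s (%d nt) longer than record %s (%d nt)",
            primer.name, L, record.id, len(record.seq),
        )
        return []
    out: list[MatchResult] = []
    strands = [("+", pm)]
    if search_minus_strand:
        strands.append(("-", iupac.complement_masks(pm)[::-1]))
    for strand, masks in strands:
        mm = _window_mismatch_counts(masks, seq_masks, mode)
        for start in np.nonzero(mm <= k_max)[0]:
            out.append(
                MatchResult(
                    record.id, strand, int(start), int(start) + L, int(mm[start])
                )
            )
    out.sort(key=lambda m: (m.mismatches, m.strand != "+", m.start))
    return out


def best_match(
    primer: DegeneratePrimer,
    record: ReferenceRecord,
    k_max: int = DEFAULT_K_MAX,
    mode: str = "intersection",
    search_minus_strand: bool = True,
) -> MatchResult | None:
    """The placement with the fewest mismatches, or None if none is within
    budget.  Ties prefer the plus strand, then the lowest plus-strand start.
    """
    hits = find_matches(primer, record, k_max, mode, search_minus_strand)
    return hits[0] if hits else None


def _pair_hits_plus(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    record: ReferenceRecord,
    k_max: int,
    mode: str,
    bounds: tuple[int, int],
) -> list[tuple[MatchResult, MatchResult]]:
    """Productive pairs in plus orientation: forward primer on the plus
    strand, 5' of the reverse primer's binding site (which appears on the
    plus strand as the reverse complement of the reverse oligo)."""
    f_hits = find_matches(fwd, record, k_max, mode, search_minus_strand=False)
    # reverse primer anneals to the plus strand; its site is rc(rev) there,
    # which is exactly a minus-strand placement of the reverse oligo
    r_hits = [
        h
        for h in find_matches(rev, record, k_max, mode, search_minus_strand=True)
        if h.strand == "-"
    ]
    lo, hi = bounds
    pairs = []
    for f in f_hits:
        for r in r_hits:
            if f.end > r.start:
                continue  # unproductive: sites overlap or reversed
            amp = r.end - f.start
            if lo <= amp <= hi:
                pairs.append((f, r))
    return pairs


def match_primer_set(
    primer_set: PrimerSet,
    record: ReferenceRecord,
    k_max: int = DEFAULT_K_MAX,
    mode: str = "intersection",
    amplicon_bounds: tuple[int, int] = DEFAULT_AMPLICON_BOUNDS,
    search_minus_strand: bool = True,
) -> PrimerSetHit | None:
    """Best productive forward+reverse placement, or None.

    Both placements must lie on the same strand in productive orientation
    with the amplicon (priming sites inclusive) within ``amplicon_bounds``.
    Among admissible pairs the one minimising total mismatches, then
    amplicon length, then leftmost start wins; plus-strand hits win any
    remaining tie.  Minus-strand hits are reported in plus-strand
    coordinates.
    """
    candidates: list[PrimerSetHit] = []
    for f, r in _pair_hits_plus(
        primer_set.forward, primer_set.reverse, record, k_max, mode, amplicon_bounds
    ):
        candidates.append(
            PrimerSetHit(record.id, "+", f, r, f.start, r.end)
        )
    if search_minus_strand:
        n = len(record.seq)
        rc_record = ReferenceRecord(
            record.id, iupac.reverse_complement(record.seq), record.lineage
        )
        for f, r in _pair_hits_plus(
            primer_set.forward, primer_set.reverse, rc_record, k_max, mode,
            amplicon_bounds,
        ):
            # map rc-frame coords back onto the plus strand
            f_plus = MatchResult(record.id, "-", n - f.end, n - f.start, f.mismatches)
            r_plus = MatchResult(record.id, "-", n - r.end, n - r.start, r.mismatches)
            candidates.append(
                PrimerSetHit(record.id, "-", f_plus, r_plus, n - r.end, n - f.start)
            )
    if not candidates:
        return None
    candidates.sort(
        key=lambda h: (
            h.total_mismatches,
            h.amplicon_length,
            h.amplicon_start,
            h.strand != "+",
        )
    )
    return candidates[0]
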