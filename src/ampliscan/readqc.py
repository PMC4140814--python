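"""Paired-read overlap merging and quality filtering with full accounting.

The processing contract mirrors standard amplicon pipelines: paired 251-nt
reads spanning a ~465-nt V3-V4 amplicon share a clear 3' overlap, are
joined on it, and the joined read is kept only when (a) strictly more than
99% of its bases have Phred quality >= 20 and (b) it contains no ambiguous
base call.  Merge defaults (minimum 6-nt overlap, at most 8% mismatching
overlap positions) follow the published defaults of the fastq-join tool
whose behaviour this module reproduces.

Every pair is accounted for: ``pairs_in == merged + merge_failed`` and
``merged == passed_quality + failed_quality + dropped_ambiguous``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

from .iupac import IUPAC_SETS, reverse_complement
from .seqio import FastqRead, read_fastq, write_fasta_reads, write_fastq

__all__ = [
    "MergeParams",
    "QcParams",
    "QcReport",
    "merge_pair",
    "quality_filter",
    "run_qc",
]

AMBIGUOUS_CODES = frozenset(IUPAC_SETS) - frozenset("ACGT")


@dataclass(frozen=True)
class MergeParams:
    """Overlap-join parameters (fastq-join defaults)."""

    min_overlap: int = 6
    max_diff_frac: float = 0.08

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.max_diff_frac < 0.5:
            raise ValueError("max_diff_frac must be in [0, 0.5)")


@dataclass(frozen=True)
class QcParams:
    """Quality-filter parameters.

    ``min_frac`` is a strict bound: a read passes only when the fraction
    of bases at or above ``min_q`` is strictly greater than ``min_frac``.
    """

    min_q: int = 20
    min_frac: float = 0.99
    drop_ambiguous: bool = True

    def __post_init__(self):
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")


@dataclass
class QcReport:
    pairs_in: int = 0
    merged: int = 0
    merge_failed: int = 0
    passed_quality: int = 0
    failed_quality: int = 0
    dropped_ambiguous: int = 0

    def validate(self) -> None:
        if self.merged + self.merge_failed != self.pairs_in:
            raise AssertionError("merge accounting broken")
        if (
            self.passed_quality + self.failed_quality + self.dropped_ambiguous
            != self.merged
        ):
            raise AssertionError("quality accounting broken")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def merge_pair(
    r1: FastqRead, r2: FastqRead, params: MergeParams = MergeParams()
) -> FastqRead | None:
    """Join mates on their best overlap, or return None when none admits.

    ``r2`` is reverse-complemented first (standard mate orientation), then
    every suffix-of-r1 / prefix-of-rc(r2) overlap of length >= min_overlap
    is scored; admissible overlaps have at most ``max_diff_frac`` of their
    positions mismatching.  The overlap maximising matched positions wins,
    longer overlaps breaking ties (deterministic).  Within the overlap the
    higher-quality base is kept and the merged quality is the maximum of
    the two.
    """
    if not r1.bases or not r2.bases:
        raise ValueError("cannot merge an empty read")
    b2 = reverse_complement(r2.bases)
    q2 = r2.quals[::-1]
    n1, n2 = len(r1), len(b2)
    best: tuple[int, int] | None = None  # (matched positions, overlap length)
    for ov in range(params.min_overlap, min(n1, n2) + 1):
        s1 = r1.bases[n1 - ov :]
        s2 = b2[:ov]
        diffs = sum(a != b for a, b in zip(s1, s2))
        if diffs > params.max_diff_frac * ov:
            continue
        cand = (ov - diffs, ov)
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    ov = best[1]
    bases = list(r1.bases[: n1 - ov])
    quals = list(r1.quals[: n1 - ov])
    for i in range(ov):
        a, qa = r1.bases[n1 - ov + i], r1.quals[n1 - ov + i]
        b, qb = b2[i], q2[i]
        bases.append(a if qa >= qb else b)
        quals.append(max(qa, qb))
    bases.extend(b2[ov:])
    quals.extend(q2[ov:])
    return FastqRead(r1.id, "".join(bases), quals)


def quality_filter(read: FastqRead, params: QcParams = QcParams()) -> tuple[bool, str]:
    """``(True, "pass")`` or ``(False, reason)`` with reason in
    {"ambiguous", "quality"}.

    Ambiguity is checked first: any IUPAC code outside A/C/G/T discards
    the read outright when ``drop_ambiguous`` is set.  Otherwise the read
    passes iff the fraction of bases with quality >= ``min_q`` is strictly
    greater than ``min_frac``.
    """
    if params.drop_ambiguous and any(c in AMBIGUOUS_CODES for c in read.bases):
        return False, "ambiguous"
    n = len(read)
    if n == 0:
        return False, "quality"
    good = sum(q >= params.min_q for q in read.quals)
    if good / n > params.min_frac:
        return True, "pass"
    return False, "quality"


def run_qc(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    merge_params: MergeParams = MergeParams(),
    qc_params: QcParams = QcParams(),
) -> tuple[list[FastqRead], QcReport]:
    """Merge and filter an iterable of mate pairs, order-preserving."""
    report = QcReport()
    kept: list[FastqRead] = []
    for r1, r2 in pairs:
        report.pairs_in += 1
        merged = merge_pair(r1, r2, merge_params)
        if merged is None:
            report.merge_failed += 1
            continue
        report.merged += 1
        ok, reason = quality_filter(merged, qc_params)
        if ok:
            report.passed_quality += 1
            kept.append(merged)
        elif reason == "ambiguous":
            report.dropped_ambiguous += 1
        else:
            report.failed_quality += 1
    report.validate()
    return kept, report


def run_qc_files(
    r1_path: str | Path,
    r2_path: str | Path,
    out_path: str | Path | None = None,
    report_path: str | Path | None = None,
    merge_params: MergeParams = MergeParams(),
    qc_params: QcParams = QcParams(),
) -> tuple[list[FastqRead], QcReport]:
    """File-level wrapper: two FASTQ inputs with mates matched by order.

    Output format follows the ``out_path`` suffix (.fastq/.fq keeps
    qualities, anything else writes FASTA).  Unequal mate counts are a
    hard error.
    """
    reads1 = list(read_fastq(r1_path))
    reads2 = list(read_fastq(r2_path))
    if len(reads1) != len(reads2):
        raise ValueError(
            f"unequal mate counts: {len(reads1)} in {r1_path}, "
            f"{len(reads2)} in {r2_path}"
        )
    kept, report = run_qc(zip(reads1, reads2), merge_params, qc_params)
    if out_path is not None:
        if str(out_path).endswith((".fastq", ".fq")):
            write_fastq(kept, out_path)
        else:
            write_fasta_reads(kept, out_path)
    if report_path is not None:
        report.to_json(report_path)
    return kept, report
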