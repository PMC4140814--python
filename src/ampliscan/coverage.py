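"""Taxon-grouped primer-coverage statistics.

Coverage of a primer set over a reference collection is the percentage of
sequences in each taxonomic group that carry a productive pair of priming
sites within the mismatch budget.  Rates are presented rounded half-up to
one decimal, mirroring how such tables are conventionally printed; full
precision is kept internally and rounding is applied only at the report
layer.

Records are pre-filtered to length strictly greater than 1,200 nt by
default — short partial 16S deposits cannot be scored fairly against a
V3-V4 primer pair because a missing priming site is indistinguishable
from a mismatching one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .match import DEFAULT_AMPLICON_BOUNDS, DEFAULT_K_MAX, best_match, match_primer_set
from .primers import PrimerSet
from .seqio import ReferenceRecord

__all__ = [
    "CoverageRow",
    "CoverageTable",
    "filter_references",
    "coverage_rate",
    "coverage_table",
    "compare_primer_sets",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 1200
UNASSIGNED = "unassigned"


def coverage_rate(hits: int, queries: int) -> float | None:
    """100 x hits / queries, rounded half-up to one decimal.

    Returns None (an undefined marker, distinct from 0.0) when there are
    no queries.
    """
    if hits < 0 or queries < 0:
        raise ValueError("hits and queries must be non-negative")
    if hits > queries:
        raise ValueError(f"hits ({hits}) exceed queries ({queries})")
    if queries == 0:
        return None
    exact = Decimal(100 * hits) / Decimal(queries)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageRow:
    group: str
    hits: int
    queries: int

    def __post_init__(self):
        if not 0 <= self.hits <= self.queries:
            raise ValueError(
                f"group {self.group!r}: hits {self.hits} outside "
                f"[0, {self.queries}]"
            )

    @property
    def rate_percent(self) -> float | None:
        return coverage_rate(self.hits, self.queries)


@dataclass
class CoverageTable:
    primer_set_name: str
    k_max: int
    rows: list[CoverageRow]
    filter_min_len: int | None = None

    def row(self, group: str) -> CoverageRow | None:
        for r in self.rows:
            if r.group == group:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "primer_set": self.primer_set_name,
                "target": r.group,
                "hits": r.hits,
                "queries": r.queries,
                "coverage_percent": r.rate_percent,
            }
            for r in self.rows
        )


def filter_references(
    records: list[ReferenceRecord], min_len: int = DEFAULT_MIN_LEN
) -> tuple[list[ReferenceRecord], dict[str, int]]:
    """Keep records strictly longer than ``min_len``; report the counts.

    The cut is strict ("greater than"), so a record of exactly ``min_len``
    nt is dropped.
    """
    if min_len < 0:
        raise ValueError("min_len must be non-negative")
    kept = [r for r in records if len(r) > min_len]
    counts = {"kept": len(kept), "dropped": len(records) - len(kept)}
    log.info(
        "length filter >%d nt: kept %d, dropped %d",
        min_len, counts["kept"], counts["dropped"],
    )
    return kept, counts


def _group_of(record: ReferenceRecord, rank: str) -> str:
    name = record.rank_name(rank)
    return name if name is not None else UNASSIGNED


def coverage_table(
    records: list[ReferenceRecord],
    primer_set: PrimerSet,
    k_max: int = DEFAULT_K_MAX,
    group_rank: str = "domain",
    mode: str = "intersection",
    amplicon_bounds: tuple[int, int] = DEFAULT_AMPLICON_BOUNDS,
    per_oligo: bool = False,
) -> CoverageTable:
    """Hits/queries/rate per group at ``group_rank`` for one primer set.

    A record is a hit when both primers place productively within the
    budget (the pair-wise rule).  With ``per_oligo=True`` the table instead
    counts records where each oligo matches anywhere irrespective of
    pairing, exposed so the stricter and looser hit conventions can both
    be inspected; the extra rows are suffixed ``/forward`` and
    ``/reverse``.  Records lacking ``group_rank`` in their lineage count
    under ``"unassigned"`` — they stay in the denominator.
    """
    if not records:
        warnings.warn("coverage_table called on an empty database", stacklevel=2)
        return CoverageTable(primer_set.name, k_max, [])
    hits: dict[str, int] = {}
    queries: dict[str, int] = {}
    oligo_hits: dict[str, int] = {}
    for rec in records:
        group = _group_of(rec, group_rank)
        queries[group] = queries.get(group, 0) + 1
        hit = match_primer_set(
            primer_set, rec, k_max=k_max, mode=mode, amplicon_bounds=amplicon_bounds
        )
        if hit is not None:
            hits[group] = hits.get(group, 0) + 1
        if per_oligo:
            for role, primer in (
                ("forward", primer_set.forward),
                ("reverse", primer_set.reverse),
            ):
                if best_match(primer, rec, k_max=k_max, mode=mode) is not None:
                    key = f"{group}/{role}"
                    oligo_hits[key] = oligo_hits.get(key, 0) + 1
    rows = [
        CoverageRow(group, hits.get(group, 0), queries[group])
        for group in sorted(queries)
    ]
    if per_oligo:
        for group in sorted(queries):
            for role in ("forward", "reverse"):
                key = f"{group}/{role}"
                rows.append(CoverageRow(key, oligo_hits.get(key, 0), queries[group]))
    return CoverageTable(primer_set.name, k_max, rows)


def compare_primer_sets(
    records: list[ReferenceRecord],
    primer_sets: list[PrimerSet],
    k_max: int = DEFAULT_K_MAX,
    group_rank: str = "domain",
    mode: str = "intersection",
    amplicon_bounds: tuple[int, int] = DEFAULT_AMPLICON_BOUNDS,
) -> pd.DataFrame:
    """One merged (primer set x target group) report over the identical
    database — the layout used to compare competing primer sets."""
    if not primer_sets:
        raise ValueError("at least one primer set is required")
    frames = [
        coverage_table(
            records, ps, k_max=k_max, group_rank=group_rank, mode=mode,
            amplicon_bounds=amplicon_bounds,
        ).to_frame()
        for ps in primer_sets
    ]
    return pd.concat(frames, ignore_index=True)


def write_coverage_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# primer-set coverage by taxon (rates in %, half-up, 1 dp)\n")
        frame.to_csv(fh, sep="\t", index=False)
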