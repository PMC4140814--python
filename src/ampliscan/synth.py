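"""Seeded generators for planted-truth reference databases and amplicon
paired reads.

``generate_reference_db`` builds FASTA-style reference collections in
which every record carries a forward priming site and a reverse priming
site with *exactly* the requested number of mismatches each, embedded in
random background that is brute-force-verified free of spurious
placements.  Because the mismatch counts are planted by construction, the
generator emits a truth table that downstream coverage statistics can be
compared against exactly.

``generate_paired_reads`` turns amplicons extracted from such records
into mate pairs with a controlled overlap, planted low-quality positions
and planted ambiguous bases, so the intended QC fate of every pair is
known in advance.

Determinism: all randomness flows through one ``numpy`` Generator seeded
from the ``seed`` argument, consumed record-by-record in declaration
order (background bases, expansion choice, mismatch positions,
substitution bases; then per pair: fate shuffle, qualities, planted
positions).  A fixed seed therefore reproduces byte-identical FASTA and
FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import iupac
from .match import match_primer_set
from .primers import PrimerSet
from .readqc import MergeParams, QcParams
from .seqio import (
    FastqRead,
    ReferenceRecord,
    write_fastq,
    write_reference_fasta,
    write_taxonomy_sidecar,
)

__all__ = [
    "PlantSpec",
    "ReadSimSpec",
    "generate_reference_db",
    "generate_paired_reads",
]

_BASES = "ACGT"
RETRY_CAP = 100


@dataclass(frozen=True)
class PlantSpec:
    """A block of records for one taxon with fixed planted mismatch counts.

    ``fwd_mismatches``/``rev_mismatches`` may be a single count applied to
    every record or a per-record list of length ``n_records``.
    """

    group: str
    n_records: int
    fwd_mismatches: int | list[int] = 0
    rev_mismatches: int | list[int] = 0
    record_length: int = 1300
    lineage_prefix: list[tuple[str, str]] | None = None

    def per_record(self, which: str) -> list[int]:
        v = self.fwd_mismatches if which == "fwd" else self.rev_mismatches
        if isinstance(v, int):
            return [v] * self.n_records
        if len(v) != self.n_records:
            raise ValueError(
                f"{which}_mismatches list length {len(v)} != n_records "
                f"{self.n_records}"
            )
        return list(v)


@dataclass(frozen=True)
class ReadSimSpec:
    """Amplicon paired-read simulation parameters.

    Reads are the two ends of the amplicon, so the overlap length is
    ``2*read_length - amplicon_length`` (the default 251-nt reads over a
    ~458-nt V3-V4 amplicon overlap by ~44 nt).  ``n_fail_quality`` pairs
    get enough sub-threshold quality positions planted (outside the
    overlap, where mate-consensus cannot rescue them) to fail the quality
    filter; ``n_ambiguous`` pairs get planted N bases.  Rates may be given
    instead of counts and are rounded to counts.
    """

    n_pairs: int
    read_length: int = 251
    base_error_rate: float = 0.0
    low_q_positions: int = 0
    n_fail_quality: int | None = None
    n_ambiguous: int | None = None
    fail_quality_rate: float = 0.0
    ambiguous_rate: float = 0.0

    def counts(self) -> tuple[int, int]:
        nf = (
            self.n_fail_quality
            if self.n_fail_quality is not None
            else round(self.fail_quality_rate * self.n_pairs)
        )
        na = (
            self.n_ambiguous
            if self.n_ambiguous is not None
            else round(self.ambiguous_rate * self.n_pairs)
        )
        if nf + na > self.n_pairs:
            raise ValueError("planted fates exceed n_pairs")
        return nf, na


def _brute_mismatches(primer_seq: str, window: str, cutoff: int | None = None) -> int:
    """Set-based mismatch count, independent of the vectorised matcher.

    With ``cutoff`` given, counting stops (returning cutoff+1) as soon as
    the budget is exceeded.
    """
    mm = 0
    for p, t in zip(primer_seq, window):
        if not (iupac.IUPAC_SETS[p] & iupac.IUPAC_SETS[t]):
            mm += 1
            if cutoff is not None and mm > cutoff:
                return mm
    return mm


def _brute_placements(primer_seq: str, seq: str, k_max: int) -> set[tuple[str, int]]:
    """All (strand, start) placements with <= k_max mismatches, brute force."""
    out: set[tuple[str, int]] = set()
    L = len(primer_seq)
    rc = iupac.reverse_complement(primer_seq)
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if _brute_mismatches(primer_seq, window, k_max) <= k_max:
            out.add(("+", start))
        if _brute_mismatches(rc, window, k_max) <= k_max:
            out.add(("-", start))
    return out


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(_BASES[i] for i in idx)


def _planted_site(
    rng: np.random.Generator, primer_seq: str, n_mismatches: int
) -> str:
    """One expansion of the primer with exactly ``n_mismatches``
    substitutions, each at a position where the substituted base falls
    outside the primer's base set (so it registers as a true mismatch)."""
    site = [
        rng.choice(sorted(iupac.IUPAC_SETS[c])) for c in primer_seq
    ]
    mutable = [
        i for i, c in enumerate(primer_seq) if len(iupac.IUPAC_SETS[c]) < 4
    ]
    if n_mismatches > len(mutable):
        bad = next(
            (i for i, c in enumerate(primer_seq) if len(iupac.IUPAC_SETS[c]) == 4),
            None,
        )
        raise ValueError(
            f"cannot plant {n_mismatches} mismatches: only {len(mutable)} "
            f"positions admit one (position {bad} accepts any base)"
        )
    pos = rng.choice(mutable, size=n_mismatches, replace=False)
    for i in sorted(int(p) for p in pos):
        outside = sorted(set(_BASES) - iupac.IUPAC_SETS[primer_seq[i]])
        site[i] = outside[rng.integers(len(outside))]
    return "".join(site)


def generate_reference_db(
    specs: list[PlantSpec],
    primer_set: PrimerSet,
    seed: int = 0,
    insert_length: int = 420,
    gc_content: float = 0.5,
    verify_k: int = 2,
) -> tuple[list[ReferenceRecord], pd.DataFrame]:
    """Build a reference collection with planted priming sites.

    Each record is ``pad | forward site | insert | rc(reverse site) | pad``
    with background pads rejection-sampled (cap ``RETRY_CAP`` per record)
    until brute force confirms the only placements of either primer with
    <= ``verify_k`` mismatches are the planted ones.  The returned truth
    table has one row per record with the planted mismatch counts and the
    expected pair-hit status at k_max = 0, 1, 2.
    """
    rng = np.random.default_rng(seed)
    fseq = primer_set.forward.sequence
    rseq = primer_set.reverse.sequence
    amplicon_len = len(fseq) + insert_length + len(rseq)
    records: list[ReferenceRecord] = []
    truth_rows = []
    counter = 0
    for spec in specs:
        fwd_mms = spec.per_record("fwd")
        rev_mms = spec.per_record("rev")
        pad_total = spec.record_length - amplicon_len
        if pad_total < 2:
            raise ValueError(
                f"record_length {spec.record_length} cannot hold the "
                f"{amplicon_len}-nt amplicon plus padding"
            )
        pad_left = pad_total // 2
        pad_right = pad_total - pad_left
        lineage = list(spec.lineage_prefix or [("domain", spec.group)])
        for i in range(spec.n_records):
            counter += 1
            rid = f"syn{counter:05d}"
            fwd_site = _planted_site(rng, fseq, fwd_mms[i])
            rev_site = _planted_site(rng, rseq, rev_mms[i])
            rc_rev_site = iupac.reverse_complement(rev_site)
            seq = None
            for _ in range(RETRY_CAP):
                cand = (
                    _random_background(rng, pad_left, gc_content)
                    + fwd_site
                    + _random_background(rng, insert_length, gc_content)
                    + rc_rev_site
                    + _random_background(rng, pad_right, gc_content)
                )
                exp_f = (
                    {("+", pad_left)} if fwd_mms[i] <= verify_k else set()
                )
                rev_start = pad_left + len(fseq) + insert_length
                exp_r = (
                    {("-", rev_start)} if rev_mms[i] <= verify_k else set()
                )
                if (
                    _brute_placements(fseq, cand, verify_k) == exp_f
                    and _brute_placements(rseq, cand, verify_k) == exp_r
                ):
                    seq = cand
                    break
            if seq is None:
                raise RuntimeError(
                    f"record {rid}: no spurious-match-free background found "
                    f"in {RETRY_CAP} attempts"
                )
            records.append(ReferenceRecord(rid, seq, lineage))
            truth_rows.append(
                {
                    "id": rid,
                    "group": spec.group,
                    "fwd_mm": fwd_mms[i],
                    "rev_mm": rev_mms[i],
                    "hit_k0": fwd_mms[i] == 0 and rev_mms[i] == 0,
                    "hit_k1": fwd_mms[i] <= 1 and rev_mms[i] <= 1,
                    "hit_k2": fwd_mms[i] <= 2 and rev_mms[i] <= 2,
                }
            )
    return records, pd.DataFrame(truth_rows)


def truth_coverage(truth: pd.DataFrame, k_max: int) -> pd.DataFrame:
    """Expected (group, hits, queries) at ``k_max`` from a truth table."""
    col = f"hit_k{k_max}"
    g = truth.groupby("group")[col].agg(["sum", "count"]).reset_index()
    return g.rename(columns={"sum": "hits", "count": "queries"})


def _extract_amplicon(
    record: ReferenceRecord, primer_set: PrimerSet, k_max: int = 2
) -> str | None:
    hit = match_primer_set(primer_set, record, k_max=k_max)
    if hit is None:
        return None
    amp = record.seq[hit.amplicon_start : hit.amplicon_end]
    return amp if hit.strand == "+" else iupac.reverse_complement(amp)


def generate_paired_reads(
    records: list[ReferenceRecord],
    primer_set: PrimerSet,
    spec: ReadSimSpec,
    seed: int = 0,
    merge_params: MergeParams = MergeParams(),
    qc_params: QcParams = QcParams(),
) -> tuple[list[tuple[FastqRead, FastqRead]], pd.DataFrame]:
    """Simulate mate pairs from amplicons with planted QC fates.

    Amplicons are cycled over the records that carry a primer-set hit.
    Pair fates (pass / fail_quality / ambiguous) are assigned up front and
    shuffled; the truth table records each pair's intended fate, which
    ``run_qc`` under the same parameters must reproduce exactly.
    """
    rng = np.random.default_rng(seed)
    amplicons = []
    for rec in records:
        amp = _extract_amplicon(rec, primer_set)
        if amp is not None:
            amplicons.append((rec.id, amp))
    if not amplicons:
        raise ValueError("no records carry a primer-set hit")
    rl = spec.read_length
    for rid, amp in amplicons:
        overlap = 2 * rl - len(amp)
        if rl > len(amp) or overlap < merge_params.min_overlap:
            raise ValueError(
                f"amplicon of {rid} ({len(amp)} nt) incompatible with "
                f"{rl}-nt reads and min overlap {merge_params.min_overlap}"
            )
    n_fail, n_amb = spec.counts()
    fates = (
        ["fail_quality"] * n_fail
        + ["ambiguous"] * n_amb
        + ["pass"] * (spec.n_pairs - n_fail - n_amb)
    )
    fates = [fates[i] for i in rng.permutation(len(fates))]

    pairs: list[tuple[FastqRead, FastqRead]] = []
    truth_rows = []
    for p in range(spec.n_pairs):
        rid, amp = amplicons[p % len(amplicons)]
        n = len(amp)
        overlap = 2 * rl - n
        b1 = list(amp[:rl])
        b2_plus = list(amp[n - rl :])  # r2 on the plus strand
        q1 = list(rng.integers(30, 41, size=rl))
        q2 = list(rng.integers(30, 41, size=rl))
        non_overlap_1 = rl - overlap  # r1 prefix not covered by r2
        fate = fates[p]
        if spec.base_error_rate > 0:
            # substitution errors confined to the r1 overhang so the
            # overlap stays clean and the merge outcome is unaffected
            for i in range(non_overlap_1):
                if rng.random() < spec.base_error_rate:
                    b1[i] = _BASES[
                        (_BASES.index(b1[i]) + 1 + rng.integers(3)) % 4
                    ]
        if fate == "fail_quality":
            need = math.ceil(n * (1 - qc_params.min_frac) - 1e-9)
            need = max(need, 1)
            if need > non_overlap_1:
                raise ValueError(
                    f"cannot plant {need} low-quality positions in a "
                    f"{non_overlap_1}-nt overhang"
                )
            pos = rng.choice(non_overlap_1, size=need, replace=False)
            for i in pos:
                q1[int(i)] = int(rng.integers(2, qc_params.min_q))
        elif fate == "ambiguous":
            pos = int(rng.integers(non_overlap_1))
            b1[pos] = "N"
        elif spec.low_q_positions > 0:
            # sub-threshold positions few enough to keep the pass fate
            allowed = math.ceil(n * (1 - qc_params.min_frac) - 1e-9) - 1
            k = min(spec.low_q_positions, max(allowed, 0))
            if k > 0:
                pos = rng.choice(non_overlap_1, size=k, replace=False)
                for i in pos:
                    q1[int(i)] = int(rng.integers(2, qc_params.min_q))
        r1 = FastqRead(f"pair{p:05d}/1", "".join(b1), [int(q) for q in q1])
        r2 = FastqRead(
            f"pair{p:05d}/2",
            iupac.reverse_complement("".join(b2_plus)),
            [int(q) for q in q2][::-1],
        )
        pairs.append((r1, r2))
        truth_rows.append({"pair": f"pair{p:05d}", "source": rid, "fate": fate})
    return pairs, pd.DataFrame(truth_rows)


def write_refdb(
    records: list[ReferenceRecord],
    truth: pd.DataFrame,
    out_prefix: str | Path,
) -> dict[str, Path]:
    """Write FASTA + taxonomy sidecar + truth table under a path prefix."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(".fasta"),
        "taxonomy": prefix.with_suffix(".tax.tsv"),
        "truth": prefix.with_suffix(".truth.tsv"),
    }
    write_reference_fasta(records, paths["fasta"])
    write_taxonomy_sidecar(records, paths["taxonomy"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_paired_reads(
    pairs: list[tuple[FastqRead, FastqRead]],
    truth: pd.DataFrame,
    out_prefix: str | Path,
) -> dict[str, Path]:
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "r1": Path(str(prefix) + "_R1.fastq"),
        "r2": Path(str(prefix) + "_R2.fastq"),
        "truth": Path(str(prefix) + ".truth.tsv"),
    }
    write_fastq([p[0] for p in pairs], paths["r1"])
    write_fastq([p[1] for p in pairs], paths["r2"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
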