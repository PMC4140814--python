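"""Reference-database and read containers plus FASTA/FASTQ/taxonomy I/O.

Reference collections arrive as FASTA with taxonomy either embedded in the
headers (``k__Bacteria; p__Firmicutes`` rank-token style, or the RDP
``Lineage=Root;rootrank;Bacteria;domain;...`` style) or in a two-column
tab-separated sidecar mapping id to lineage.  Lineages are stored as
ordered ``(rank, name)`` pairs, domain first; ranks the source does not
provide are never invented.

Internal coordinates throughout the package are 0-based half-open; report
writers emit 1-based inclusive positions and say so in their headers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import iupac

__all__ = [
    "Lineage",
    "ReferenceRecord",
    "FastqRead",
    "parse_lineage",
    "read_reference_fasta",
    "write_reference_fasta",
    "read_fastq",
    "write_fastq",
]

log = logging.getLogger(__name__)

#: ordered (rank, name) pairs, domain first when present
Lineage = list[tuple[str, str]]

_RANK_PREFIX = {
    "k": "domain",  # greengenes writes kingdom where 16S work means domain
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

_DEFAULT_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

GAP_CHARS = "-."


@dataclass
class ReferenceRecord:
    """One database sequence with identifier, sequence, and lineage."""

    id: str
    seq: str
    lineage: Lineage = field(default_factory=list)

    def __post_init__(self):
        if not self.id:
            raise ValueError("reference record must have a non-empty id")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.seq = iupac.normalize(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def rank_name(self, rank: str) -> str | None:
        """Name at ``rank``, or None when the lineage lacks it."""
        for r, name in self.lineage:
            if r == rank:
                return name
        return None


@dataclass
class FastqRead:
    """A read with Sanger-encoded per-base Phred qualities."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality values"
            )
        if self.quals and (min(self.quals) < 0 or max(self.quals) > 93):
            raise ValueError(f"read {self.id!r}: Phred scores outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)


def parse_lineage(text: str) -> Lineage:
    """Parse a lineage string in any of the supported conventions.

    * rank tokens: ``k__Bacteria; p__Firmicutes; c__Clostridia``
    * RDP header style: ``Lineage=Root;rootrank;Bacteria;domain;...``
      (alternating name;rank, with the Root/rootrank pair dropped)
    * bare semicolon-joined names: ranks assigned positionally from
      domain downwards
    """
    text = text.strip()
    if not text:
        return []
    if text.lower().startswith("lineage="):
        body = text[len("lineage="):].strip().strip(";")
        tokens = [t.strip() for t in body.split(";")]
        pairs = list(zip(tokens[0::2], tokens[1::2]))
        return [
            (rank.lower(), name)
            for name, rank in pairs
            if rank.lower() != "rootrank"
        ]
    parts = [p.strip() for p in text.split(";") if p.strip()]
    if any("__" in p for p in parts):
        out: Lineage = []
        for p in parts:
            prefix, _, name = p.partition("__")
            if not name:
                continue  # empty rank placeholder like "s__"
            rank = _RANK_PREFIX.get(prefix.lower(), prefix.lower())
            out.append((rank, name))
        return out
    return [(rank, name) for rank, name in zip(_DEFAULT_RANKS, parts)]


def _lineage_from_header(description: str) -> Lineage:
    """Extract a lineage from a FASTA description line, if one is present."""
    # id is the first whitespace token; the rest may carry taxonomy
    _, _, rest = description.partition(" ")
    rest = rest.strip()
    if not rest:
        return []
    if "lineage=" in rest.lower():
        idx = rest.lower().index("lineage=")
        return parse_lineage(rest[idx:])
    if "__" in rest:
        return parse_lineage(rest)
    return []


def _read_taxonomy_sidecar(path: str | Path) -> dict[str, Lineage]:
    table: dict[str, Lineage] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise ValueError(
                f"{path}:{lineno}: expected id<TAB>lineage, got {line!r}"
            )
        rid, _, lineage_text = line.partition("\t")
        table[rid.strip()] = parse_lineage(lineage_text)
    return table


def read_reference_fasta(
    path: str | Path,
    taxonomy: str | Path | None = None,
    strip_gaps: bool = True,
) -> list[ReferenceRecord]:
    """Load a reference FASTA, attaching lineages from headers or a sidecar.

    Gap characters (``-``, ``.``) common in aligned-database exports are
    stripped unless ``strip_gaps=False``.  Duplicate ids are a hard error;
    sidecar rows naming absent records produce a warning and are ignored.
    """
    sidecar = _read_taxonomy_sidecar(taxonomy) if taxonomy is not None else None
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if strip_gaps:
            for g in GAP_CHARS:
                seq = seq.replace(g, "")
        if sidecar is not None:
            lineage = sidecar.get(rec.id, [])
        else:
            lineage = _lineage_from_header(rec.description)
        records.append(ReferenceRecord(rec.id, seq, lineage))
    if sidecar is not None:
        orphans = set(sidecar) - seen
        if orphans:
            warnings.warn(
                f"{len(orphans)} taxonomy rows name records absent from "
                f"{path} (ignored)",
                stacklevel=2,
            )
    return records


def write_reference_fasta(
    records: Iterable[ReferenceRecord], path: str | Path
) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_taxonomy_sidecar(
    records: Iterable[ReferenceRecord], path: str | Path
) -> None:
    """Write an ``id<TAB>rank__name; ...`` sidecar for annotated records."""
    short = {v: k for k, v in _RANK_PREFIX.items() if k != "k"}
    with open(path, "w") as fh:
        for r in records:
            tokens = "; ".join(
                f"{short.get(rank, rank)}__{name}" for rank, name in r.lineage
            )
            fh.write(f"{r.id}\t{tokens}\n")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate over a Sanger (Phred+33) FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield FastqRead(
            rec.id,
            str(rec.seq).upper(),
            list(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{quals}\n")


def write_fasta_reads(reads: Iterable[FastqRead], path: str | Path) -> None:
    """Write reads as FASTA (qualities dropped)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.bases), 60):
                fh.write(r.bases[i : i + 60] + "\n")
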