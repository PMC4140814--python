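"""Degenerate-primer data type, bundled 16S V3-V4 primer sets, and helpers
for stripping Illumina construct scaffolds down to the priming region.

The bundled primers are the published V3-V4 oligos this package was built
around: the prokaryotic universal pair Pro341F/Pro805R, the *Bacteria*
pair 341F/R806, the *Archaea* pair ARC344F/Arch806R, and the older
universal forward primer Uni340F.  Pro341F is Uni340F with the 9th base
relaxed from R (A/G) to N, which removes the single mismatch the
*Verrucomicrobia* 16S sequence carries against the bacterial 341F primer
at that position; every expansion of 341F and of Uni340F is therefore an
expansion of Pro341F.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from . import iupac

__all__ = [
    "DegeneratePrimer",
    "PrimerSet",
    "PRO341F",
    "PRO805R",
    "BACT341F",
    "R806",
    "ARC344F",
    "ARCH806R",
    "UNI340F",
    "BUILTIN_SETS",
    "strip_construct",
    "read_primer_tsv",
]

MIN_PRIMER_LEN = 10
MAX_PRIMER_LEN = 50


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named oligo over the IUPAC alphabet with a forward/reverse role.

    ``sequence`` is stored 5'->3' as synthesised; a reverse primer anneals
    to the plus strand, so its binding site appears on the plus strand as
    the reverse complement of ``sequence``.
    """

    name: str
    sequence: str
    role: str  # "forward" | "reverse"

    def __post_init__(self):
        object.__setattr__(self, "sequence", iupac.normalize(self.sequence))
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward/reverse, got {self.role!r}")
        n = len(self.sequence)
        if not (MIN_PRIMER_LEN <= n <= MAX_PRIMER_LEN):
            raise ValueError(
                f"primer {self.name!r}: length {n} outside "
                f"[{MIN_PRIMER_LEN}, {MAX_PRIMER_LEN}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return iupac.degeneracy(self.sequence)

    def expansions(self) -> set[str]:
        return iupac.expand_degenerate(self.sequence)


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse pair delimiting one amplicon."""

    name: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer

    def __post_init__(self):
        if self.forward.role != "forward" or self.reverse.role != "reverse":
            raise ValueError(f"primer set {self.name!r}: roles are swapped")


PRO341F = DegeneratePrimer("Pro341F", "CCTACGGGNBGCASCAG", "forward")
PRO805R = DegeneratePrimer("Pro805R", "GACTACNVGGGTATCTAATCC", "reverse")
BACT341F = DegeneratePrimer("341F", "CCTACGGGAGGCAGCAG", "forward")
R806 = DegeneratePrimer("R806", "GGACTACHVGGGTWTCTAAT", "reverse")
ARC344F = DegeneratePrimer("ARC344F", "ACGGGGYGCAGCAGGCGCGA", "forward")
ARCH806R = DegeneratePrimer("Arch806R", "GGACTACVSGGGTATCTAAT", "reverse")
UNI340F = DegeneratePrimer("Uni340F", "CCTACGGGRBGCASCAG", "forward")

BUILTIN_SETS: dict[str, PrimerSet] = {
    ps.name: ps
    for ps in (
        PrimerSet("Pro341F/Pro805R", PRO341F, PRO805R),
        PrimerSet("341F/R806", BACT341F, R806),
        PrimerSet("ARC344F/Arch806R", ARC344F, ARCH806R),
    )
}

# Illumina construct scaffolds preceding the priming region: the forward
# oligo carries adapter + sequencing-primer + linker; the reverse carries
# adapter + 6-nt barcode (NNNNNN) + sequencing-primer.  Barcodes vary per
# library, so the reverse scaffold is matched with N as a wildcard.
FORWARD_SCAFFOLD = (
    "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGCTCTTCCGATCT"
    "CCTACGGGAGGCAGCAG"
)
REVERSE_SCAFFOLD = (
    "CAAGCAGAAGACGGCATACGAGATNNNNNNGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT"
)


def strip_construct(oligo: str, role: str) -> str:
    """Strip the Illumina adapter/barcode/linker scaffold from a full
    library-construct oligo, returning the priming region only.

    Returns the input unchanged (normalized) when no scaffold prefix is
    present, so already-stripped primers pass through.
    """
    seq = iupac.normalize(oligo)
    scaffold = FORWARD_SCAFFOLD if role == "forward" else REVERSE_SCAFFOLD
    pattern = "^" + scaffold.replace("N", "[ACGT]")
    m = re.match(pattern, seq)
    if m:
        return seq[m.end():]
    return seq


def read_primer_tsv(path: str | Path, strip: bool = False) -> list[PrimerSet]:
    """Read primer sets from a ``name<TAB>forward<TAB>reverse`` table.

    Lines starting with ``#`` are ignored.  With ``strip=True`` each oligo
    is first passed through :func:`strip_construct`.
    """
    sets = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated fields, "
                f"got {len(parts)}"
            )
        name, fwd, rev = parts
        if strip:
            fwd = strip_construct(fwd, "forward")
            rev = strip_construct(rev, "reverse")
        sets.append(
            PrimerSet(
                name,
                DegeneratePrimer(f"{name}_F", fwd, "forward"),
                DegeneratePrimer(f"{name}_R", rev, "reverse"),
            )
        )
    if not sets:
        raise ValueError(f"{path}: no primer sets found")
    return sets
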