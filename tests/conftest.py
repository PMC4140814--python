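"""Shared fixtures: an independent set-based matching oracle and small
planted databases."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ampliscan.iupac import IUPAC_SETS, reverse_complement
from ampliscan.primers import BUILTIN_SETS, PrimerSet
from ampliscan.seqio import ReferenceRecord
from ampliscan.synth import PlantSpec, generate_reference_db

IUPAC_CODES = sorted(IUPAC_SETS)


def oracle_mismatches(primer_seq: str, window: str, mode: str) -> int:
    """Positionwise mismatch count straight from the IUPAC set definitions
    (pure-Python sets; shares nothing with the bitmask matcher)."""
    assert len(primer_seq) == len(window)
    mm = 0
    for p, t in zip(primer_seq, window):
        ps, ts = IUPAC_SETS[p], IUPAC_SETS[t]
        ok = ts <= ps if mode == "subset" else bool(ps & ts)
        mm += not ok
    return mm


def oracle_best_match(primer_seq: str, seq: str, k_max: int, mode: str):
    """Exhaustive offset x strand scan with the same tie-break contract
    (fewest mismatches, plus strand first, lowest start)."""
    L = len(primer_seq)
    candidates = []
    for strand, pseq in (("+", primer_seq), ("-", reverse_complement(primer_seq))):
        for start in range(len(seq) - L + 1):
            mm = oracle_mismatches(pseq, seq[start : start + L], mode)
            if mm <= k_max:
                candidates.append((mm, strand != "+", start))
    if not candidates:
        return None
    mm, minus, start = min(candidates)
    return ("-" if minus else "+", start, mm)


def random_iupac(rng: np.random.Generator, n: int, ambiguous_frac: float = 0.0) -> str:
    """Random sequence over A/C/G/T with an admixture of ambiguity codes."""
    out = []
    for _ in range(n):
        if ambiguous_frac and rng.random() < ambiguous_frac:
            out.append(IUPAC_CODES[rng.integers(len(IUPAC_CODES))])
        else:
            out.append("ACGT"[rng.integers(4)])
    return "".join(out)


@pytest.fixture(scope="session")
def pro_set() -> PrimerSet:
    return BUILTIN_SETS["Pro341F/Pro805R"]


@pytest.fixture(scope="session")
def planted_db(pro_set):
    """100 Bacteria records: 90 perfect sites, 10 with two forward
    mismatches — coverage 90/100 at k_max=1 by construction."""
    specs = [
        PlantSpec("Bacteria", 90, 0, 0, record_length=600),
        PlantSpec("Bacteria", 10, 2, 0, record_length=600),
    ]
    return generate_reference_db(specs, pro_set, seed=11)


@pytest.fixture()
def random_record():
    def make(rng: np.random.Generator, n: int, ambiguous_frac: float = 0.0):
        return ReferenceRecord("r", random_iupac(rng, n, ambiguous_frac))

    return make
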