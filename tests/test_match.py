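"""Primer placement: mismatch counting, best placement vs an exhaustive
oracle, pairing into amplicons, and strand symmetry."""

import numpy as np
import pytest

from ampliscan.iupac import expand_degenerate, reverse_complement
from ampliscan.match import (
    best_match,
    count_mismatches,
    find_matches,
    match_primer_set,
)
from ampliscan.primers import BACT341F, PRO341F, PRO805R, UNI340F, DegeneratePrimer
from ampliscan.seqio import ReferenceRecord

from conftest import oracle_best_match, oracle_mismatches, random_iupac

# the 16S window carried by Verrucomicrobia-like sequences: C at the 9th
# position, which the plain bacterial primer rejects and the N accepts
VERRUCO_WINDOW = "CCTACGGGCGGCAGCAG"


class TestCountMismatches:
    def test_ninth_base_mismatch_resolved_by_n(self):
        assert count_mismatches(BACT341F, VERRUCO_WINDOW) == 1
        assert count_mismatches(PRO341F, VERRUCO_WINDOW) == 0

    def test_primer_matches_own_expansions(self):
        for concrete in expand_degenerate(PRO341F.sequence):
            assert count_mismatches(PRO341F, concrete) == 0
            assert count_mismatches(PRO341F, concrete, mode="subset") == 0

    def test_all_positions_differ(self):
        assert count_mismatches("ACGT", "TGCA") == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_mismatches(PRO341F, "ACGT")

    def test_agrees_with_set_oracle_on_random_windows(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(5, 25))
            p = random_iupac(rng, n, ambiguous_frac=0.25)
            w = random_iupac(rng, n, ambiguous_frac=0.25)
            for mode in ("intersection", "subset"):
                assert count_mismatches(p, w, mode) == oracle_mismatches(p, w, mode)


def _plant(rng, primer, n_before, n_after, subs=0):
    """A record with one primer expansion planted; substituted positions
    get a base outside the primer's set so they count as mismatches."""
    import ampliscan.iupac as iupac

    site = list(sorted(expand_degenerate(primer.sequence))[0])
    mutable = [
        i for i, c in enumerate(primer.sequence) if len(iupac.IUPAC_SETS[c]) < 4
    ]
    for i in list(rng.choice(mutable, size=subs, replace=False)):
        site[i] = sorted(set("ACGT") - iupac.IUPAC_SETS[primer.sequence[i]])[0]
    for _ in range(100):
        seq = (
            random_iupac(rng, n_before) + "".join(site) + random_iupac(rng, n_after)
        )
        rec = ReferenceRecord("r", seq)
        spurious = [
            m
            for m in find_matches(primer, rec, k_max=2)
            if not (m.strand == "+" and m.start == n_before)
        ]
        if not spurious:
            return rec
    raise AssertionError("could not build a spurious-free background")


class TestBestMatch:
    def test_planted_verbatim(self):
        rng = np.random.default_rng(0)
        rec = _plant(rng, PRO341F, 50, 433)
        m = best_match(PRO341F, rec, k_max=1)
        assert (m.strand, m.start, m.mismatches) == ("+", 50, 0)
        assert m.end - m.start == len(PRO341F)

    def test_two_substitutions_need_budget_two(self):
        rng = np.random.default_rng(1)
        rec = _plant(rng, PRO341F, 50, 433, subs=2)
        assert best_match(PRO341F, rec, k_max=1) is None
        m = best_match(PRO341F, rec, k_max=2)
        assert m.mismatches == 2 and m.start == 50

    def test_primer_longer_than_record_returns_none(self):
        rec = ReferenceRecord("short", "ACGTACGT")
        assert best_match(PRO341F, rec) is None

    def test_kmax_monotonicity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rec = ReferenceRecord("r", random_iupac(rng, 200, 0.05))
            p = DegeneratePrimer("p", random_iupac(rng, 12, 0.2), "forward")
            hits = [
                {(m.strand, m.start) for m in find_matches(p, rec, k_max=k)}
                for k in (0, 1, 2)
            ]
            assert hits[0] <= hits[1] <= hits[2]

    @pytest.mark.parametrize("mode", ["intersection", "subset"])
    def test_oracle_equivalence_randomized(self, mode):
        """best_match must agree with the exhaustive positionwise oracle
        on randomized primers/records, ambiguity codes included."""
        rng = np.random.default_rng(42)
        n_with_hit = 0
        for i in range(200):
            plen = int(rng.integers(10, 21))
            rlen = int(rng.integers(plen, 301))
            k_max = int(rng.integers(0, 3))
            primer = DegeneratePrimer("p", random_iupac(rng, plen, 0.2), "forward")
            seq = random_iupac(rng, rlen, 0.1)
            if i % 2 == 0:
                # splice a (possibly substituted, possibly minus-strand)
                # copy of the primer in; the oracle judges independently
                site = sorted(expand_degenerate(primer.sequence))[0]
                site = list(site)
                for j in rng.choice(plen, size=int(rng.integers(0, 4)), replace=False):
                    site[j] = "ACGT"[rng.integers(4)]
                site = "".join(site)
                if rng.random() < 0.5:
                    site = reverse_complement(site)
                pos = int(rng.integers(0, rlen - plen + 1))
                seq = seq[:pos] + site + seq[pos + plen :]
            rec = ReferenceRecord("r", seq)
            got = best_match(primer, rec, k_max=k_max, mode=mode)
            want = oracle_best_match(primer.sequence, rec.seq, k_max, mode)
            if want is None:
                assert got is None
            else:
                n_with_hit += 1
                assert (got.strand, got.start, got.mismatches) == want
        assert n_with_hit > 10  # the comparison actually exercised hits


class TestExpansionSubsetMonotonicity:
    """Relaxing a primer position can only reduce mismatch counts: the
    prokaryotic forward primer (N at position 9) is bounded above by both
    narrower forward primers on every window."""

    @pytest.mark.parametrize("narrower", [BACT341F, UNI340F])
    def test_on_random_windows(self, narrower):
        rng = np.random.default_rng(7)
        for _ in range(500):
            w = random_iupac(rng, len(PRO341F), ambiguous_frac=0.1)
            assert count_mismatches(PRO341F, w) <= count_mismatches(narrower, w)

    def test_on_planted_records(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            rec = _plant(rng, BACT341F, int(rng.integers(10, 60)), 200)
            wide = best_match(PRO341F, rec, k_max=2)
            narrow = best_match(BACT341F, rec, k_max=2)
            assert narrow is not None and wide is not None
            assert wide.mismatches <= narrow.mismatches


def _paired_record(pad=100, insert=420):
    rng = np.random.default_rng(3)
    fwd_site = sorted(expand_degenerate(PRO341F.sequence))[0]
    rev_site = sorted(expand_degenerate(PRO805R.sequence))[0]
    seq = (
        random_iupac(rng, pad)
        + fwd_site
        + random_iupac(rng, insert)
        + reverse_complement(rev_site)
        + random_iupac(rng, pad)
    )
    return ReferenceRecord("amp", seq)


class TestMatchPrimerSet:
    def test_planted_pair_yields_458nt_amplicon(self, pro_set):
        rec = _paired_record()
        hit = match_primer_set(pro_set, rec, k_max=1)
        assert hit is not None
        assert hit.amplicon_length == 17 + 420 + 21 == 458
        assert hit.strand == "+"
        assert hit.total_mismatches == 0

    def test_missing_reverse_site_gives_none(self, pro_set):
        rng = np.random.default_rng(4)
        rec = _plant(rng, PRO341F, 100, 441)
        assert match_primer_set(pro_set, rec, k_max=1) is None

    def test_reverse_complemented_record_hits_minus_strand(self, pro_set):
        rec = _paired_record()
        rc = ReferenceRecord("amp_rc", reverse_complement(rec.seq))
        plus = match_primer_set(pro_set, rec)
        minus = match_primer_set(pro_set, rc)
        assert minus is not None and minus.strand == "-"
        assert minus.amplicon_length == plus.amplicon_length == 458
        n = len(rec.seq)
        assert minus.amplicon_start == n - plus.amplicon_end

    def test_amplicon_bounds_respected(self, pro_set):
        rec = _paired_record()
        assert match_primer_set(pro_set, rec, amplicon_bounds=(100, 400)) is None
        assert match_primer_set(pro_set, rec, amplicon_bounds=(458, 458)) is not None

    def test_strand_restriction(self, pro_set):
        rc = ReferenceRecord("rc", reverse_complement(_paired_record().seq))
        assert match_primer_set(pro_set, rc, search_minus_strand=False) is None
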