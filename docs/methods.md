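# Methods

## Degenerate-primer matching

A primer is a string over the 15-letter IUPAC alphabet; each letter
denotes a non-empty subset of {A, C, G, T}, and the primer denotes the
Cartesian product of those subsets (its *expansions*). Matching is
**ungapped**: annealing tolerance is positional, so placements are scored
by a Hamming-style count of rejecting positions, never by edit distance.
Sequences are encoded as 4-bit occupancy masks (A=1, C=2, G=4, T=8) and
all offsets of a record are scored at once with vectorised bitwise
operations; the same arithmetic evaluated per-position with Python sets
serves as the independent oracle in the test suite.

Two conventions govern ambiguity codes in the **target**:

* `intersection` (default): position matches when primer and target base
  sets overlap. An `N` in a database sequence — which reflects base-calling
  uncertainty, not primer-template chemistry — never counts as a mismatch.
  Penalising it would deflate coverage for reasons unrelated to primer
  design, which is why this is the default.
* `subset`: the target set must be contained in the primer set. Strictly
  stronger; exposed for sensitivity analysis.

The primer's degeneracy is always authoritative (the comparison is not
symmetric). Both strands are searched by default, since public 16S
deposits occur in either orientation; minus-strand placements are found by
scanning the reverse-complemented primer mask along the plus strand
(complementation is a bijection on base sets, so mismatch counts are
strand-invariant) and reported in plus-strand coordinates. Ties are broken
deterministically: fewest mismatches, plus strand before minus, lowest
start.

A **primer-set hit** requires both oligos to place productively on the
same strand — forward site 5′ of the reverse site — with each within
`k_max` (default 1) and the inclusive amplicon inside configurable bounds.
The bounds default to [100, 2000] nt: the true V3–V4 product is ~465 nt,
and deliberately wide bounds avoid false negatives from unusual
insertions while still rejecting degenerate pairings across a chromosome.
Among multiple admissible pairs the one minimising total mismatches, then
amplicon length, then start position is reported. Whether a published
coverage table counted paired placements or independent oligo matches is
generally unknowable from the table alone, so the pair-wise rule is the
default and `per_oligo=True` additionally reports each oligo's
independent hit counts for comparison.

## Coverage statistics

Coverage of a group is `100 · hits / queries` over the records assigned
to that group at the requested rank (default: domain). Records whose
lineage lacks the rank are counted under `unassigned` and remain in the
global denominator — they are never silently dropped. References are
pre-filtered to length **strictly greater than** 1,200 nt by default;
short partial deposits cannot be scored fairly because an absent priming
site is indistinguishable from a mismatching one. Rates are rounded
half-up to one decimal at the report layer only; hit and query counts are
additive under database partition, rates are not.

The arithmetic, not any particular database snapshot, is the contract:
reproducing a historical table's absolute counts would require the exact
versioned reference release and its quality flags, which is out of scope.
The printed hits/queries pairs themselves are carried as inputs and
pushed through the same rounding path.

## Read merging and quality filtering

Mate pairs in standard orientation are joined on the best
suffix(R1)/prefix(rc R2) overlap. Defaults mirror the published defaults
of fastq-join, the tool whose behaviour this module reproduces: minimum
overlap 6 nt, at most 8% of overlap positions mismatching. The admissible
overlap maximising matched positions wins, longer overlaps breaking ties;
within the overlap the higher-quality base is kept and the merged quality
is the positionwise maximum. This consensus rule is intentionally simple —
no posterior quality recalculation — because downstream filtering only
thresholds at Q20.

The quality rule is applied to the **joined** read (the natural order of
operations; a flagless helper applies it per-mate if wanted): a read
passes when strictly more than 99% of its bases have quality ≥ 20
(`>99%` is implemented as a strict inequality exactly as conventionally
stated, so 5 sub-threshold bases in a 500-nt read fail while 4 pass), and
any read containing an ambiguity code is discarded first. Accounting is
total: `pairs_in = merged + merge_failed` and
`merged = passed + failed_quality + dropped_ambiguous` are asserted on
every run.

## qPCR arithmetic

* Plasmid standard copies: `m · N_A / (L · 660)` with N_A = 6.022×10²³
  and 660 g/mol per bp hard-coded as 330 Da × 2 nucleotides — fidelity to
  the conventional lab calculation over the more precise 649.7 g/mol.
* Standard curve: ordinary least squares of Ct on log10(copies)
  (scipy's linear regression), requiring ≥3 distinct positive copy
  levels. Efficiency is `10^(−1/slope) − 1`; a non-negative slope flags
  the curve invalid (a flat dilution series cannot quantify anything).
* Unknowns: `copies = 10^((Ct − intercept)/slope)`. Ct values outside
  the standards' range are extrapolated with a warning rather than
  rejected — rejecting them would silently censor low-abundance groups.
* Abundance ratio: `100 · B / (A + B)`, undefined (None, not 0) when
  both totals are zero. One implementation serves every group pairing
  (Archaea vs all prokaryotes, or one archaeal class vs another); the
  complementary-sum identity `r(a,b) + r(b,a) = 100` is property-tested.
  No per-genome 16S copy-number correction is applied — the statistic is
  a ratio of gene copies, not of cells.

## Synthetic data: what it emulates and what it does not

`generate_reference_db` plants, in each record, one forward site and one
reverse site drawn from the primer's expansions and then substitutes
exactly the requested number of positions, each substitution chosen
*outside* the primer's base set at that position so the planted count
equals the Hamming count by construction (positions where the primer has
`N` admit no countable mismatch and raise an error if demanded). The
surrounding background is uniform-GC (0.5 by default, configurable)
random sequence, rejection-sampled — up to 100 redraws, then a hard
error — until an exhaustive set-based scan confirms the planted
placements are the **only** placements of either primer within the
verification budget (k=2). The emitted truth table is therefore exact,
and downstream coverage checks compare against it rather than re-deriving
expectations.

`generate_paired_reads` reads both ends of each amplicon (251 nt by
default, the common paired-end read length, over the ~458 nt V3–V4
product, giving a ~44 nt overlap), assigns each pair a fate up front —
pass, fail-quality, or ambiguous — and plants the evidence in the R1
overhang *outside* the overlap, where mate-consensus cannot repair it:
fail-quality pairs receive exactly `ceil(n·(1−min_frac))` sub-Q20
positions, ambiguous pairs one `N`. Base-call errors, when enabled, are
likewise confined to the overhang so the merge outcome is unaffected.

All randomness flows through one numpy generator seeded per call and
consumed in a documented order, so a fixed seed reproduces byte-identical
FASTA/FASTQ.

This generator emulates *placement geometry and bookkeeping*, not
sequencing physics. Real amplicon data additionally shows
position-dependent quality decay, correlated errors, chimeras,
length-variable amplicons across taxa, PCR amplification bias, and
taxonomy that is wrong or incomplete in the reference. Passing tests on
synthetic data therefore demonstrate that the matching, counting and
filtering rules are implemented exactly — not that any particular primer
will perform equivalently on a real community.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately small instances — records
of 600–1,300 nt, databases of tens of records, 10 seeded generator
configurations, 200 randomized oracle instances, 100-pair read sets, and
1,000 random windows for the mismatch-bound property — sizes at which
exhaustive brute-force oracles remain exact, which is the point of the
synthetic substrate. Rounding is decimal half-up (never banker's);
coordinates are 0-based half-open internally and 1-based inclusive in
report files, which state so in their headers; case and `U`/`T` are
normalized on input; gap characters are stripped from reference
sequences by default (aligned exports are common) with a strict flag to
refuse them.

## Known limitations

No thermodynamic scoring (Tm, ΔG, 3′-terminal mismatch weighting), no
indel-tolerant matching, no chimera simulation or detection, no
multi-plate qPCR calibration or efficiency-corrected relative
quantification, and taxonomy handling trusts the provided lineages as
given. The per-oligo versus paired hit-counting conventions can differ on
real databases; both are reported so the choice is inspectable.
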