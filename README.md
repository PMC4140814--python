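# ampliscan

In-silico coverage evaluation of degenerate 16S rRNA primers, amplicon
paired-read quality control, and qPCR absolute-quantification arithmetic —
with seeded synthetic-data generators so the whole pipeline is testable
offline.

## The problem

Microbial community surveys amplify the 16S rRNA gene with "universal"
PCR primers and sequence the product. Whether a survey sees a taxon at
all — and at what apparent abundance — depends on how well the primer
anneals to that taxon's 16S sequence: even a single internal
primer–template mismatch can underrepresent a group by orders of
magnitude. Primer design therefore hinges on a *coverage* statistic: the
percentage of sequences in a reference database (grouped by taxon, e.g.
the domains *Bacteria* and *Archaea*) that a primer pair matches within a
small mismatch budget, conventionally ≤1.

`ampliscan` implements the computational substrate of that analysis for
V3–V4 primer sets such as the prokaryotic universal pair
Pro341F (`CCTACGGGNBGCASCAG`) / Pro805R (`GACTACNVGGGTATCTAATCC`):

* **Degenerate matching** — a primer position with IUPAC code *c* accepts
  target base *t* when their base sets overlap (so a primer `N` accepts
  anything, and the `N` at position 9 of Pro341F absorbs the mismatch
  that the plain bacterial primer 341F has against *Verrucomicrobia*
  sequences). A placement's score is its Hamming-style mismatch count;
  the best placement over every offset and both strands is reported if it
  is within `k_max`.
* **Coverage tables** — per-taxon `hits / queries` and the rate
  `100·hits/queries` rounded half-up to one decimal, over references
  longer than 1,200 nt, for one or several competing primer sets.
* **Read QC** — mate pairs are joined on their best 3′ overlap
  (fastq-join semantics: ≥6 nt overlap, ≤8% overlap mismatches; the
  higher-quality base wins) and kept only if strictly more than 99% of
  bases have Phred quality ≥20 and no base call is ambiguous.
* **qPCR arithmetic** — plasmid-standard copies
  `m · N_A / (L · 660 g/mol/bp)`, the standard curve
  `Ct = slope · log10(copies) + intercept` with efficiency
  `10^(−1/slope) − 1`, inversion for unknowns, and the abundance ratio
  `100 · B / (A + B)` (e.g. archaeal copies as a percentage of all
  prokaryotic copies).
* **Synthetic data** — reference databases with priming sites planted at
  *exactly* specified mismatch counts (background verified
  primer-free by brute force) and amplicon mate pairs with planted QC
  fates, each with a machine-checkable truth table.

## Worked example

Simulate a database of 14 references — 8 *Bacteria* with perfect priming
sites drawn from the Pro341F/Pro805R expansions, 2 *Bacteria* with two
forward-site mismatches, 4 *Archaea* with one — then score two primer
sets against it:

```bash
$ ampliscan simulate refdb --spec db.yaml --seed 17 --out-prefix sim/db
14 records -> sim/db.fasta
$ ampliscan coverage --db sim/db.fasta --tax sim/db.tax.tsv \
    --builtin Pro341F/Pro805R --builtin 341F/R806 --out coverage.tsv
$ cat coverage.tsv
# primer-set coverage by taxon (rates in %, half-up, 1 dp)
primer_set      target  hits    queries coverage_percent
Pro341F/Pro805R Archaea 4       4       100.0
Pro341F/Pro805R Bacteria        8       10      80.0
341F/R806       Archaea 0       4       0.0
341F/R806       Bacteria        2       10      20.0
```

The prokaryotic set recovers every record within one mismatch except the
two with two planted forward mismatches (8/10 = 80.0%). The narrower
bacterial set only hits the planted sites that happen to fall inside its
smaller expansion set — every expansion of 341F is an expansion of
Pro341F, never the other way round — and misses *Archaea* entirely.

Simulate reads from those amplicons and run QC (100 pairs, of which 10
are planted to fail the quality rule and 5 carry an ambiguous base):

```bash
$ ampliscan simulate reads --db sim/db.fasta --spec reads.yaml --seed 5 \
    --out-prefix sim/reads
$ ampliscan qc --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --out merged.fasta --report qc.json
100 pairs: 100 merged, 85 passed, 10 failed quality, 5 ambiguous
```

The qPCR side, as a library call:

```python
>>> from ampliscan import plasmid_copies, fit_standard_curve, quantify, abundance_ratio
>>> plasmid_copies(mass_grams=1e-6, construct_length_bp=3015 + 458)
2.627e+11                      # copies in a 1 µg prep of vector + insert
>>> curve = fit_standard_curve(standards)   # [(copies, Ct), ...]
>>> curve.slope, curve.efficiency
(-3.3219, 1.00)                # perfect doubling: slope = -1/log10(2)
>>> bact, arch = quantify(14.2, curve), quantify(20.1, curve)
>>> abundance_ratio(bact, arch)
1.6                            # archaeal % of all prokaryotic copies
```

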