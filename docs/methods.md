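# Methods

## Read classification model

A sequencing read is classified against an annotated mature small-RNA
sequence by exact, 5′-locked prefix matching. The 5′ genome-matched component
(5GMC) is the longest common prefix of read and reference; the first mismatch
terminates it even if downstream bases agree again, and it is capped at the
reference 3′ end. Trim length is reference length minus 5GMC; every base
downstream of the 5GMC is tail, *including* bases that happen to be
genome-templated extensions beyond the annotated 3′ end. This cap makes the
annotated sequence itself the coordinate system and removes any dependence on
genome alignment. Reads whose 5GMC is 12 nt or shorter are excluded
(`min_gmc = 13`); reads whose 5′ base differs from every reference are
excluded by construction of the prefix match.

Assumptions this encodes:

* 5′ ends of miRNAs are precise; 5′ isomiRs are deliberately out of scope.
* No sequencing-error model: an internal substitution truncates the 5GMC and
  reclassifies the remainder as tail. The synthetic tests quantify this
  misclassification rather than correcting it.
* A read matching several annotated sequences equally well (miRNA families)
  is shared fractionally (weight 1/k) by default, so family-shared abundance
  is never double-counted; a `unique` mode (lexicographically first id)
  exists for comparability with single-assignment tools.
  Tie-breaking is maximal 5GMC first, then minimal trim, then id order.

## Identifiability and canonical coordinates

The decomposition (trim, tail) is not injective: a 1-nt-trimmed molecule that
then received a tail starting with exactly the trimmed base is byte-identical
to the untrimmed molecule with a 1-nt-shorter tail. No classifier can
distinguish them. The simulator therefore records, next to the drawn
coordinates, the *canonical* coordinates obtained by greedily re-matching
leading tail bases against the trimmed template (implemented independently of
the profiling code), and recovery is scored against the canonical truth. The
same fact constrains validation of tail composition: with trimming active, a
tail base equal to the next templated base is absorbed into the 5GMC, so
"recovered composition equals emission probabilities" is only testable in a
tailing-only regime; with trimming, recovered composition is compared against
the canonical truth instead.

## Ingest

Adapter removal searches for the leftmost exact occurrence of the adapter's
first `min_overlap` (default 8) bases; this also recognizes a partial
terminal adapter on 51-cycle reads whose insert pushes the adapter past the
final cycle. No mismatches are tolerated in the seed; mismatch-tolerant
trimming is out of scope. Inserts outside 13–30 nt are rejected (13 is the
minimum that can ever pass the 5GMC filter; 30 covers 18–25-nt species plus
tails), as are reads containing N. Unique insert sequences are collapsed to
(sequence, count) records ordered by descending count then lexicographically;
counts — not unique sequences — are the abundance unit everywhere downstream.

## Summaries

All percentages are abundance-weighted (count × assignment weight) over the
analyzed total, hence invariant to uniform depth scaling. Tail composition is
pooled: abundance-weighted nucleotide counts across all tail positions
divided by pooled tail length — not the mean of per-read fractions — which
keeps raw counts additive over disjoint coordinate subsets (e.g. the
(trim, tail) = (1, 1) subset used to exclude processing artifacts).
Coordinate matrices store unbounded trim/tail axes; display capping (trim ≤ 8,
tail ≤ 14 by default) aggregates into edge bins at plot time only. The
renormalized mode removes the (0, 0) annotated species and rescales the
variants to 100 %; requesting it when all mass is at the origin is an error.
Matrix totals are asserted to 100 within 1e-9.

The ≥22-nt proportion contrast between genotypes is offered two ways: a
one-way ANOVA F on replicate-level percents, and an uncorrected (textbook)
2×2 chi-square on pooled counts. With only two replicates per group the F
test has (1, 2) degrees of freedom and cannot produce very small p-values
regardless of effect size; the pooled chi-square is the branch that can
support claims at the 1e-4 level, and its statistic matches the closed form
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) exactly. Degenerate inputs (identical
groups, zero within-group variance) return p = 1 and p = 0 respectively.

## Synthetic libraries

The generator emulates indexed single-end 51-cycle sequencing: per read it
draws a reference (uniform or abundance-weighted), a trim length, a tail
length, i.i.d. tail bases from per-nucleotide emission probabilities,
optional corruption (±1-nt 5′ shift, or one internal substitution), then
appends the 3′ adapter and pads/truncates to 51 cycles. Draws whose trim
would leave a 5GMC below 13 nt are redrawn and tallied. Everything is
deterministic given the seed; FASTQ is emitted in the DNA alphabet with
constant quality, as a sequencer would.

Four preset regimes emulate the genotype series:

| regime            | trimmed mass | tailed mass | pU    |
|-------------------|-------------|-------------|-------|
| wild-type         | 0.07        | 0.08        | 0.767 |
| hen1              | 0.60        | 0.70        | 0.884 |
| hen1-heso1        | 0.72        | 0.38        | 0.903 |
| hen1-heso1-urt1   | 0.78        | 0.10        | 0.391 |

The uridine emission probabilities are the reported per-genotype tail-uridine
preferences; the trim/tail length distributions are plausible settings chosen
once to reproduce the qualitative regime structure (wild type concentrated at
(0, 0); broad U-rich tailing plus a 4-nt trim mode — the 17-nt 5GMC shoulder
of 21-nt species — in *hen1*; progressive loss of tailing and gain of
trimming through the double and triple mutants). They are **not** estimates
of the real length distributions, and simulated percentages are not meant to
equal any published dataset-level value. Tail emission is i.i.d. per
position (no within-tail ordering model); trim and tail lengths are
independent by default, with an optional per-trim tail-length table for
coupling. What passing tests show is that the *pipeline* recovers whatever
structure the generator put in; they do not show that real libraries have
that structure, and real data additionally contain sequencing errors,
PCR duplicates, 5′ heterogeneity above the simulated rate, and reference
annotation mismatches that the generator does not model.

## Problem sizes and numerical choices

The test suite runs the zero-noise round trip at 4 genotypes × 2 replicates ×
20,000 reads, parameter recovery at 200,000 reads (tail-composition deviation
bounded by 3 binomial standard errors on the pooled tail-nucleotide count;
length distributions by total-variation 0.01 against canonical truth), the
5′-lock check at 100,000 reads with a 10 % variant rate (binomial 3σ bound on
the unassigned tally), and the splitter/brute-force oracle comparison on
10,000 randomized pairs spanning trims 0–8, tails 0–14, internal mismatches
and 5′ shifts. The acceptance script uses 20 references (20–22 nt, 21 nt
dominant, kept ≤ 22 nt so maximal tails stay inside the insert window) at
50,000 reads per library. Fractional weights are exact (built from rational
1/k); percentage assertions use absolute tolerances of 1e-9.

## Known limitations

* No mismatch-tolerant matching anywhere: one internal sequencing error
  reclassifies the read's 3′ end. Error rates above ~1 % visibly inflate
  long-tail bins.
* Tail composition near the annotated 3′ end is partially unidentifiable
  under simultaneous trimming and tailing (see canonical coordinates); all
  reported compositions are compositions of *identifiable* tails.
* The ANOVA branch of the proportion comparison is underpowered at two
  replicates by construction; it is reported alongside, not instead of, the
  pooled chi-square.
* Collapsed-FASTA ingestion trusts the `_xN` header counts; no validation
  against raw files is possible.
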