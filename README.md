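# mirtail

5′-anchored profiling of small-RNA 3′-end **trimming** and non-templated
**tailing** from sequencing reads, with a ground-truthed synthetic library
generator for the *Arabidopsis* HEN1/HESO1/URT1 genotype regimes.

## The problem

Plant miRNAs and siRNAs carry a 2′-*O*-methyl group on their 3′-terminal
ribose, deposited by HEN1. When methylation is lost, terminal
nucleotidyltransferases (HESO1, URT1) add non-templated nucleotides — mostly
uridines — to the 3′ end, and 3′→5′ exonucleolytic trimming shortens the
molecule. Quantifying these two antagonistic modifications from small-RNA
sequencing requires classifying every read relative to its annotated mature
sequence without a genome aligner second-guessing which 3′ bases are
"templated".

## The algorithm

Each read *r* is compared to an annotated mature sequence *m* with the 5′ end
locked (reads whose first base differs are excluded; no mismatches allowed).
The **5′ genome-matched component** is the longest mismatch-free common
prefix, capped at the annotated 3′ end:

    5GMC(r, m) = max { k ≤ |m| : r[1..k] = m[1..k] }

and the read decomposes into coordinates

    trim = |m| − 5GMC        (nt removed from the annotated 3′ end)
    tail = r[5GMC+1 .. |r|]  (every base downstream of the 5GMC,
                              templated or not)

Only reads with 5GMC > 12 nt are analyzed. Coordinate (trim, tail) = (0, 0)
is the exact annotated species. On these records the package computes
read-length and 5GMC-length distributions, per-length tailing/trimming
extents (% of analyzed reads), pooled tail nucleotide composition
(abundance-weighted nucleotide counts ÷ total tail length), two-dimensional
(trim, tail) percentage matrices — optionally renormalized to 100 % after
removing the annotated species — and a two-group proportion comparison
(replicate-level one-way ANOVA F, or a pooled 2×2 chi-square).

## Worked example

Profile a simulated *hen1*-regime library against two mature miRNAs:

```python
from mirtail import (simulate_library, profile_library, evaluate_recovery,
                     tail_composition, coordinate_matrix, long_species_fraction)
from mirtail.reference_io import ReferenceEntry, ReferenceSet
from mirtail.read_ingest import process_library
from mirtail.synthetic_data import genotype_params, write_fastq

refs = ReferenceSet(entries=[
    ReferenceEntry(ids=("miR158a",), sequence="UCCCAAAUGUAGACAAAGCA"),
    ReferenceEntry(ids=("miR173",),  sequence="UUCGCUUGCAGAGAGAAAUCAC"),
])
params = genotype_params("hen1", depth=50_000, seed=7)
records, truth = simulate_library(refs, params, library_id="hen1_rep1")
write_fastq(records, "hen1_rep1.fastq")

reads, meta = process_library("hen1_rep1.fastq", adapter=params.adapter,
                              library_id="hen1_rep1")
table = profile_library(reads, refs)
comp = tail_composition(table)
print(f"tailed         : {comp.extent_percent:.1f}%")
print(f"tail U fraction: {comp.fraction_by_nucleotide['U']:.3f}")
print(f">=22 nt        : {long_species_fraction(table, threshold=22):.1f}%")
```

prints

```
tailed         : 67.8%
tail U fraction: 0.890
>=22 nt        : 45.4%
```

i.e. in this methylation-defective regime two-thirds of reads carry a 3′
tail, the tails are 89 % uridine, and 45 % of species exceed the annotated
21-nt size. `evaluate_recovery(truth, table)` reports an exact-recovery
fraction of 1.000: on uncorrupted reads the profiler returns every simulated
(trim, tail) coordinate exactly (in its canonical, identifiable form — see
`docs/methods.md`).

The same pipeline runs from the shell over a YAML config:

```
mirtail simulate  -c config.yaml   # FASTQ + ground truth per library
mirtail profile   -c config.yaml   # adapter-trim, collapse, 5'-anchor split
mirtail summarize -c config.yaml   # distributions, extents, matrices, tests
mirtail plot      -c config.yaml   # bubble matrices + composition panels
```

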