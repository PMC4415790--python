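"""Synthetic small-RNA library generator with per-read ground truth.

Emulates indexed single-end 51-cycle sequencing of small-RNA libraries in
which each read is a mature-miRNA-derived insert — possibly 3'-trimmed and/or
3'-tailed with a biased nucleotide composition — followed by the 3' adapter
and, when cycles remain, downstream library sequence. Four preset parameter
regimes emulate the genotype series of the methylation-defective Arabidopsis
mutants (wild type with HEN1 methylation intact; hen1; hen1 heso1;
hen1 heso1 urt1): tailing is rare and mostly uridine on the small
unmethylated fraction in wild type, massive and U-rich when methylation is
lost, and progressively lost — while 3'-to-5' trimming grows — as the two
uridylyltransferases are removed.

Ground truth records both the drawn (trim, tail) and the *canonical*
coordinates. When a drawn tail begins with exactly the base that trimming
removed, the resulting read is mathematically indistinguishable from one with
less trimming and a shorter tail; the canonical coordinates are that maximal
reduction, and recovery is scored against them.

Tail bases are emitted i.i.d. per position. Trim and tail lengths are drawn
independently by default; an optional per-trim tail-length table
(``tail_len_dist_by_trim``) couples them, which real libraries motivate
(trimmed species are preferential tailing substrates).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mirtail.anchor_profile import MIN_GMC_LEN, ModificationTable
from mirtail.reference_io import ReferenceSet
from mirtail.summarize import NUCLEOTIDES, tail_composition

#: widely used small-RNA 3' sequencing adapter (RNA alphabet)
DEFAULT_ADAPTER = "UCGUAUGCCGUCUUCUGCUUG"

_PROB_TOL = 1e-9


@dataclass
class GenotypeParams:
    """Generator parameters for one simulated library.

    ``trim_dist`` and ``tail_len_dist`` are probability masses over trim and
    tail lengths (nt); ``tail_nt_probs`` are the per-position emission
    probabilities over {A,C,G,U} (pU is the uridylation preference);
    ``five_prime_variant_rate`` / ``internal_mismatch_rate`` corrupt reads
    with a 5' end shift (+-1 nt) or one internal substitution. ``depth`` is
    the number of reads; everything is deterministic given ``seed``.
    """

    trim_dist: dict[int, float]
    tail_len_dist: dict[int, float]
    tail_nt_probs: dict[str, float]
    depth: int
    five_prime_variant_rate: float = 0.0
    internal_mismatch_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0
    read_length: int = 51
    ref_weights: dict[str, float] | None = None
    tail_len_dist_by_trim: dict[int, dict[int, float]] | None = None

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for name, dist in (("trim_dist", self.trim_dist), ("tail_len_dist", self.tail_len_dist)):
            _check_pmf(name, dist)
        _check_pmf("tail_nt_probs", self.tail_nt_probs)
        if set(self.tail_nt_probs) - set(NUCLEOTIDES):
            raise ValueError("tail_nt_probs keys must be A/C/G/U")
        for rate in (self.five_prime_variant_rate, self.internal_mismatch_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("corruption rates must lie in [0, 1]")
        if self.tail_len_dist_by_trim is not None:
            for t, dist in self.tail_len_dist_by_trim.items():
                _check_pmf(f"tail_len_dist_by_trim[{t}]", dist)
        if not self.adapter:
            raise ValueError("adapter must be non-empty")


def _check_pmf(name: str, dist: dict) -> None:
    if not dist:
        raise ValueError(f"{name} is empty")
    values = list(dist.values())
    if any(v < 0 for v in values):
        raise ValueError(f"{name} has negative probabilities")
    if abs(sum(values) - 1.0) > 1e-6:
        raise ValueError(f"{name} must sum to 1 (got {sum(values)})")


@dataclass
class TruthRow:
    """Ground truth for one simulated read."""

    read_id: str
    ref_label: str
    drawn_trim: int
    drawn_tail: str
    canon_trim: int
    canon_tail: str
    five_prime_variant: bool
    internal_mismatch: bool


@dataclass
class SimulationTruth:
    library_id: str
    params: GenotypeParams
    rows: list[TruthRow] = field(default_factory=list)
    ref_sequences: dict[str, str] = field(default_factory=dict)
    resampled_draws: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": r.read_id,
                "ref_label": r.ref_label,
                "drawn_trim": r.drawn_trim,
                "drawn_tail": r.drawn_tail,
                "canon_trim": r.canon_trim,
                "canon_tail": r.canon_tail,
                "five_prime_variant": r.five_prime_variant,
                "internal_mismatch": r.internal_mismatch,
            }
            for r in self.rows
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class FastqRecord:
    read_id: str
    sequence: str  # DNA alphabet, as a sequencer emits it
    quality: str


def canonical_coordinates(ref_seq: str, trim: int, tail: str) -> tuple[int, str]:
    """Reduce drawn (trim, tail) to the identifiable coordinates.

    Greedily re-matches tail bases that coincide with the trimmed template:
    each such base extends the 5' genome-matched component, decrementing trim
    and shortening the tail, until either the trim is exhausted (further tail
    is beyond the annotated 3' end and stays tail) or the next tail base
    mismatches the template.
    """
    ref_len = len(ref_seq)
    while trim > 0 and tail and tail[0] == ref_seq[ref_len - trim]:
        trim -= 1
        tail = tail[1:]
    return trim, tail


def simulate_library(
    refs: ReferenceSet,
    params: GenotypeParams,
    library_id: str = "sim",
) -> tuple[list[FastqRecord], SimulationTruth]:
    """Generate one library of ``params.depth`` reads plus ground truth.

    Per read: pick a reference (uniform or ``ref_weights``); draw a trim and
    remove that many 3' bases (redrawing, with a tally, when the remaining
    5GMC would fall below the analyzable minimum); draw a tail length and
    emit that many i.i.d. bases from ``tail_nt_probs``; optionally corrupt
    with a 5' shift or an internal substitution; append the adapter and pad
    or truncate to ``read_length`` cycles. FASTQ sequences use the DNA
    alphabet (U written as T), as a sequencer emits them.
    """
    params.validate()
    if len(refs) == 0:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(params.seed)

    entries = list(refs)
    if params.ref_weights is not None:
        weights = np.array(
            [params.ref_weights.get(e.ids[0], 0.0) for e in entries], dtype=float
        )
        if weights.sum() <= 0:
            raise ValueError("ref_weights assign no mass to any reference")
        ref_probs = weights / weights.sum()
    else:
        ref_probs = np.full(len(entries), 1.0 / len(entries))

    n = params.depth
    trim_vals, trim_probs = _dist_arrays(params.trim_dist)
    tail_vals, tail_probs = _dist_arrays(params.tail_len_dist)
    nt_probs = np.array([params.tail_nt_probs.get(nt, 0.0) for nt in NUCLEOTIDES])
    pad = "A" * params.read_length
    quality = "I" * params.read_length

    truth = SimulationTruth(
        library_id=library_id,
        params=params,
        ref_sequences={e.label: e.sequence for e in entries},
    )

    # all random draws happen vectorized, up front
    ref_lens = np.array([e.length for e in entries])
    for entry in entries:
        if all(entry.length - t < MIN_GMC_LEN for t in trim_vals):
            raise ValueError(f"reference {entry.label} too short for the trim distribution")
    ref_idx = rng.choice(len(entries), size=n, p=ref_probs)
    trims = trim_vals[rng.choice(len(trim_vals), size=n, p=trim_probs)]
    invalid = ref_lens[ref_idx] - trims < MIN_GMC_LEN
    while invalid.any():
        k = int(invalid.sum())
        truth.resampled_draws += k
        trims[invalid] = trim_vals[rng.choice(len(trim_vals), size=k, p=trim_probs)]
        invalid = ref_lens[ref_idx] - trims < MIN_GMC_LEN

    tail_lens = tail_vals[rng.choice(len(tail_vals), size=n, p=tail_probs)]
    if params.tail_len_dist_by_trim is not None:
        for t, dist in params.tail_len_dist_by_trim.items():
            mask = trims == t
            if mask.any():
                tv, tp = _dist_arrays(dist)
                tail_lens[mask] = tv[rng.choice(len(tv), size=int(mask.sum()), p=tp)]
    total_tail_nt = int(tail_lens.sum())
    tail_bases = rng.choice(4, size=total_tail_nt, p=nt_probs)
    tail_offsets = np.concatenate([[0], np.cumsum(tail_lens)])

    five_prime_flags = rng.random(n) < params.five_prime_variant_rate
    shift_downstream = rng.random(n) < 0.5
    upstream_choice = rng.choice(3, size=n)
    mismatch_flags = rng.random(n) < params.internal_mismatch_rate
    mismatch_pos_u = rng.random(n)
    mismatch_alt = rng.choice(3, size=n)

    nt_str = "".join(NUCLEOTIDES)
    records: list[FastqRecord] = []
    for i in range(n):
        entry = entries[ref_idx[i]]
        ref_seq = entry.sequence
        trim = int(trims[i])
        tail = "".join(
            nt_str[b] for b in tail_bases[tail_offsets[i]: tail_offsets[i + 1]]
        )
        insert = ref_seq[: len(ref_seq) - trim] + tail

        five_prime = bool(five_prime_flags[i])
        if five_prime:
            if shift_downstream[i]:
                insert = insert[1:]  # start one base downstream
            else:
                # start one base upstream: the extra base never equals the
                # annotated 5' base, so the anchor is genuinely broken
                choices = [nt for nt in NUCLEOTIDES if nt != ref_seq[0]]
                insert = choices[upstream_choice[i]] + insert
        mismatch = bool(mismatch_flags[i]) and len(insert) > 2
        if mismatch:
            pos = 1 + int(mismatch_pos_u[i] * (len(insert) - 2))
            alt = [nt for nt in NUCLEOTIDES if nt != insert[pos]]
            insert = insert[:pos] + alt[mismatch_alt[i]] + insert[pos + 1:]

        cycles = (insert + params.adapter + pad)[: params.read_length]
        read_id = f"{library_id}:read{i}"
        records.append(
            FastqRecord(read_id=read_id, sequence=cycles.replace("U", "T"), quality=quality)
        )
        canon_trim, canon_tail = canonical_coordinates(ref_seq, trim, tail)
        truth.rows.append(
            TruthRow(
                read_id=read_id,
                ref_label=entry.label,
                drawn_trim=trim,
                drawn_tail=tail,
                canon_trim=canon_trim,
                canon_tail=canon_tail,
                five_prime_variant=five_prime,
                internal_mismatch=mismatch,
            )
        )
    return records, truth


def _dist_arrays(dist: dict[int, float]) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return np.array(keys), probs / probs.sum()


def write_fastq(records: Sequence[FastqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.quality}\n")


@dataclass
class RecoveryReport:
    """Comparison of a profiled table against simulation ground truth."""

    n_reads: int
    n_uncorrupted: int
    exact_recovery_fraction: float
    tv_trim: float
    tv_tail_len: float
    estimated_nt_fractions: dict[str, float]
    true_nt_fractions: dict[str, float]
    emission_nt_probs: dict[str, float]
    unassigned_fraction: float
    corrupted_counts: dict[str, int]


def evaluate_recovery(truth: SimulationTruth, table: ModificationTable) -> RecoveryReport:
    """Score how well the profiling pipeline recovered the simulated truth.

    Exact recovery is assessed on uncorrupted reads only, against the
    canonical (identifiable) coordinates; corrupted reads are tallied
    separately. Distribution agreement is reported as total-variation
    distance between the table's abundance-weighted trim / tail-length
    distributions and the canonical truth distributions of uncorrupted reads.
    """
    if truth.library_id and table.meta.library_id and truth.library_id != table.meta.library_id:
        raise ValueError(
            f"library id mismatch: truth={truth.library_id!r} table={table.meta.library_id!r}"
        )
    by_seq: dict[str, list] = defaultdict(list)
    for rec in table.records:
        by_seq[rec.read_sequence].append(rec)

    n_ok = 0
    n_clean = 0
    true_trim: Counter = Counter()
    true_tail_len: Counter = Counter()
    true_nt: Counter = Counter()
    corrupted: Counter = Counter()
    for row in truth.rows:
        if row.five_prime_variant or row.internal_mismatch:
            if row.five_prime_variant:
                corrupted["five-prime-variant"] += 1
            if row.internal_mismatch:
                corrupted["internal-mismatch"] += 1
            continue
        n_clean += 1
        true_trim[row.canon_trim] += 1
        true_tail_len[len(row.canon_tail)] += 1
        true_nt.update(row.canon_tail)
        # the emitted insert is invariant under canonicalization: rebuild it
        # from the drawn coordinates (ref prefix plus drawn tail)
        ref_seq = truth.ref_sequences[row.ref_label]
        insert = ref_seq[: len(ref_seq) - row.drawn_trim] + row.drawn_tail
        for rec in by_seq.get(insert, []):
            if (
                rec.trim_len == row.canon_trim
                and rec.tail_seq == row.canon_tail
                and any(rid in rec.ref_ids for rid in row.ref_label.split(","))
            ):
                n_ok += 1
                break

    est_trim: Counter = Counter()
    est_tail_len: Counter = Counter()
    for rec in table.records:
        est_trim[rec.trim_len] += rec.mass
        est_tail_len[rec.tail_len] += rec.mass

    est_comp = tail_composition(table) if table.records else None
    est_fracs = (
        est_comp.fraction_by_nucleotide
        if est_comp is not None and not est_comp.empty
        else {nt: float("nan") for nt in NUCLEOTIDES}
    )
    total_true_nt = sum(true_nt.values())
    true_fracs = {
        nt: (true_nt[nt] / total_true_nt if total_true_nt else float("nan"))
        for nt in NUCLEOTIDES
    }
    denominator = table.analyzed_total + table.unassigned_total
    return RecoveryReport(
        n_reads=len(truth.rows),
        n_uncorrupted=n_clean,
        exact_recovery_fraction=(n_ok / n_clean) if n_clean else float("nan"),
        tv_trim=_total_variation(true_trim, est_trim),
        tv_tail_len=_total_variation(true_tail_len, est_tail_len),
        estimated_nt_fractions=est_fracs,
        true_nt_fractions=true_fracs,
        emission_nt_probs={nt: truth.params.tail_nt_probs.get(nt, 0.0) for nt in NUCLEOTIDES},
        unassigned_fraction=(table.unassigned_total / denominator) if denominator else 0.0,
        corrupted_counts=dict(corrupted),
    )


def _total_variation(p: Counter, q: Counter) -> float:
    tp, tq = sum(p.values()), sum(q.values())
    if tp == 0 or tq == 0:
        return float("nan")
    support = set(p) | set(q)
    return 0.5 * sum(abs(p[k] / tp - q[k] / tq) for k in support)


# ---------------------------------------------------------------------------
# Preset genotype regimes
#
# The four regimes mirror the qualitative structure of the Arabidopsis
# methylation series: wild type (HEN1 methylation intact) keeps nearly all
# mass at coordinate (0, 0) with sparse, U-rich tails on the unmethylated
# fraction; hen1 shows broad U-rich tailing (pU 0.884) plus a secondary trim
# peak 4 nt in (the 17-nt 5GMC shoulder of 21-nt species); hen1 heso1 shifts
# mass toward trimming with tails still U-dominated (pU 0.903); the triple
# mutant hen1 heso1 urt1 nearly abolishes tailing, with residual tails showing
# a strongly reduced uridine preference (pU 0.391), and trims furthest. The
# pU values are the uridine preferences reported for these genotypes; length
# distributions are plausible settings chosen to reproduce the regime
# orderings, not measured values.
# ---------------------------------------------------------------------------

GENOTYPE_PRESETS: dict[str, dict] = {
    "wild-type": dict(
        trim_dist={0: 0.93, 1: 0.04, 2: 0.02, 3: 0.01},
        tail_len_dist={0: 0.92, 1: 0.05, 2: 0.02, 3: 0.01},
        tail_nt_probs={"U": 0.767, "A": 0.120, "C": 0.060, "G": 0.053},
    ),
    "hen1": dict(
        trim_dist={0: 0.40, 1: 0.12, 2: 0.10, 3: 0.08, 4: 0.18, 5: 0.06, 6: 0.04, 7: 0.02},
        tail_len_dist={
            0: 0.30, 1: 0.20, 2: 0.15, 3: 0.12, 4: 0.09, 5: 0.06, 6: 0.04, 7: 0.02, 8: 0.02,
        },
        tail_nt_probs={"U": 0.884, "A": 0.060, "C": 0.032, "G": 0.024},
    ),
    "hen1-heso1": dict(
        trim_dist={
            0: 0.28, 1: 0.15, 2: 0.14, 3: 0.13, 4: 0.11, 5: 0.09, 6: 0.06, 7: 0.03, 8: 0.01,
        },
        tail_len_dist={0: 0.62, 1: 0.16, 2: 0.09, 3: 0.06, 4: 0.04, 5: 0.02, 6: 0.01},
        tail_nt_probs={"U": 0.903, "A": 0.050, "C": 0.025, "G": 0.022},
    ),
    "hen1-heso1-urt1": dict(
        trim_dist={
            0: 0.22, 1: 0.16, 2: 0.15, 3: 0.14, 4: 0.12, 5: 0.10, 6: 0.06, 7: 0.03, 8: 0.02,
        },
        tail_len_dist={0: 0.90, 1: 0.07, 2: 0.02, 3: 0.01},
        tail_nt_probs={"U": 0.391, "A": 0.360, "C": 0.140, "G": 0.109},
    ),
}

#: canonical ordering of the genotype series, wild type first
GENOTYPE_ORDER = ("wild-type", "hen1", "hen1-heso1", "hen1-heso1-urt1")


def genotype_params(
    name: str, depth: int = 20_000, seed: int = 0, **overrides
) -> GenotypeParams:
    """Build GenotypeParams for a preset regime (see GENOTYPE_PRESETS)."""
    if name not in GENOTYPE_PRESETS:
        raise KeyError(f"unknown genotype preset {name!r}; choose from {GENOTYPE_ORDER}")
    kwargs = {**GENOTYPE_PRESETS[name], "depth": depth, "seed": seed, **overrides}
    return GenotypeParams(**kwargs)
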