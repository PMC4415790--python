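"""Dataset-level summaries of the (trim, tail) modification landscape.

All quantities are read-abundance weighted: a record contributes
count x weight, and percentages are taken over the analyzed total (the
count-weighted number of assigned reads). This makes every percentage output
invariant to uniform scaling of all counts.

Summaries provided:

* size distributions over read length or 5GMC length;
* tailing/trimming extents — the percent of analyzed reads carrying a tail
  (or trim) of each length — with per-length tail nucleotide composition;
* tail nucleotide composition over arbitrary coordinate subsets, computed as
  pooled nucleotide counts divided by pooled tail length (abundance-weighted),
  so raw counts stay additive over disjoint subsets;
* two-dimensional (trim, tail-length) percentage matrices, optionally
  renormalized to 100% after removing the exact annotated species at (0, 0);
* the fraction of species at or above a length threshold, and a
  between-genotype proportion comparison (one-way ANOVA F on replicate
  percents, or a textbook 2x2 chi-square on pooled counts).
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirtail.anchor_profile import ModificationTable

NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass
class SizeDistribution:
    """Percent of analyzed abundance per length (read length or 5GMC length).

    ``display_cutoff`` only flags bins for display; it never alters the
    stored mass, which always sums to 100.
    """

    axis: str
    percent_by_length: dict[int, float]
    display_cutoff: float = 0.5

    def below_cutoff(self, length: int) -> bool:
        return self.percent_by_length.get(length, 0.0) < self.display_cutoff

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "axis": self.axis,
                "length": length,
                "percent": pct,
                "below_cutoff": pct < self.display_cutoff,
            }
            for length, pct in sorted(self.percent_by_length.items())
        ]
        return pd.DataFrame(rows, columns=["axis", "length", "percent", "below_cutoff"])


@dataclass
class TailCompositionSummary:
    """Tail nucleotide composition for one scope (all tails, one tail length, a subset).

    ``extent_percent`` is the percent of analyzed reads carrying the
    modification; ``fraction_by_nucleotide`` divides each nucleotide's pooled
    (abundance-weighted) tail count by the pooled tail length. When the scope
    holds zero tail nucleotides the fractions are undefined and ``empty`` is
    set.
    """

    scope: str
    extent_percent: float
    raw_nucleotide_counts: dict[str, float] = field(default_factory=dict)
    empty: bool = False

    @property
    def total_tail_nt(self) -> float:
        return sum(self.raw_nucleotide_counts.values())

    @property
    def fraction_by_nucleotide(self) -> dict[str, float]:
        total = self.total_tail_nt
        if total <= 0:
            return {nt: float("nan") for nt in NUCLEOTIDES}
        return {nt: self.raw_nucleotide_counts.get(nt, 0.0) / total for nt in NUCLEOTIDES}


@dataclass
class ProfileMatrix:
    """Percent of abundance on each (trim, tail-length) coordinate.

    Coordinate (0, 0) is the exact annotated species. With
    ``renormalized_without_origin`` the (0, 0) mass has been removed and the
    remaining variants rescaled to 100%. Axes are unbounded in storage; any
    aggregation into edge bins is a plotting concern only.
    """

    scope: str
    mass: dict[tuple[int, int], float]
    renormalized_without_origin: bool = False

    @property
    def total(self) -> float:
        return sum(self.mass.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "scope": self.scope,
                "trim": t,
                "tail": l,
                "percent": pct,
                "renormalized": self.renormalized_without_origin,
            }
            for (t, l), pct in sorted(self.mass.items())
        ]
        return pd.DataFrame(rows, columns=["scope", "trim", "tail", "percent", "renormalized"])


@dataclass
class ComparisonResult:
    method: str
    statistic: float
    df: tuple[float, ...]
    pvalue: float


def _require_nonempty(table: ModificationTable) -> float:
    total = table.analyzed_total
    if not table.records or total <= 0:
        raise ValueError("empty modification table")
    return total


def size_distribution(
    table: ModificationTable, axis: str = "read-length", display_cutoff: float = 0.5
) -> SizeDistribution:
    """Abundance-weighted length histogram, in percent of the analyzed total.

    ``axis='read-length'`` bins by full read length (trim and tail combined);
    ``axis='gmc-length'`` bins by 5GMC length, isolating the trimming signal.
    """
    if axis not in ("read-length", "gmc-length"):
        raise ValueError(f"unknown axis {axis!r}")
    total = _require_nonempty(table)
    mass: dict[int, float] = defaultdict(float)
    for rec in table.records:
        length = len(rec.read_sequence) if axis == "read-length" else rec.gmc_len
        mass[length] += rec.mass
    percent = {length: 100.0 * m / total for length, m in sorted(mass.items())}
    return SizeDistribution(axis=axis, percent_by_length=percent, display_cutoff=display_cutoff)


def tail_trim_extent(
    table: ModificationTable,
) -> tuple[list[TailCompositionSummary], list[TailCompositionSummary]]:
    """Per-length tailing and trimming extents.

    Returns (tail series, trim series). For each tail length l >= 1 the extent
    is the percent of analyzed reads carrying an l-nt tail, with the
    nucleotide composition of those tails; likewise per trim length. Length 0
    entries report the unmodified mass (no composition).
    """
    total = _require_nonempty(table)
    tail_mass: dict[int, float] = defaultdict(float)
    trim_mass: dict[int, float] = defaultdict(float)
    tail_nt: dict[int, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    for rec in table.records:
        tail_mass[rec.tail_len] += rec.mass
        trim_mass[rec.trim_len] += rec.mass
        for nt in rec.tail_seq:
            tail_nt[rec.tail_len][nt] += rec.mass
    tails = [
        TailCompositionSummary(
            scope=f"tail-length-{l}",
            extent_percent=100.0 * m / total,
            raw_nucleotide_counts=dict(tail_nt[l]),
            empty=(l == 0),
        )
        for l, m in sorted(tail_mass.items())
    ]
    trims = [
        TailCompositionSummary(
            scope=f"trim-length-{t}",
            extent_percent=100.0 * m / total,
            raw_nucleotide_counts={},
            empty=True,
        )
        for t, m in sorted(trim_mass.items())
    ]
    return tails, trims


def tail_composition(
    table: ModificationTable,
    subset: Callable[[tuple[int, int]], bool] | None = None,
    scope: str = "all-tails",
) -> TailCompositionSummary:
    """Pooled tail nucleotide composition over a coordinate subset.

    ``subset`` is a predicate on (trim, tail-length) coordinates; the default
    selects every tailed read. Composition is the pooled abundance-weighted
    count of each nucleotide across all tail positions, divided by the pooled
    tail length. Raw counts are retained so that disjoint subsets add.
    """
    total = _require_nonempty(table)
    counts: dict[str, float] = defaultdict(float)
    selected_mass = 0.0
    for rec in table.records:
        if subset is not None and not subset(rec.coordinate):
            continue
        if rec.tail_len == 0:
            continue
        selected_mass += rec.mass
        for nt in rec.tail_seq:
            counts[nt] += rec.mass
    return TailCompositionSummary(
        scope=scope,
        extent_percent=100.0 * selected_mass / total,
        raw_nucleotide_counts=dict(counts),
        empty=(sum(counts.values()) <= 0),
    )


def coordinate_matrix(
    table: ModificationTable,
    ref_id: str | None = None,
    renormalize_without_origin: bool = False,
) -> ProfileMatrix:
    """Percent of abundance at each (trim, tail-length) coordinate.

    ``ref_id`` restricts the matrix to records assigned to one reference
    (matched against any of its merged ids); None pools all references,
    weighting each by its read abundance. With
    ``renormalize_without_origin`` the exact annotated species at (0, 0) is
    removed first and the remaining variant mass rescaled to 100%.
    """
    records = [
        rec
        for rec in table.records
        if ref_id is None or ref_id in rec.ref_ids
    ]
    mass: dict[tuple[int, int], float] = defaultdict(float)
    for rec in records:
        mass[rec.coordinate] += rec.mass
    total = sum(mass.values())
    if total <= 0:
        raise ValueError(f"no records in scope {ref_id or 'pooled'!r}")
    if renormalize_without_origin:
        mass.pop((0, 0), None)
        total = sum(mass.values())
        if total <= 0:
            raise ValueError("no variants: all mass at coordinate (0, 0)")
    percent = {coord: 100.0 * m / total for coord, m in mass.items()}
    return ProfileMatrix(
        scope=ref_id or "pooled",
        mass=percent,
        renormalized_without_origin=renormalize_without_origin,
    )


def long_species_fraction(table: ModificationTable, threshold: int = 22) -> float:
    """Percent of analyzed abundance on reads of at least ``threshold`` nt."""
    total = _require_nonempty(table)
    long_mass = sum(rec.mass for rec in table.records if len(rec.read_sequence) >= threshold)
    return 100.0 * long_mass / total


def chi_square_2x2(a_hit: float, a_total: float, b_hit: float, b_total: float) -> ComparisonResult:
    """Uncorrected chi-square test of two pooled proportions (2x2, df = 1).

    Uses the closed-form statistic N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on
    the table [[hit, miss], [hit, miss]]; no continuity correction, so the
    statistic is exactly the textbook value.
    """
    a, b = a_hit, a_total - a_hit
    c, d = b_hit, b_total - b_hit
    if min(a, b, c, d) < 0 or a_total <= 0 or b_total <= 0:
        raise ValueError("counts must be non-negative with positive totals")
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        statistic = 0.0
    else:
        statistic = n * (a * d - b * c) ** 2 / denom
    pvalue = float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    return ComparisonResult(method="chi-square", statistic=statistic, df=(1,), pvalue=pvalue)


def compare_proportions(
    group_a: Sequence[float] | tuple[float, float],
    group_b: Sequence[float] | tuple[float, float],
    method: str = "anova-f",
) -> ComparisonResult:
    """Compare a proportion (e.g. percent of reads >= 22 nt) between two groups.

    ``method='anova-f'``: one-way ANOVA F on replicate-level percents
    (requires >= 2 replicates per group); groups are sequences of percents.
    ``method='chi-square'``: uncorrected 2x2 test on pooled weighted counts;
    groups are (hit_count, total_count) pairs.
    """
    if method == "anova-f":
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("anova-f requires at least 2 replicates per group")
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            statistic, pvalue = stats.f_oneway(a, b)
        df = (1.0, float(a.size + b.size - 2))
        if not math.isfinite(statistic):
            # zero within-group variance: p collapses to 0 (groups differ) or 1
            if math.isclose(a.mean(), b.mean()):
                statistic, pvalue = 0.0, 1.0
            else:
                statistic, pvalue = float("inf"), 0.0
        return ComparisonResult(
            method="anova-f", statistic=float(statistic), df=df, pvalue=float(pvalue)
        )
    if method == "chi-square":
        (a_hit, a_total), (b_hit, b_total) = group_a, group_b
        return chi_square_2x2(a_hit, a_total, b_hit, b_total)
    raise ValueError(f"unknown method {method!r}")
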