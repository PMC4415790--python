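"""The core computation: 5'-locked splitting of reads into 5GMC, trim, and tail.

Each read is compared to an annotated mature sequence with its 5' end locked:
a read whose first base differs from the reference is excluded, and no
mismatch is permitted within the match. The 5' genome-matched component
(5GMC) is the longest common prefix of read and reference, capped at the
reference 3' end. Everything between the annotated 3' end and the 5GMC is
trimmed; every base downstream of the 5GMC — whether or not it happens to be
genome-templated — is tail. Only reads with a 5GMC longer than 12 nt enter
the analysis.

The cap at the annotated 3' end means a read extending past the reference
counts its extension as tail even when templated, which removes any need for
genome alignment: the annotated sequence itself is the coordinate system.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import pandas as pd

from mirtail.read_ingest import CollapsedRead, LibraryMeta
from mirtail.reference_io import ReferenceEntry, ReferenceSet

#: minimum 5GMC length: reads with 5GMC of 12 nt or less are excluded
MIN_GMC_LEN = 13

#: unassigned-reason labels
NO_ANCHOR = "no-anchor"
SHORT_GMC = "short-gmc"


@dataclass(frozen=True)
class ModificationRecord:
    """One read's assignment to one reference: 5GMC length, trim, tail, weight.

    ``weight`` < 1 arises when a read matches several references equally well
    and its abundance is shared fractionally among them; per original read the
    weights always sum to 1.
    """

    ref_ids: tuple[str, ...]
    read_sequence: str
    count: int
    weight: float
    gmc_len: int
    trim_len: int
    tail_seq: str

    @property
    def tail_len(self) -> int:
        return len(self.tail_seq)

    @property
    def mass(self) -> float:
        """Abundance contribution of this record (count x weight)."""
        return self.count * self.weight

    @property
    def coordinate(self) -> tuple[int, int]:
        """(trim, tail-length) position; (0, 0) is the exact annotated species."""
        return (self.trim_len, self.tail_len)


@dataclass
class ModificationTable:
    """All assignment records of one library plus unassigned tallies."""

    records: list[ModificationRecord] = field(default_factory=list)
    meta: LibraryMeta = field(default_factory=LibraryMeta)
    unassigned: Counter = field(default_factory=Counter)

    @property
    def analyzed_total(self) -> float:
        return sum(r.mass for r in self.records)

    @property
    def unassigned_total(self) -> int:
        return sum(self.unassigned.values())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_id": self.meta.library_id,
                "ref_ids": ",".join(r.ref_ids),
                "read_sequence": r.read_sequence,
                "count": r.count,
                "weight": r.weight,
                "gmc_len": r.gmc_len,
                "trim_len": r.trim_len,
                "tail_seq": r.tail_seq,
            }
            for r in self.records
        )

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        if df.empty:
            df = pd.DataFrame(
                columns=[
                    "library_id", "ref_ids", "read_sequence", "count",
                    "weight", "gmc_len", "trim_len", "tail_seq",
                ]
            )
        df.to_csv(path, sep="\t", index=False)


def read_modification_tsv(path: str | Path, meta: LibraryMeta | None = None) -> ModificationTable:
    """Load a modification table written by :meth:`ModificationTable.write_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"read_sequence": str, "tail_seq": str})
    table = ModificationTable(meta=meta if meta is not None else LibraryMeta())
    for row in df.to_dict("records"):
        tail = row["tail_seq"]
        tail = "" if (not isinstance(tail, str) and pd.isna(tail)) else str(tail)
        table.records.append(
            ModificationRecord(
                ref_ids=tuple(str(row["ref_ids"]).split(",")),
                read_sequence=str(row["read_sequence"]),
                count=int(row["count"]),
                weight=float(row["weight"]),
                gmc_len=int(row["gmc_len"]),
                trim_len=int(row["trim_len"]),
                tail_seq=tail,
            )
        )
        if not table.meta.library_id:
            table.meta.library_id = str(row["library_id"])
    return table


def split_read(
    read: str, ref: ReferenceEntry | str, min_gmc: int = MIN_GMC_LEN
) -> tuple[int, int, str] | None:
    """Split a read against one reference; return (gmc_len, trim_len, tail) or None.

    gmc_len is the longest common prefix of read and reference, capped at the
    reference length; the first mismatch terminates it even if downstream
    bases would match again. trim_len = reference length - gmc_len; the tail
    is the read suffix beyond the 5GMC. Returns None (no match) when the 5GMC
    is shorter than ``min_gmc`` — in particular for any read whose 5' end
    differs from the reference.
    """
    ref_seq = ref.sequence if isinstance(ref, ReferenceEntry) else ref
    limit = min(len(read), len(ref_seq))
    gmc = 0
    while gmc < limit and read[gmc] == ref_seq[gmc]:
        gmc += 1
    if gmc < min_gmc:
        return None
    return gmc, len(ref_seq) - gmc, read[gmc:]


def assign_read(
    read: CollapsedRead,
    refs: ReferenceSet,
    mode: str = "fractional",
    min_gmc: int = MIN_GMC_LEN,
) -> list[ModificationRecord]:
    """Assign one collapsed read to the best-anchoring reference(s).

    Every reference is tried; candidates with 5GMC >= ``min_gmc`` are ranked
    by maximal 5GMC length, then minimal trim. Remaining ties (same 5GMC and
    trim against distinct references, typical of miRNA families) are either
    shared with weight 1/k (``mode='fractional'``, default) or resolved to the
    lexicographically first id (``mode='unique'``). Returns [] for an
    unassignable read.
    """
    if mode not in ("fractional", "unique"):
        raise ValueError(f"unknown assign mode {mode!r}")
    candidates: list[tuple[int, int, ReferenceEntry, str]] = []
    for entry in refs:
        result = split_read(read.sequence, entry, min_gmc=min_gmc)
        if result is not None:
            gmc, trim, tail = result
            candidates.append((gmc, trim, entry, tail))
    if not candidates:
        return []
    best_gmc = max(c[0] for c in candidates)
    candidates = [c for c in candidates if c[0] == best_gmc]
    best_trim = min(c[1] for c in candidates)
    candidates = [c for c in candidates if c[1] == best_trim]
    candidates.sort(key=lambda c: c[2].ids[0])
    if mode == "unique":
        candidates = candidates[:1]
    weight = float(Fraction(1, len(candidates)))
    return [
        ModificationRecord(
            ref_ids=entry.ids,
            read_sequence=read.sequence,
            count=read.count,
            weight=weight,
            gmc_len=gmc,
            trim_len=trim,
            tail_seq=tail,
        )
        for gmc, trim, entry, tail in candidates
    ]


def profile_library(
    reads: Iterable[CollapsedRead],
    refs: ReferenceSet,
    mode: str = "fractional",
    min_gmc: int = MIN_GMC_LEN,
    meta: LibraryMeta | None = None,
) -> ModificationTable:
    """Profile a collapsed library against a reference set.

    The table's ``analyzed_total`` equals the count-weighted number of
    assigned reads. Unassigned reads are tallied by reason: ``no-anchor``
    (5' end matches no reference at all) versus ``short-gmc`` (anchored but
    with 5GMC below the threshold), so 5'-variant loss is distinguishable
    from heavy truncation.
    """
    if len(refs) == 0:
        raise ValueError("empty reference set")
    table = ModificationTable(meta=meta if meta is not None else LibraryMeta())
    for read in reads:
        records = assign_read(read, refs, mode=mode, min_gmc=min_gmc)
        if records:
            table.records.extend(records)
            continue
        best = max(
            (_prefix_len(read.sequence, entry.sequence) for entry in refs),
            default=0,
        )
        table.unassigned[NO_ANCHOR if best == 0 else SHORT_GMC] += read.count
    return table


def _prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n
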