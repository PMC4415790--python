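"""Small-RNA library ingestion: FASTQ/FASTA reading, 3' adapter removal, collapsing.

Libraries arrive demultiplexed, single-end (~51 cycles on the platform the
pipeline emulates). The 3' sequencing adapter follows the small-RNA insert; on
short inserts the adapter is read in full, on long ones it is truncated at the
final cycle. Adapter removal therefore searches for the leftmost exact
occurrence of the adapter's first ``min_overlap`` bases, which also recognizes
a partial terminal adapter of at least that length.

Unique insert sequences are collapsed to (sequence, count) pairs; counts — not
unique sequences — are the abundance unit everywhere downstream, because the
reported percentages are read-abundance based.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_ACCEPTED = frozenset("ACGUTN")

#: rejection reason labels used in ingest reports
NO_ADAPTER = "no-adapter"
TOO_SHORT = "too-short"
TOO_LONG = "too-long"
CONTAINS_N = "contains-n"


class IngestError(ValueError):
    """Raised for unreadable or malformed read input."""


@dataclass(frozen=True)
class CollapsedRead:
    """A unique adapter-trimmed read sequence with its abundance count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise IngestError("CollapsedRead sequence must be non-empty")
        if self.count < 1:
            raise IngestError("CollapsedRead count must be >= 1")


@dataclass
class LibraryMeta:
    """Per-library bookkeeping: identity and stage-by-stage read counts."""

    library_id: str = ""
    genotype: str = ""
    replicate: int = 0
    raw_read_count: int = 0
    adapter_trimmed_count: int = 0
    collapsed_unique_count: int = 0
    rejections: Counter = field(default_factory=Counter)

    def check(self) -> None:
        if self.adapter_trimmed_count > self.raw_read_count:
            raise IngestError("adapter_trimmed_count exceeds raw_read_count")


def _normalize_read(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def ingest(path: str | Path, format: str = "fastq") -> Iterator[tuple[str, int]]:
    """Stream (sequence, count) pairs from a library file.

    Formats: ``fastq`` (4-line, qualities ignored), ``fasta``, and
    ``collapsed-fasta`` whose headers carry a ``_xN`` count suffix
    (e.g. ``>seq1_x57``). Sequences are upper-cased and T->U normalized;
    characters outside {A,C,G,U,T,N} are a hard error.
    """
    path = Path(path)
    if format not in ("fastq", "fasta", "collapsed-fasta"):
        raise ValueError(f"unknown format {format!r}")
    n = 0
    with open(path) as fh:
        if format == "fastq":
            # FastqGeneralIterator raises ValueError on truncated records or
            # sequence/quality length mismatches
            stream = ((title, seq) for title, seq, _qual in FastqGeneralIterator(fh))
        else:
            stream = SimpleFastaParser(fh)
        for title, raw_seq in stream:
            n += 1
            name = title.split(None, 1)[0] if title else f"record#{n}"
            seq = _normalize_read(raw_seq)
            bad = set(seq) - _ACCEPTED - {"U"}
            if bad:
                raise IngestError(
                    f"read {name!r} contains unsupported characters {sorted(bad)}"
                )
            if format == "collapsed-fasta":
                token = name.rsplit("_x", 1)
                if len(token) != 2 or not token[1].isdigit() or int(token[1]) < 1:
                    raise IngestError(
                        f"collapsed-fasta header {name!r} lacks a parsable _xN count token"
                    )
                yield seq, int(token[1])
            else:
                yield seq, 1
    if n == 0:
        warnings.warn(f"no reads found in {path}", stacklevel=2)


def trim_adapter(
    seq: str,
    adapter: str,
    min_overlap: int = 8,
    min_insert: int = 13,
    max_insert: int = 30,
) -> tuple[str | None, str | None]:
    """Remove the 3' adapter from one read; return (insert, None) or (None, reason).

    The seed is the adapter's first ``min_overlap`` bases (the full adapter if
    it is shorter); the leftmost exact seed occurrence marks the insert end.
    A read truncated mid-adapter is handled as long as at least ``min_overlap``
    adapter bases were sequenced. Rejection reasons: ``no-adapter``,
    ``too-short``, ``too-long``, ``contains-n``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = _normalize_read(adapter)
    seq = _normalize_read(seq)
    seed = adapter[: min(min_overlap, len(adapter))]
    pos = seq.find(seed)
    if pos < 0:
        return None, NO_ADAPTER
    insert = seq[:pos]
    if "N" in insert:
        return None, CONTAINS_N
    if len(insert) < min_insert:
        return None, TOO_SHORT
    if len(insert) > max_insert:
        return None, TOO_LONG
    return insert, None


def collapse_reads(
    inserts: Iterable[tuple[str, int]] | Iterable[str],
) -> tuple[list[CollapsedRead], LibraryMeta]:
    """Collapse a stream of inserts to unique (sequence, count) records.

    Accepts either bare sequences or (sequence, count) pairs. Output order is
    deterministic: descending count, then lexicographic — so any permutation
    of the input stream collapses to the same list. Counts are conserved:
    their sum equals the number of (weighted) input inserts.
    """
    counter: Counter = Counter()
    total = 0
    for item in inserts:
        if isinstance(item, str):
            seq, count = item, 1
        else:
            seq, count = item
        counter[seq] += count
        total += count
    reads = [
        CollapsedRead(sequence=seq, count=count)
        for seq, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    meta = LibraryMeta(
        raw_read_count=total,
        adapter_trimmed_count=total,
        collapsed_unique_count=len(reads),
    )
    return reads, meta


def process_library(
    path: str | Path,
    format: str = "fastq",
    adapter: str | None = None,
    min_overlap: int = 8,
    min_insert: int = 13,
    max_insert: int = 30,
    library_id: str = "",
    genotype: str = "",
    replicate: int = 0,
) -> tuple[list[CollapsedRead], LibraryMeta]:
    """Full ingest stage: read, adapter-trim (if an adapter is given), collapse.

    ``adapter=None`` skips trimming (for pre-trimmed or collapsed inputs); reads
    containing N are then discarded with reason ``contains-n``.
    """
    rejections: Counter = Counter()
    raw = 0
    kept: list[tuple[str, int]] = []
    for seq, count in ingest(path, format=format):
        raw += count
        if adapter is not None:
            insert, reason = trim_adapter(
                seq, adapter, min_overlap=min_overlap,
                min_insert=min_insert, max_insert=max_insert,
            )
        elif "N" in seq:
            insert, reason = None, CONTAINS_N
        else:
            insert, reason = seq, None
        if insert is None:
            rejections[reason] += count
        else:
            kept.append((insert, count))
    reads, meta = collapse_reads(kept)
    meta.library_id = library_id
    meta.genotype = genotype
    meta.replicate = replicate
    meta.raw_read_count = raw
    meta.rejections = rejections
    meta.check()
    return reads, meta


def write_collapsed_tsv(reads: list[CollapsedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for read in reads:
            fh.write(f"{read.sequence}\t{read.count}\n")


def write_ingest_report(meta: LibraryMeta, path: str | Path) -> None:
    """Per-reason rejection counts plus stage totals, as TSV."""
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"library_id\t{meta.library_id}\n")
        fh.write(f"genotype\t{meta.genotype}\n")
        fh.write(f"replicate\t{meta.replicate}\n")
        fh.write(f"raw_read_count\t{meta.raw_read_count}\n")
        fh.write(f"adapter_trimmed_count\t{meta.adapter_trimmed_count}\n")
        fh.write(f"collapsed_unique_count\t{meta.collapsed_unique_count}\n")
        for reason in (NO_ADAPTER, TOO_SHORT, TOO_LONG, CONTAINS_N):
            fh.write(f"rejected:{reason}\t{meta.rejections.get(reason, 0)}\n")
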