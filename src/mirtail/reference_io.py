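"""Loading and normalization of annotated mature small-RNA reference sequences.

References are the anchors of the whole analysis: a read is classified by
exact 5'-locked prefix matching against these sequences, and the annotated 3'
end defines trim = 0. Mature miRNA FASTA files (e.g. from miRBase) use the RNA
alphabet; many user files use DNA. Both are accepted via ``alphabet_policy``.

Identical mature sequences deposited under several locus names (common within
miRNA families) are merged into a single entry whose ids are concatenated, so
a read can never be counted twice against what is physically one molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")
_ACCEPTED = frozenset("ACGUTN")


class ReferenceError(ValueError):
    """Raised for malformed or unusable reference input."""


@dataclass(frozen=True)
class ReferenceEntry:
    """One annotated mature small-RNA sequence (5'->3', RNA alphabet).

    ``ids`` holds every reference name that maps to this exact sequence.
    """

    ids: tuple[str, ...]
    sequence: str

    def __post_init__(self) -> None:
        if not self.ids:
            raise ReferenceError("ReferenceEntry requires at least one id")
        if not self.sequence:
            raise ReferenceError(f"empty sequence for {self.ids[0]!r}")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ReferenceError(
                f"reference {self.ids[0]!r} contains non-RNA characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def label(self) -> str:
        return ",".join(self.ids)


@dataclass
class ReferenceSet:
    """Deduplicated, deterministically ordered collection of reference entries."""

    entries: list[ReferenceEntry] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        seqs = [e.sequence for e in self.entries]
        if len(seqs) != len(set(seqs)):
            raise ReferenceError("ReferenceSet entries must have pairwise distinct sequences")
        self.entries = sorted(self.entries, key=lambda e: e.ids[0])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceEntry]:
        return iter(self.entries)

    def by_id(self, ref_id: str) -> ReferenceEntry:
        for entry in self.entries:
            if ref_id in entry.ids:
                return entry
        raise KeyError(ref_id)


def normalize_sequence(raw: str, record_name: str, alphabet_policy: str = "dna-to-rna") -> str:
    """Upper-case a sequence and map it onto {A,C,G,U}.

    ``alphabet_policy='dna-to-rna'`` converts T to U; ``'rna'`` rejects T.
    N and any other character are hard errors for references, because exact
    anchoring requires fully determined bases.
    """
    seq = raw.strip().upper()
    if not seq:
        raise ReferenceError(f"record {record_name!r} has an empty sequence")
    bad = set(seq) - _ACCEPTED
    if bad:
        raise ReferenceError(
            f"record {record_name!r} contains unsupported characters {sorted(bad)}"
        )
    if "N" in seq:
        raise ReferenceError(f"record {record_name!r} contains N; exact anchoring requires ACGU")
    if "T" in seq:
        if alphabet_policy == "dna-to-rna":
            seq = seq.replace("T", "U")
        elif alphabet_policy == "rna":
            raise ReferenceError(
                f"record {record_name!r} contains T but alphabet_policy='rna'"
            )
        else:
            raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    return seq


def load_reference(fasta_path: str | Path, alphabet_policy: str = "dna-to-rna") -> ReferenceSet:
    """Load mature small-RNA sequences from FASTA into a deduplicated anchor set.

    Records are case-folded, T->U converted under the default policy, and
    identical sequences merged (ids concatenated in input order). Entry
    ordering is lexicographic by first id, so two loads of the same file are
    identical.
    """
    fasta_path = Path(fasta_path)
    by_seq: dict[str, list[str]] = {}
    n_records = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        name = record.id or f"record#{n_records}"
        seq = normalize_sequence(str(record.seq), name, alphabet_policy)
        by_seq.setdefault(seq, []).append(name)
    if n_records == 0:
        raise ReferenceError(f"no FASTA records found in {fasta_path}")
    entries = [ReferenceEntry(ids=tuple(ids), sequence=seq) for seq, ids in by_seq.items()]
    return ReferenceSet(entries=entries, source_label=str(fasta_path))


def validate_reference(refs: ReferenceSet, min_len: int = 13) -> list[str]:
    """Warn about references too short to ever yield an analyzable read.

    The downstream filter keeps only reads whose 5' genome-matched component
    exceeds 12 nt, so a reference shorter than 13 nt can never contribute a
    record. Entries are warned about, never removed.
    """
    if len(refs) == 0:
        raise ReferenceError("no references")
    warnings = []
    for entry in refs:
        if entry.length < min_len:
            warnings.append(
                f"reference {entry.label} is {entry.length} nt (< {min_len} nt); "
                "no read anchored to it can pass the 5GMC filter"
            )
    return warnings


def write_reference_tsv(refs: ReferenceSet, path: str | Path) -> None:
    """Write the normalized reference set as a provenance TSV (ids, sequence, length)."""
    with open(path, "w") as fh:
        fh.write("ids\tsequence\tlength\n")
        for entry in refs:
            fh.write(f"{entry.label}\t{entry.sequence}\t{entry.length}\n")


def write_reference_fasta(refs: ReferenceSet, path: str | Path) -> None:
    """Round-trip writer used by fixtures.

    Merged entries are expanded back to one record per id so that
    ``load(write(load(f)))`` reproduces ``load(f)`` exactly.
    """
    with open(path, "w") as fh:
        for entry in refs:
            for ref_id in entry.ids:
                fh.write(f">{ref_id}\n{entry.sequence}\n")
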