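"""Shared fixtures: small reference sets and an end-to-end pipeline helper."""

from __future__ import annotations

import numpy as np
import pytest

from mirtail.anchor_profile import profile_library
from mirtail.read_ingest import process_library
from mirtail.reference_io import ReferenceEntry, ReferenceSet
from mirtail.synthetic_data import simulate_library, write_fastq

#: 21-nt periodic reference used throughout the worked examples
REF_R = "ACGUACGUACGUACGUACGUA"


@pytest.fixture
def ref_r() -> ReferenceEntry:
    return ReferenceEntry(ids=("miR-R",), sequence=REF_R)


@pytest.fixture
def single_ref_set(ref_r) -> ReferenceSet:
    return ReferenceSet(entries=[ref_r])


def make_random_refs(n: int = 8, length: int = 21, seed: int = 11) -> ReferenceSet:
    """Random mature-sized references with distinct 5' context."""
    rng = np.random.default_rng(seed)
    entries = []
    seen = set()
    while len(entries) < n:
        seq = "".join(rng.choice(list("ACGU"), size=length))
        if seq in seen:
            continue
        seen.add(seq)
        entries.append(ReferenceEntry(ids=(f"miR-{len(entries):02d}",), sequence=seq))
    return ReferenceSet(entries=entries)


@pytest.fixture(scope="session")
def random_refs() -> ReferenceSet:
    return make_random_refs()


def run_pipeline(refs, params, tmp_path, library_id="lib", mode="fractional"):
    """simulate -> write FASTQ -> ingest/trim/collapse -> profile."""
    records, truth = simulate_library(refs, params, library_id=library_id)
    fastq = tmp_path / f"{library_id}.fastq"
    write_fastq(records, fastq)
    reads, meta = process_library(fastq, adapter=params.adapter, library_id=library_id)
    table = profile_library(reads, refs, mode=mode, meta=meta)
    return truth, table
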