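"""Readers and writers for the plain-text formats used across the pipeline.

FASTQ is Sanger/Phred+33 throughout (454-style single-end reads). TSV tables
go through pandas; generated tables carry a ``# seed=N`` header comment so a
run can always be traced back to its random seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class Read:
    """A single amplicon read with per-base Phred quality scores."""

    read_id: str
    sequence: str
    qualities: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def mean_qv(self) -> float:
        """Arithmetic mean of the per-base Phred scores."""
        if len(self.qualities) == 0:
            raise ValueError(f"read {self.read_id} has an empty quality vector")
        return float(self.qualities.mean())

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    """Stream reads from a Sanger-encoded FASTQ file."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            read_id = title.split()[0]
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(
                np.int16
            ) - PHRED_OFFSET
            yield Read(read_id, seq.upper(), quals)


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> int:
    """Write reads as Phred+33 FASTQ; returns the number of records written."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(
                chr(int(q) + PHRED_OFFSET) for q in np.clip(read.qualities, 0, 60)
            )
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike,
                seed: int | None = None, width: int = 80) -> int:
    n = 0
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f";seed={seed}\n")
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip()
            if not line or line.startswith(";"):
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_tsv(df, path: str | os.PathLike, seed: int | None = None,
              index: bool = True) -> None:
    """Write a DataFrame as TSV with an optional ``# seed=N`` header comment."""
    with open(path, "w") as handle:
        if seed is not None:
            handle.write(f"# seed={seed}\n")
        df.to_csv(handle, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs):
    import pandas as pd

    kwargs.setdefault("comment", "#")
    return pd.read_csv(path, sep="\t", **kwargs)
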