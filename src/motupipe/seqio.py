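"""Reading and writing barcode sequence data.

Supports plain FASTA (read/write, wrapped or unwrapped), a minimal NEXUS
subset (DATA/CHARACTERS blocks, sequential or interleaved, read only), and
the pre-clustering length filter. Inputs are unaligned amplicon reads:
lowercase and IUPAC ambiguity codes are accepted and uppercased; gap
characters are stripped on NEXUS read and rejected in FASTA.
"""

from __future__ import annotations

import collections
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Nexus import Nexus

# A,C,G,T plus U and the full IUPAC nucleotide ambiguity alphabet.
IUPAC_NUCLEOTIDES = frozenset("ACGTUMRWSYKVHDBN")


class ParseError(ValueError):
    """Malformed sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One input barcode read: unique id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record has an empty id")
        bad = set(self.residues) - IUPAC_NUCLEOTIDES
        if bad:
            raise ParseError(
                f"record {self.id!r}: invalid residue symbol(s) {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | os.PathLike[str]) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Sequence lines may be wrapped; they are concatenated and uppercased.
    Errors name the offending line or id: text before the first ">" header,
    a duplicate id, or a header with no residue body all raise ParseError.
    """
    source = os.path.basename(os.fspath(path))
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(
                f"{source}: header at line {header_line} has an empty sequence body"
            )
        name, _, desc = header.partition(" ")
        records.append(
            SequenceRecord(
                id=name, residues="".join(chunks).upper(),
                description=desc.strip(), source=source,
            )
        )

    with open(path, encoding="ascii") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise ParseError(f"{source}: empty header at line {lineno}")
            else:
                if header is None:
                    raise ParseError(
                        f"{source}: line {lineno} precedes any '>' header"
                    )
                if "-" in line or any(c.isspace() for c in line):
                    raise ParseError(
                        f"{source}: line {lineno} contains gap or whitespace "
                        "characters inside a sequence"
                    )
                chunks.append(line)
        flush()
    _check_unique_ids(records)
    return records


def read_fasta_dir(path: str | os.PathLike[str]) -> list[SequenceRecord]:
    """Read every .fasta/.fa/.fna file in a directory, sorted by file name."""
    names = sorted(
        n for n in os.listdir(path)
        if n.lower().endswith((".fasta", ".fa", ".fna"))
    )
    records: list[SequenceRecord] = []
    for name in names:
        records.extend(read_fasta(os.path.join(os.fspath(path), name)))
    _check_unique_ids(records)
    return records


def read_nexus(path: str | os.PathLike[str]) -> list[SequenceRecord]:
    """Read taxa from a NEXUS DATA or CHARACTERS matrix.

    Sequential and interleaved matrices are supported; taxon labels become
    record ids and gap symbols ("-") are stripped from the residues.
    """
    source = os.path.basename(os.fspath(path))
    try:
        nex = Nexus.Nexus(os.fspath(path))
    except Nexus.NexusError as exc:
        raise ParseError(f"{source}: {exc}") from exc
    if not nex.matrix:
        raise ParseError(f"{source}: no MATRIX found in DATA/CHARACTERS block")
    records = []
    for taxon in nex.taxlabels:
        residues = str(nex.matrix[taxon]).upper().replace("-", "").replace("?", "")
        records.append(
            SequenceRecord(id=taxon, residues=residues, source=source)
        )
    _check_unique_ids(records)
    return records


def read_input(path: str | os.PathLike[str]) -> list[SequenceRecord]:
    """Dispatch on input type: directory of FASTA, .nex/.nexus file, or FASTA."""
    p = os.fspath(path)
    if os.path.isdir(p):
        return read_fasta_dir(p)
    if p.lower().endswith((".nex", ".nexus", ".nxs")):
        return read_nexus(p)
    return read_fasta(p)


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | os.PathLike[str],
    width: int = 70,
) -> None:
    with open(path, "w", encoding="ascii") as handle:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{head}\n")
            for i in range(0, rec.length, width):
                handle.write(rec.residues[i : i + width] + "\n")


def filter_by_length(
    records: Sequence[SequenceRecord], min_length: int
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition records into (kept, removed) by the inclusive length threshold.

    A record is kept iff its length is >= ``min_length``; order is preserved
    and every input record lands in exactly one of the two lists.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = [r for r in records if r.length >= min_length]
    removed = [r for r in records if r.length < min_length]
    return kept, removed


def length_histogram(records: Iterable[SequenceRecord]) -> dict[int, int]:
    """Map sequence length -> number of records of that length."""
    return dict(collections.Counter(r.length for r in records))
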