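"""Synthetic barcode communities with known species structure.

Emulates a trimmed amplicon survey: a set of species reference sequences
kept at least ``min_separation`` mismatches apart, each sampled by reads
carrying up to ``within_substitutions`` random substitutions, optional
pyrosequencing-style homopolymer-run indels, and optional exact 5'/3'
fragments. The first read of every species is emitted error-free — the
modal amplicon sequence — so within-species reads form a star of radius
``within_substitutions`` around it and recoverability is guaranteed
whenever min_separation > 2 * within_substitutions. A truth table records,
for every read, its species and the errors applied.

All randomness flows from a single integer seed through one numpy
Generator stream; identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .align import pair_distance
from .seqio import SequenceRecord, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunityConfig:
    """Study conditions for one synthetic community."""

    n_species: int = 8
    seq_length: int = 600
    reads_per_species: int | tuple[int, ...] = 10
    within_substitutions: int = 2
    #: per-homopolymer-run slip probability; a random 600-base read has
    #: ~450 maximal runs, so 0.002 yields about one slip per read
    homopolymer_indel_rate: float = 0.002
    fragment_fraction: float = 0.1
    min_separation: int = 30
    seed: int = 0
    id_prefix: str = "read"
    #: when set, species references are drawn from this separate seed so
    #: several batches can share species while sampling independent reads
    reference_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.homopolymer_indel_rate <= 1.0:
            raise ValueError("homopolymer_indel_rate must be in [0, 1]")
        if self.min_separation <= 2 * self.within_substitutions:
            raise ValueError(
                "min_separation must exceed 2 * within_substitutions "
                "for species to be recoverable"
            )

    def reads_for(self, species_index: int) -> int:
        if isinstance(self.reads_per_species, int):
            return self.reads_per_species
        return self.reads_per_species[species_index]


@dataclass(frozen=True)
class TruthRow:
    species_index: int
    substitutions_applied: int
    indels_applied: int
    is_fragment: bool


def generate_references(config: CommunityConfig) -> list[SequenceRecord]:
    """Species reference sequences, rejection-sampled so that every pair's
    global-alignment mismatch distance is >= min_separation."""
    rng = np.random.default_rng(config.seed)
    return _generate_references(config, rng)


def _generate_references(
    config: CommunityConfig, rng: np.random.Generator
) -> list[SequenceRecord]:
    refs: list[str] = []
    attempts = 0
    while len(refs) < config.n_species:
        if attempts > 50 * config.n_species:
            raise RuntimeError(
                "could not satisfy min_separation after bounded retries; "
                "try longer sequences or fewer species"
            )
        attempts += 1
        candidate = "".join(rng.choice(_BASES, size=config.seq_length))
        cand_rec = SequenceRecord(id="cand", residues=candidate)
        ok = True
        for existing in refs:
            pd = pair_distance(
                SequenceRecord(id="a", residues=existing), cand_rec
            )
            if pd.mismatches < config.min_separation:
                ok = False
                break
        if ok:
            refs.append(candidate)
    return [
        SequenceRecord(id=f"species_{i:03d}", residues=seq, source="synthetic")
        for i, seq in enumerate(refs)
    ]


def mutate_substitutions(
    sequence: str, k: int, rng: np.random.Generator | int
) -> str:
    """Change exactly k distinct positions, each to a different base."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if k > len(sequence):
        raise ValueError("k exceeds sequence length")
    positions = rng.choice(len(sequence), size=k, replace=False)
    out = list(sequence)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _homopolymer_runs(sequence: str) -> list[tuple[int, int]]:
    """(start, length) of every maximal single-base run."""
    runs = []
    start = 0
    for i in range(1, len(sequence) + 1):
        if i == len(sequence) or sequence[i] != sequence[start]:
            runs.append((start, i - start))
            start = i
    return runs


def mutate_homopolymer_indels(
    sequence: str,
    rate: float,
    rng: np.random.Generator | int,
    direction: str | None = None,
) -> str:
    """Apply slippage indels: each maximal homopolymer run is independently
    lengthened or shortened by one base with probability ``rate``.

    The slip direction ("insert" or "delete") is drawn once per call and
    applied to every affected run, modelling directional polymerase
    slippage; this keeps indel-only divergence invisible to the
    mismatch-only distance (mixed +1/-1 slips in adjacent runs can make a
    one-mismatch ungapped alignment optimal). No substitutions are ever
    introduced.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if direction is None:
        direction = "insert" if rng.random() < 0.5 else "delete"
    if direction not in ("insert", "delete"):
        raise ValueError("direction must be 'insert', 'delete' or None")
    pieces = []
    for start, length in _homopolymer_runs(sequence):
        base = sequence[start]
        if rng.random() < rate:
            length = length + 1 if direction == "insert" else length - 1
        pieces.append(base * length)
    return "".join(pieces)


def count_indels(parent: str, child: str) -> int:
    """Net slippage events between a parent and its indel-only child,
    counted per run whose length changed."""
    pruns = _homopolymer_runs(parent)
    cruns = _homopolymer_runs(child)
    if len(pruns) == len(cruns):
        return sum(
            pl != cl for (_, pl), (_, cl) in zip(pruns, cruns)
        )
    return abs(len(parent) - len(child))


def generate_community(
    config: CommunityConfig,
) -> tuple[list[SequenceRecord], dict[str, TruthRow], list[SequenceRecord]]:
    """Emit (reads, truth, references) for one community.

    Read ids are sequential over a shuffled read order, so they encode
    nothing about species or errors. Per read: up to within_substitutions
    substitutions, homopolymer indels at the configured per-run rate, and
    with probability fragment_fraction an exact contiguous fragment
    covering >= 60% of the read. Read 0 of each species carries no error
    of any kind — the modal amplicon — so every same-species read is
    within within_substitutions mismatches of it.
    """
    rng = np.random.default_rng(config.seed)
    if config.reference_seed is None:
        references = _generate_references(config, rng)
    else:
        references = _generate_references(
            config, np.random.default_rng(config.reference_seed)
        )
    drafts: list[tuple[str, TruthRow]] = []
    for sp_index, ref in enumerate(references):
        for j in range(config.reads_for(sp_index)):
            k = 0 if j == 0 else int(rng.integers(0, config.within_substitutions + 1))
            seq = mutate_substitutions(ref.residues, k, rng) if k else ref.residues
            indels = 0
            if j > 0 and config.homopolymer_indel_rate > 0:
                mutated = mutate_homopolymer_indels(
                    seq, config.homopolymer_indel_rate, rng
                )
                indels = count_indels(seq, mutated)
                seq = mutated
            is_fragment = False
            if j > 0 and rng.random() < config.fragment_fraction:
                frac = rng.uniform(0.6, 0.95)
                flen = max(1, int(round(frac * len(seq))))
                start = int(rng.integers(0, len(seq) - flen + 1))
                seq = seq[start : start + flen]
                is_fragment = True
            drafts.append((seq, TruthRow(sp_index, k, indels, is_fragment)))
    order = rng.permutation(len(drafts))
    records = []
    truth: dict[str, TruthRow] = {}
    for rank, idx in enumerate(order, start=1):
        seq, row = drafts[idx]
        read_id = f"{config.id_prefix}_{rank:04d}"
        records.append(SequenceRecord(id=read_id, residues=seq, source="synthetic"))
        truth[read_id] = row
    return records, truth, references


def truth_partition(truth: dict[str, TruthRow]) -> list[frozenset[str]]:
    """The true species partition of the read ids."""
    by_species: dict[int, set[str]] = {}
    for read_id, row in truth.items():
        by_species.setdefault(row.species_index, set()).add(read_id)
    return [frozenset(v) for _, v in sorted(by_species.items())]


# ---------------------------------------------------------------------------
# on-disk fixtures for the annotation stage
# ---------------------------------------------------------------------------

#: two synthetic phyla the species are split across, for rank summaries
_PHYLA = ("Nematoda", "Arthropoda")


def write_community_fixture(
    config: CommunityConfig, out_dir: str | os.PathLike[str]
) -> dict[str, str]:
    """Write a complete offline test fixture for one community.

    Produces reads.fasta, truth.tsv, references.fasta, a ref-id -> taxid
    map, and a tiny synthetic NCBI-style taxonomy dump (nodes.dmp /
    names.dmp) with a kingdom -> phylum -> genus -> species chain per
    species, split across two phyla. Returns the path of each artifact.
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    records, truth, references = generate_community(config)
    paths = {
        "reads": os.path.join(out, "reads.fasta"),
        "truth": os.path.join(out, "truth.tsv"),
        "references": os.path.join(out, "references.fasta"),
        "taxid_map": os.path.join(out, "taxid_map.tsv"),
        "nodes": os.path.join(out, "nodes.dmp"),
        "names": os.path.join(out, "names.dmp"),
    }
    write_fasta(records, paths["reads"])
    write_fasta(references, paths["references"])
    with open(paths["truth"], "w", encoding="ascii") as handle:
        handle.write(
            "read_id\tspecies_index\tsubstitutions\tindels\tis_fragment\n"
        )
        for rec in records:
            row = truth[rec.id]
            handle.write(
                f"{rec.id}\t{row.species_index}\t{row.substitutions_applied}\t"
                f"{row.indels_applied}\t{int(row.is_fragment)}\n"
            )
    with open(paths["taxid_map"], "w", encoding="ascii") as handle:
        for i, ref in enumerate(references):
            handle.write(f"{ref.id}\t{species_taxid(i)}\n")
    nodes, names = taxonomy_fixture_rows(config.n_species)
    with open(paths["nodes"], "w", encoding="ascii") as handle:
        for taxid, parent, rank in nodes:
            handle.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(paths["names"], "w", encoding="ascii") as handle:
        for taxid, name in names:
            handle.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    return paths


def species_taxid(species_index: int) -> int:
    return 1000 + 10 * species_index


def genus_taxid(species_index: int) -> int:
    return 1001 + 10 * species_index


def species_phylum(species_index: int) -> str:
    return _PHYLA[species_index % len(_PHYLA)]


def taxonomy_fixture_rows(
    n_species: int,
) -> tuple[list[tuple[int, int, str]], list[tuple[int, str]]]:
    """Rows for a minimal nodes.dmp / names.dmp covering n_species."""
    nodes = [(1, 1, "no rank"), (2, 1, "kingdom"), (3, 2, "phylum"), (4, 2, "phylum")]
    names = [(1, "root"), (2, "Metazoa"), (3, _PHYLA[0]), (4, _PHYLA[1])]
    for i in range(n_species):
        phylum_id = 3 + i % 2
        nodes.append((genus_taxid(i), phylum_id, "genus"))
        names.append((genus_taxid(i), f"Genus{i:03d}"))
        nodes.append((species_taxid(i), genus_taxid(i), "species"))
        names.append((species_taxid(i), f"Genus{i:03d} sp{i:03d}"))
    return nodes, names


def read_taxid_map(path: str | os.PathLike[str]) -> dict[str, int]:
    """Two-column TSV: reference id, taxid."""
    mapping: dict[str, int] = {}
    with open(path, encoding="ascii") as handle:
        for line in handle:
            if not line.strip():
                continue
            ref_id, taxid = line.split("\t")[:2]
            mapping[ref_id] = int(taxid)
    return mapping
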