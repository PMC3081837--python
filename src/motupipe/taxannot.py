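"""Taxonomic annotation of MOTU against a local reference database.

Each MOTU is represented by its longest member sequence, which is aligned
against every sequence in a reference database of taxonomically attributed
barcodes. The best-scoring matches (top ten by default) above a similarity
acceptance cutoff are recorded, each with the full ranked lineage — genus
up to kingdom — pulled from a local copy of the NCBI taxonomy dump
(nodes.dmp / names.dmp). Annotation uses the most similar existing
sequences rather than demanding exact matches, so MOTU from taxa absent
from the reference can still be placed at higher ranks; a MOTU whose best
identity falls below the cutoff is left unannotated.
"""

from __future__ import annotations

import collections
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import ScoringScheme, nw_align
from .seqio import SequenceRecord

# ranks retained in a stored lineage, innermost first
LINEAGE_RANKS = ("genus", "family", "order", "class", "phylum", "kingdom")

DEFAULT_TOP_N = 10
DEFAULT_MIN_IDENTITY = 0.70


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


@dataclass(frozen=True)
class AnnotationHit:
    """One reference match for a MOTU representative."""

    motu_name: str
    ref_id: str
    identity: float
    score: int
    rank_index: int
    taxid: int
    lineage: tuple[tuple[str, str], ...]  # (rank, name), genus -> kingdom


class Taxonomy:
    """Parent-pointer tree over NCBI-dump-style nodes."""

    def __init__(self, nodes: Mapping[int, TaxonNode]):
        self.nodes = dict(nodes)
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise ValueError(
                    f"orphan taxid {node.taxid}: parent {node.parent_taxid} missing"
                )
        for node in self.nodes.values():
            seen = set()
            taxid = node.taxid
            while True:
                if taxid in seen:
                    raise ValueError(f"cycle in taxonomy at taxid {taxid}")
                seen.add(taxid)
                parent = self.nodes[taxid].parent_taxid
                if parent == taxid:  # root is its own parent
                    break
                taxid = parent

    def ancestors(self, taxid: int) -> list[TaxonNode]:
        """The node itself and its chain of ancestors up to (excluding) root."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        chain = []
        node = self.nodes[taxid]
        while True:
            chain.append(node)
            if node.parent_taxid == node.taxid:
                break
            node = self.nodes[node.parent_taxid]
        return chain

    def lineage(self, taxid: int) -> list[tuple[str, str]]:
        """Ranked (rank, name) pairs from genus up to kingdom, unranked
        nodes skipped; innermost rank first."""
        keep = {r: i for i, r in enumerate(LINEAGE_RANKS)}
        ranked = [
            (n.rank, n.name) for n in self.ancestors(taxid) if n.rank in keep
        ]
        return sorted(ranked, key=lambda rn: keep[rn[0]])


def _split_dmp(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\t|").split("\t|\t")


def load_taxonomy(
    nodes_path: str | os.PathLike[str], names_path: str | os.PathLike[str]
) -> Taxonomy:
    """Parse NCBI-format nodes.dmp and names.dmp (scientific names only)."""
    parents: dict[int, tuple[int, str]] = {}
    with open(nodes_path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = _split_dmp(line)
            parents[int(fields[0])] = (int(fields[1]), fields[2].strip())
    names: dict[int, str] = {}
    with open(names_path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) >= 4 and fields[3].strip() == "scientific name":
                names[int(fields[0])] = fields[1].strip()
    nodes = {
        taxid: TaxonNode(taxid, parent, rank, names.get(taxid, f"taxid {taxid}"))
        for taxid, (parent, rank) in parents.items()
    }
    return Taxonomy(nodes)


def pick_motu_representative(
    motu_expanded_members: Iterable[str],
    records: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
) -> SequenceRecord:
    """The longest member sequence, ties by lexicographically smallest id."""
    if not isinstance(records, Mapping):
        records = {r.id: r for r in records}
    members = list(motu_expanded_members)
    if not members:
        raise ValueError("MOTU has no members")
    best = min(members, key=lambda i: (-records[i].length, i))
    return records[best]


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Matching columns / columns where neither side is a gap."""
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(x == y for x, y in pairs) / len(pairs)


def annotate_motu(
    representative: SequenceRecord,
    reference_records: Sequence[SequenceRecord],
    taxid_map: Mapping[str, int],
    taxonomy: Taxonomy,
    top_n: int = DEFAULT_TOP_N,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    motu_name: str = "",
    scoring: ScoringScheme | None = None,
) -> list[AnnotationHit]:
    """Rank reference matches for one MOTU representative.

    Every reference is aligned exhaustively (desk scale); hits are ordered
    by score, then identity, then ref_id, and at most ``top_n`` hits with
    identity >= ``min_identity`` are kept. An empty result means the MOTU
    is unannotated.
    """
    scored = []
    for ref in reference_records:
        if ref.id not in taxid_map:
            raise KeyError(f"reference id {ref.id!r} has no taxid mapping")
        taxid = taxid_map[ref.id]
        if taxid not in taxonomy.nodes:
            raise KeyError(f"reference {ref.id!r}: taxid {taxid} not in taxonomy")
        aln = nw_align(representative.residues, ref.residues, scoring)
        identity = alignment_identity(aln.a, aln.b)
        scored.append((-aln.score, -identity, ref.id, taxid))
    scored.sort()
    hits = []
    for neg_score, neg_identity, ref_id, taxid in scored:
        if -neg_identity < min_identity:
            continue
        hits.append(
            AnnotationHit(
                motu_name=motu_name, ref_id=ref_id, identity=-neg_identity,
                score=-neg_score, rank_index=len(hits) + 1, taxid=taxid,
                lineage=tuple(taxonomy.lineage(taxid)),
            )
        )
        if len(hits) == top_n:
            break
    return hits


def summarize_by_rank(
    all_hits: Mapping[str, Sequence[AnnotationHit]],
    rank: str,
    motu_sizes: Mapping[str, int],
) -> dict[str, tuple[int, int]]:
    """Tally MOTU and original-sequence counts per taxon name at one rank.

    Each MOTU contributes only its rank-1 hit; MOTU without hits, or whose
    best hit's lineage lacks the requested rank, count under "unassigned".
    """
    if rank not in LINEAGE_RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
    tally: dict[str, list[int]] = collections.defaultdict(lambda: [0, 0])
    for motu_name, size in motu_sizes.items():
        hits = all_hits.get(motu_name, ())
        label = "unassigned"
        if hits:
            lineage = dict(hits[0].lineage)
            label = lineage.get(rank, "unassigned")
        tally[label][0] += 1
        tally[label][1] += size
    return {name: (motu, seqs) for name, (motu, seqs) in tally.items()}


def write_hits_tsv(
    all_hits: Mapping[str, Sequence[AnnotationHit]], path
) -> None:
    with open(path, "w", encoding="ascii") as handle:
        handle.write("motu\trank_index\tref_id\tidentity\ttaxid\tlineage\n")
        for motu_name in sorted(all_hits):
            for hit in all_hits[motu_name]:
                lineage = ";".join(f"{r}:{n}" for r, n in hit.lineage)
                handle.write(
                    f"{motu_name}\t{hit.rank_index}\t{hit.ref_id}\t"
                    f"{hit.identity:.6f}\t{hit.taxid}\t{lineage}\n"
                )
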