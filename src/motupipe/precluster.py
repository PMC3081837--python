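"""Exact-subsequence dereplication.

Before any alignment, the input is collapsed into preclusters: groups of
sequences that are exact contiguous substrings of a single representative
(a sequence is a substring of itself, so identical duplicates merge too).
Only the representatives go on to screening and alignment; MOTU membership
is later expanded back through the precluster map.

The grouping is greedy and deterministic: sequences are processed in order
of decreasing length (ties by lexicographically smaller id) and each joins
the first existing precluster whose representative contains it, else founds
its own. Only forward-strand containment is tested; reverse complements are
never merged.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqio import SequenceRecord


@dataclass
class Precluster:
    """A redundancy group: representative id plus all member ids."""

    rep_id: str
    member_ids: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def build_preclusters(records: Sequence[SequenceRecord]) -> list[Precluster]:
    """Group exact-subsequence matches, longest-first, one pass.

    Returns preclusters sorted by decreasing size, ties by rep_id. Every
    input id appears in exactly one precluster; each representative is a
    longest member of its group.
    """
    if not records:
        raise ValueError("no records to precluster")
    by_id = {}
    for rec in records:
        if rec.id in by_id:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        by_id[rec.id] = rec

    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    groups: list[Precluster] = []  # in founding order
    rep_seqs: list[str] = []
    exact_index: dict[str, int] = {}  # residues -> group index, fast dup path
    for rec in ordered:
        idx = exact_index.get(rec.residues)
        if idx is None:
            for i, rep_seq in enumerate(rep_seqs):
                if rec.residues in rep_seq:
                    idx = i
                    break
        if idx is None:
            groups.append(Precluster(rep_id=rec.id, member_ids={rec.id}))
            rep_seqs.append(rec.residues)
            exact_index[rec.residues] = len(groups) - 1
        else:
            groups[idx].member_ids.add(rec.id)
    return sorted(groups, key=lambda g: (-g.size, g.rep_id))


def representative_records(
    preclusters: Sequence[Precluster],
    records: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
) -> list[SequenceRecord]:
    """One record per precluster, in precluster order."""
    if not isinstance(records, Mapping):
        records = {r.id: r for r in records}
    out = []
    for pc in preclusters:
        if pc.rep_id not in records:
            raise KeyError(f"representative id {pc.rep_id!r} not found in records")
        out.append(records[pc.rep_id])
    return out


def write_precluster_tsv(
    preclusters: Iterable[Precluster], path: str | os.PathLike[str]
) -> None:
    """Audit export: one (rep_id, member_id) row per member."""
    with open(path, "w", encoding="ascii") as handle:
        handle.write("rep_id\tmember_id\n")
        for pc in preclusters:
            for member in sorted(pc.member_ids):
                handle.write(f"{pc.rep_id}\t{member}\n")
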