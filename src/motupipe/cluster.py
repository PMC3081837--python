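"""Single-linkage MOTU clustering at one or many cutoffs.

Two representatives are linked when their stored mismatch distance is at
or below the cutoff; MOTU are the connected components of the thresholded
distance graph (union–find). Because single linkage is greedy and
determinate, the clusters do not depend on sequence order, and no member
of one cluster is within the cutoff of any member of another. One distance
collection, computed once for the largest cutoff, serves every smaller
cutoff — partitions at increasing cutoffs are nested coarsenings.

Also here: MOTU naming ("{cutoff}bp_MOTU0001", largest first), expansion
of representative clusters back to original sequence membership through
the preclusters, the MOTU-count-versus-cutoff curve, and the two-tier
divide-and-conquer analysis for datasets too large to cluster in one pass.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import PairDistance, ScoringScheme, compute_distances
from .precluster import Precluster, build_preclusters, representative_records
from .screen import ScreenConfig, find_candidate_pairs
from .seqio import SequenceRecord


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self._parent = {x: x for x in items}

    def find(self, x: str) -> str:
        p = self._parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self._parent[rb] = ra

    def components(self) -> list[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for x in self._parent:
            groups.setdefault(self.find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]


@dataclass
class MOTUPartition:
    """Clustering of representatives at one cutoff.

    ``clusters``, ``names`` and ``expanded`` are parallel lists (index i is
    one MOTU): representative-id sets, stable names, and original-sequence
    id sets obtained by expanding each representative through its
    precluster. ``names``/``expanded`` are empty until name_and_expand."""

    cutoff: int
    clusters: list[frozenset[str]]
    names: list[str] = field(default_factory=list)
    expanded: list[frozenset[str]] = field(default_factory=list)

    @property
    def motu_count(self) -> int:
        return len(self.clusters)

    def expanded_sizes(self) -> list[int]:
        return [len(members) for members in self.expanded]

    def members_of(self, name: str) -> frozenset[str]:
        return self.expanded[self.names.index(name)]


def single_linkage(
    representative_ids: Iterable[str],
    distances: Mapping[tuple[str, str], PairDistance],
    cutoff: int,
) -> MOTUPartition:
    """Connected components of the distance graph thresholded at ``cutoff``.

    Pairs absent from ``distances`` (failed the screen or the overlap test)
    are unlinked at every cutoff; they are never realigned here.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    uf = _UnionFind(representative_ids)
    for (id_a, id_b), pd in distances.items():
        if pd.mismatches <= cutoff:
            uf.union(id_a, id_b)
    clusters = sorted(uf.components(), key=lambda c: min(c))
    return MOTUPartition(cutoff=cutoff, clusters=clusters)


def cluster_all_cutoffs(
    representative_ids: Sequence[str],
    distances: Mapping[tuple[str, str], PairDistance],
    cutoffs: Iterable[int],
    max_cutoff: int,
) -> dict[int, MOTUPartition]:
    """One partition per cutoff, all from the same distance collection.

    ``max_cutoff`` is the largest cutoff the distances were screened and
    computed for; requesting a cutoff above it would silently miss links,
    so it is an error.
    """
    cutoffs = sorted(set(cutoffs))
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    if cutoffs[-1] > max_cutoff:
        raise ValueError(
            f"cutoff {cutoffs[-1]} exceeds the max_cutoff {max_cutoff} the "
            "distances were computed for"
        )
    ids = list(representative_ids)
    return {c: single_linkage(ids, distances, c) for c in cutoffs}


def name_and_expand(
    partition: MOTUPartition, preclusters: Sequence[Precluster]
) -> MOTUPartition:
    """Expand representative clusters to original membership and assign names.

    A MOTU's expanded membership is the union of its representatives'
    precluster members. Names are "{cutoff}bp_MOTU{NNNN}" assigned in
    decreasing expanded-size order, ties broken by the lexicographically
    smallest member id, numbering from 0001.
    """
    members_by_rep = {pc.rep_id: frozenset(pc.member_ids) for pc in preclusters}
    expanded = []
    for cluster in partition.clusters:
        acc: set[str] = set()
        for rep in cluster:
            if rep not in members_by_rep:
                raise KeyError(f"representative {rep!r} has no precluster")
            acc |= members_by_rep[rep]
        expanded.append(frozenset(acc))
    order = sorted(
        range(len(partition.clusters)),
        key=lambda i: (-len(expanded[i]), min(expanded[i])),
    )
    return MOTUPartition(
        cutoff=partition.cutoff,
        clusters=[partition.clusters[i] for i in order],
        names=[
            f"{partition.cutoff}bp_MOTU{rank:04d}"
            for rank in range(1, len(order) + 1)
        ],
        expanded=[expanded[i] for i in order],
    )


def motu_count_curve(
    partitions: Mapping[int, MOTUPartition] | Iterable[MOTUPartition],
) -> list[tuple[int, int]]:
    """Ordered (cutoff, MOTU count) pairs — the discovery curve."""
    if isinstance(partitions, Mapping):
        partitions = partitions.values()
    return sorted((p.cutoff, p.motu_count) for p in partitions)


# ---------------------------------------------------------------------------
# pipeline orchestration (precluster -> screen -> align -> cluster)
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything one clustering run produces, keyed for the results store."""

    records: list[SequenceRecord]
    preclusters: list[Precluster]
    candidate_pairs: set[tuple[str, str]]
    distances: dict[tuple[str, str], PairDistance]
    partitions: dict[int, MOTUPartition]  # named and expanded


def cluster_records(
    records: Sequence[SequenceRecord],
    cutoffs: Iterable[int],
    scoring: ScoringScheme | None = None,
    screen_mode: str = "kmer",
    word_size: int | None = None,
    min_overlap: float = 0.90,
    min_identity: float = 0.95,
) -> PipelineResult:
    """Run precluster -> screen -> align -> cluster over ``records``."""
    cutoffs = sorted(set(cutoffs))
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    max_cutoff = cutoffs[-1]
    preclusters = build_preclusters(records)
    reps = representative_records(preclusters, records)
    if len(reps) > 1:
        config = ScreenConfig(
            max_cutoff=max_cutoff, min_identity=min_identity,
            word_size=word_size, mode=screen_mode,
        )
        pairs = find_candidate_pairs(reps, config)
        distances = compute_distances(reps, pairs, scoring, min_overlap)
    else:
        pairs, distances = set(), {}
    rep_ids = [r.id for r in reps]
    partitions = {
        c: name_and_expand(p, preclusters)
        for c, p in cluster_all_cutoffs(rep_ids, distances, cutoffs, max_cutoff).items()
    }
    return PipelineResult(
        records=list(records), preclusters=preclusters,
        candidate_pairs=pairs, distances=distances, partitions=partitions,
    )


# ---------------------------------------------------------------------------
# two-tier divide-and-conquer
# ---------------------------------------------------------------------------

@dataclass
class TwoTierResult:
    """Second-tier partition over pooled first-tier representatives.

    ``carried_counts`` maps each second-tier MOTU name to the total number
    of ORIGINAL sequences it contains (sum of the first-tier MOTU counts of
    its pooled representatives); ``first_tier_members`` maps each pooled
    representative id to the original-sequence membership of its first-tier
    MOTU, so full membership is recoverable by joining."""

    partition: MOTUPartition
    carried_counts: dict[str, int]
    first_tier_members: dict[str, frozenset[str]]


def two_tier(
    batches: Sequence[Sequence[SequenceRecord]],
    t1: int,
    t2: int,
    scoring: ScoringScheme | None = None,
    screen_mode: str = "kmer",
    min_overlap: float = 0.90,
) -> TwoTierResult:
    """Cluster each batch at ``t1``, pool the longest sequence of every
    first-tier MOTU with its original-sequence count, recluster at ``t2``.

    Every second-tier MOTU is a union of whole first-tier MOTU, and its
    carried count is the sum of their counts. Sequence ids must be unique
    across batches.
    """
    if t1 > t2:
        raise ValueError("t1 must be <= t2")
    pooled: list[SequenceRecord] = []
    counts: dict[str, int] = {}
    first_members: dict[str, frozenset[str]] = {}
    for batch in batches:
        result = cluster_records(
            batch, [t1], scoring=scoring,
            screen_mode=screen_mode, min_overlap=min_overlap,
        )
        by_id = {r.id: r for r in batch}
        part = result.partitions[t1]
        for members in part.expanded:
            rep = min(members, key=lambda i: (-by_id[i].length, i))
            if rep in counts:
                raise ValueError(f"duplicate sequence id {rep!r} across batches")
            pooled.append(by_id[rep])
            counts[rep] = len(members)
            first_members[rep] = members
    second = cluster_records(
        pooled, [t2], scoring=scoring,
        screen_mode=screen_mode, min_overlap=min_overlap,
    ).partitions[t2]
    carried = {
        name: sum(counts[rep] for rep in second.expanded[i])
        for i, name in enumerate(second.names)
    }
    return TwoTierResult(
        partition=second, carried_counts=carried, first_tier_members=first_members
    )


def write_motu_text(
    partition: MOTUPartition, path: str | os.PathLike[str]
) -> None:
    """One line per MOTU: name, expanded size, comma-separated member ids."""
    with open(path, "w", encoding="ascii") as handle:
        for name, members in zip(partition.names, partition.expanded):
            handle.write(f"{name}\t{len(members)}\t{','.join(sorted(members))}\n")
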