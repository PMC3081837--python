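"""Exact pairwise distances from global (Needleman–Wunsch/Gotoh) alignment.

The distance between two barcode sequences is the number of aligned columns
in which both sequences carry a determined, differing nucleotide. Columns
with a gap on either side, or with any symbol outside {A,C,G,T} (N or an
IUPAC ambiguity code), contribute nothing — indels (including pyrosequencing
homopolymer slippage) and unresolved base calls are invisible to the metric.
This mismatch-only distance does not in general satisfy the triangle
inequality; nothing downstream relies on it doing so.

The alignment itself is an optimal global alignment under an affine-gap
scoring scheme, computed by the Gotoh three-state dynamic programme. Among
co-optimal alignments the traceback is deterministic (diagonal > up > left
at every tie), so identical inputs always produce the identical alignment
and hence the identical distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from numba import njit

from .seqio import SequenceRecord

_NEG = np.int32(-(2**30))
_DETERMINED = frozenset("ACGT")

# residue byte -> small code; every symbol distinct so X==Y iff same symbol
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate("ACGTUMRWSYKVHDBN"):
    _CODE[ord(_c)] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap nucleotide scoring. Only the alignment shape matters
    downstream (the distance counts mismatched columns, not score), so any
    scheme with match > mismatch is admissible. The default is linear
    (gap_extend == gap_open): under affine gaps with a cheaper extension,
    bundling several nearby single-base gaps into one long gap plus
    compensating mismatches can tie the score of keeping the gaps separate,
    and the deterministic traceback may then report spurious mismatches for
    indel-only divergence. With linear penalties the mismatch-free gapping
    is strictly optimal, so homopolymer slippage is exactly invisible to
    the distance."""

    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


class Alignment(NamedTuple):
    a: str
    b: str
    score: int


@dataclass(frozen=True)
class PairDistance:
    """Mismatch distance and overlap for one representative pair,
    stored canonically with id_a < id_b."""

    id_a: str
    id_b: str
    mismatches: int
    overlap_frac: float
    aligned_columns: int

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("PairDistance requires id_a < id_b")

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(2**30)
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b: consume a ("up")
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a: consume b ("left")
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = best + s
            vx = M[i - 1, j] + gap_open
            if Iy[i - 1, j] + gap_open > vx:
                vx = Iy[i - 1, j] + gap_open
            if Ix[i - 1, j] + gap_extend > vx:
                vx = Ix[i - 1, j] + gap_extend
            Ix[i, j] = vx
            vy = M[i, j - 1] + gap_open
            if Ix[i, j - 1] + gap_open > vy:
                vy = Ix[i, j - 1] + gap_open
            if Iy[i, j - 1] + gap_extend > vy:
                vy = Iy[i, j - 1] + gap_extend
            Iy[i, j] = vy

    # end state: precedence M (diagonal) > Ix (up) > Iy (left) at ties
    score = M[n, m]
    state = 0
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = 1
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = 2

    ops = np.empty(n + m, dtype=np.uint8)  # 0 diag, 1 up, 2 left; reversed
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i, j] - s
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            if M[i, j] == target:
                state = 0
            elif Ix[i, j] == target:
                state = 1
            else:
                state = 2
        elif state == 1:
            target = Ix[i, j]
            ops[k] = 1
            k += 1
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == target:
                state = 0
            elif Iy[i, j] + gap_open == target:
                state = 2
            else:
                state = 1
        else:
            target = Iy[i, j]
            ops[k] = 2
            k += 1
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == target:
                state = 0
            elif Ix[i, j] + gap_open == target:
                state = 1
            else:
                state = 2
    return score, ops[:k]


def nw_align(a: str, b: str, scoring: ScoringScheme | None = None) -> Alignment:
    """Optimal global alignment of two residue strings.

    Returns the two equal-length gapped strings and the alignment score.
    Raises ValueError on an empty sequence.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    scoring = scoring or ScoringScheme()
    ca = _CODE[np.frombuffer(a.encode("ascii"), dtype=np.uint8)]
    cb = _CODE[np.frombuffer(b.encode("ascii"), dtype=np.uint8)]
    score, ops = _gotoh(
        ca, cb,
        scoring.match_score, scoring.mismatch_score,
        scoring.gap_open, scoring.gap_extend,
    )
    out_a = []
    out_b = []
    i = j = 0
    for op in ops[::-1]:
        if op == 0:
            out_a.append(a[i]); out_b.append(b[j]); i += 1; j += 1
        elif op == 1:
            out_a.append(a[i]); out_b.append("-"); i += 1
        else:
            out_a.append("-"); out_b.append(b[j]); j += 1
    return Alignment("".join(out_a), "".join(out_b), int(score))


def motu_distance(
    aligned_a: str, aligned_b: str, len_a: int, len_b: int
) -> tuple[int, float, int]:
    """Mismatch-only distance of one alignment.

    Returns (mismatches, overlap_frac, aligned_columns). A column counts as
    a mismatch only when both symbols are in {A,C,G,T} and differ; gap or
    ambiguity columns count zero. The overlap fraction is the share of the
    SHORTER input covered by gap-free columns (so an exact fragment of a
    longer sequence has overlap 1.0).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings have unequal length")
    mismatches = 0
    ungapped = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        ungapped += 1
        if x != y and x in _DETERMINED and y in _DETERMINED:
            mismatches += 1
    shorter = min(len_a, len_b)
    overlap_frac = ungapped / shorter if shorter else 0.0
    return mismatches, overlap_frac, len(aligned_a)


def pair_distance(
    rec_a: SequenceRecord,
    rec_b: SequenceRecord,
    scoring: ScoringScheme | None = None,
) -> PairDistance:
    """Align one pair and package the mismatch distance canonically."""
    id_a, id_b = sorted((rec_a.id, rec_b.id))
    if rec_a.residues == rec_b.residues:
        return PairDistance(id_a, id_b, 0, 1.0, rec_a.length)
    aln = nw_align(rec_a.residues, rec_b.residues, scoring)
    mismatches, overlap, cols = motu_distance(
        aln.a, aln.b, rec_a.length, rec_b.length
    )
    return PairDistance(id_a, id_b, mismatches, overlap, cols)


def compute_distances(
    representatives: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    candidate_pairs: Iterable[tuple[str, str]],
    scoring: ScoringScheme | None = None,
    min_overlap: float = 0.90,
) -> dict[tuple[str, str], PairDistance]:
    """Exact distances for every candidate pair that passes the overlap test.

    Pairs whose overlap fraction falls below ``min_overlap`` are omitted and
    thus unlinked at every cutoff. The result is a pure function of the pair
    set, independent of evaluation order.
    """
    if not isinstance(representatives, Mapping):
        representatives = {r.id: r for r in representatives}
    out: dict[tuple[str, str], PairDistance] = {}
    for raw_a, raw_b in candidate_pairs:
        for rid in (raw_a, raw_b):
            if rid not in representatives:
                raise KeyError(f"unknown representative id {rid!r}")
        pd = pair_distance(representatives[raw_a], representatives[raw_b], scoring)
        if pd.overlap_frac >= min_overlap:
            out[pd.key] = pd
    return out


def write_distance_tsv(
    distances: Mapping[tuple[str, str], PairDistance], path
) -> None:
    with open(path, "w", encoding="ascii") as handle:
        handle.write("id_a\tid_b\tmismatches\toverlap_frac\n")
        for key in sorted(distances):
            pd = distances[key]
            handle.write(
                f"{pd.id_a}\t{pd.id_b}\t{pd.mismatches}\t{pd.overlap_frac:.6f}\n"
            )
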