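"""Candidate-pair screening before exact alignment.

Aligning every representative against every other is quadratic in the
number of unique sequences, and almost all of those pairs are far beyond
any requested cutoff. The screen cheaply selects the pairs that could
possibly lie within the largest cutoff, so exact global alignment is only
spent where it can matter.

The screen is an exact-word (k-mer) filter with a pigeonhole guarantee:
two sequences of length >= L that differ by at most c substitutions must
share at least one exact word of length floor(L / (c + 1)) — split either
sequence into c + 1 blocks and at least one block is untouched. Choosing
word_size at or below that bound therefore returns a superset of every
pair within the cutoff, for substitution-only divergence. Pairs diverged
mainly by long indels can in principle evade any word filter; all_pairs
mode is the guaranteed (and quadratic) fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .seqio import SequenceRecord

DEFAULT_WORD_SIZE = 14


@dataclass(frozen=True)
class ScreenConfig:
    """Screen parameters.

    max_cutoff is the largest clustering cutoff the distances will be used
    for. min_identity is the permissive "gathering" identity filter of the
    original BLAST-based screen; the internal word screen is strictly more
    permissive, so the value is recorded for provenance but does not alter
    the pair set. word_size None selects min(14, pigeonhole bound); an
    explicit word_size above the bound is an error. mode "all_pairs"
    returns every pair and ignores word_size.
    """

    max_cutoff: int
    min_identity: float = 0.95
    word_size: int | None = None
    mode: str = "kmer"

    def __post_init__(self) -> None:
        if self.max_cutoff < 0:
            raise ValueError("max_cutoff must be >= 0")
        if self.mode not in ("kmer", "all_pairs"):
            raise ValueError(f"unknown screen mode {self.mode!r}")
        if self.word_size is not None and self.word_size < 4:
            raise ValueError("word_size must be >= 4")


def expected_min_score(
    overlap_len: int, max_cutoff: int, match_score: int, mismatch_score: int
) -> int:
    """Minimum ungapped score of an overlap_len-column alignment with at
    most max_cutoff mismatches — the score floor a candidate pair must beat."""
    if overlap_len <= max_cutoff:
        raise ValueError("overlap_len must exceed max_cutoff")
    return (overlap_len - max_cutoff) * match_score + max_cutoff * mismatch_score


def pigeonhole_word_bound(min_length: int, max_cutoff: int) -> int:
    """Largest word size that still guarantees a shared word for any pair of
    length->=min_length sequences within max_cutoff substitutions."""
    return min_length // (max_cutoff + 1)


def find_candidate_pairs(
    representatives: Sequence[SequenceRecord], config: ScreenConfig
) -> set[tuple[str, str]]:
    """Unordered id pairs worth aligning exactly.

    kmer mode returns every pair sharing at least one exact word of the
    effective word size; all_pairs mode returns all n(n-1)/2 pairs. The
    result is a set of (id_a, id_b) tuples with id_a < id_b, independent
    of input order.
    """
    if len(representatives) < 2:
        raise ValueError("need at least two representatives to screen")
    ids = sorted(r.id for r in representatives)
    if config.mode == "all_pairs":
        return set(combinations(ids, 2))

    min_len = min(r.length for r in representatives)
    bound = pigeonhole_word_bound(min_len, config.max_cutoff)
    if bound < 4:
        raise ValueError(
            f"shortest representative ({min_len} bases) is too short for a "
            f"word screen at max_cutoff {config.max_cutoff}; use all_pairs mode"
        )
    if config.word_size is None:
        word = min(DEFAULT_WORD_SIZE, bound)
    elif config.word_size > bound:
        raise ValueError(
            f"word_size {config.word_size} exceeds the pigeonhole bound "
            f"{bound} for the shortest sequence at max_cutoff "
            f"{config.max_cutoff}; choose word_size <= {bound} or all_pairs mode"
        )
    else:
        word = config.word_size

    index: dict[str, set[str]] = {}
    for rec in representatives:
        seen: set[str] = set()
        seq = rec.residues
        for i in range(rec.length - word + 1):
            seen.add(seq[i : i + word])
        for w in seen:
            index.setdefault(w, set()).add(rec.id)
    pairs: set[tuple[str, str]] = set()
    for bucket in index.values():
        if len(bucket) > 1:
            pairs.update(combinations(sorted(bucket), 2))
    return pairs


def write_candidate_tsv(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="ascii") as handle:
        handle.write("id_a\tid_b\n")
        for a, b in sorted(pairs):
            handle.write(f"{a}\t{b}\n")
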