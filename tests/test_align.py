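import itertools

import numpy as np
import pytest
from Bio import Align as BioAlign
from hypothesis import given
from hypothesis import strategies as st

from motupipe import (
    PairDistance,
    ScoringScheme,
    compute_distances,
    motu_distance,
    mutate_homopolymer_indels,
    mutate_substitutions,
    nw_align,
    pair_distance,
)

from conftest import random_seq, rec

DNA = st.text(alphabet="ACGT", min_size=1, max_size=7)


def enumerate_best_score(a, b, scoring):
    """Exhaustive oracle: walk every global alignment path, score it with
    affine gap bookkeeping, return the optimum."""

    best = [None]

    def walk(i, j, score, prev):
        if i == len(a) and j == len(b):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = scoring.match_score if a[i] == b[j] else scoring.mismatch_score
            walk(i + 1, j + 1, score + s, "M")
        if i < len(a):
            g = scoring.gap_extend if prev == "U" else scoring.gap_open
            walk(i + 1, j, score + g, "U")
        if j < len(b):
            g = scoring.gap_extend if prev == "L" else scoring.gap_open
            walk(i, j + 1, score + g, "L")

    walk(0, 0, 0, None)
    return best[0]


def biopython_score(a, b, scoring):
    aligner = BioAlign.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match_score
    aligner.mismatch_score = scoring.mismatch_score
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner.score(a, b)


class TestNwAlign:
    def test_identity(self):
        aln = nw_align("ACGT", "ACGT")
        assert (aln.a, aln.b) == ("ACGT", "ACGT")
        assert aln.score == 4 * ScoringScheme().match_score

    def test_single_deletion_alignment(self):
        aln = nw_align("ACGTACGT", "ACGTCGT")
        gaps = sum(c == "-" for c in aln.a + aln.b)
        matches = sum(
            x == y and x != "-" for x, y in zip(aln.a, aln.b)
        )
        assert gaps == 1 and matches == 7

    def test_single_substitution_alignment(self):
        aln = nw_align("ACGT", "ACTT")
        assert "-" not in aln.a + aln.b
        assert sum(x != y for x, y in zip(aln.a, aln.b)) == 1

    @given(DNA, DNA)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        scoring = ScoringScheme()
        assert nw_align(a, b, scoring).score == enumerate_best_score(a, b, scoring)

    @given(DNA, DNA)
    def test_nondefault_scheme_matches_enumeration(self, a, b):
        scoring = ScoringScheme(
            match_score=2, mismatch_score=-3, gap_open=-4, gap_extend=-1
        )
        assert nw_align(a, b, scoring).score == enumerate_best_score(a, b, scoring)

    def test_score_matches_biopython_on_long_random_pairs(self):
        rng = np.random.default_rng(2)
        scoring = ScoringScheme()
        for _ in range(10):
            a = random_seq(rng, int(rng.integers(100, 400)))
            b = random_seq(rng, int(rng.integers(100, 400)))
            assert nw_align(a, b, scoring).score == biopython_score(a, b, scoring)

    def test_deterministic(self):
        a, b = "ACGTACGTAC", "ACGTCGTAC"
        assert nw_align(a, b) == nw_align(a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            nw_align("", "ACGT")


class TestMotuDistance:
    @pytest.mark.parametrize(
        "aligned_a, aligned_b, mismatches, overlap",
        [
            ("ACGT", "ACTT", 1, 1.0),
            ("ACGTACGT", "ACGT-CGT", 0, 7 / 7),  # gap column ignored
            ("ACNT", "ACGT", 0, 1.0),            # N column ignored
            ("ARGT", "AGGT", 0, 1.0),            # IUPAC ambiguity ignored
        ],
    )
    def test_column_rules(self, aligned_a, aligned_b, mismatches, overlap):
        len_a = len(aligned_a.replace("-", ""))
        len_b = len(aligned_b.replace("-", ""))
        mm, ov, cols = motu_distance(aligned_a, aligned_b, len_a, len_b)
        assert mm == mismatches
        assert ov == pytest.approx(overlap)
        assert cols == len(aligned_a)

    def test_unequal_strings_rejected(self):
        with pytest.raises(ValueError):
            motu_distance("ACGT", "ACG", 4, 3)

    def test_fragment_overlap_is_one(self):
        rng = np.random.default_rng(3)
        parent = random_seq(rng, 300)
        frag = parent[40:240]
        aln = nw_align(parent, frag)
        mm, ov, _ = motu_distance(aln.a, aln.b, 300, 200)
        assert mm == 0 and ov == pytest.approx(1.0)


class TestDistanceProperties:
    def test_self_distance_zero(self, small_community):
        _config, records, _truth, _refs = small_community
        for r in records[:5]:
            aln = nw_align(r.residues, r.residues)
            mm, ov, _ = motu_distance(aln.a, aln.b, r.length, r.length)
            assert mm == 0 and ov == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rec("a", random_seq(rng, 150))
        b = rec("b", random_seq(rng, 140))
        assert pair_distance(a, b) == pair_distance(b, a)

    @given(st.integers(0, 10))
    def test_planted_substitutions_give_distance_k(self, k):
        rng = np.random.default_rng(17)
        parent = random_seq(rng, 600)
        child = mutate_substitutions(parent, k, np.random.default_rng(k))
        pd = pair_distance(rec("a", parent), rec("b", child))
        assert pd.mismatches == k

    @given(st.integers(0, 40))
    def test_indel_only_divergence_gives_distance_zero(self, seed):
        rng = np.random.default_rng(seed)
        parent = random_seq(rng, 300)
        child = mutate_homopolymer_indels(parent, 0.3, rng)
        pd = pair_distance(rec("a", parent), rec("b", child))
        assert pd.mismatches == 0

    def test_canonical_storage(self):
        with pytest.raises(ValueError):
            PairDistance("b", "a", 0, 1.0, 10)


class TestComputeDistances:
    def test_identical_pair_present_with_zero(self):
        recs = [rec("a", "ACGTACGT"), rec("b", "ACGTACGT")]
        out = compute_distances(recs, [("a", "b")])
        assert out[("a", "b")].mismatches == 0

    def test_low_overlap_pair_omitted(self):
        long = rec("a", "ACGTACGTACGTACGTACGT")
        out = compute_distances(
            [long, rec("c", long.residues[:10])], [("a", "c")], min_overlap=0.9
        )
        assert ("a", "c") in out  # exact fragment: overlap 1.0 passes
        # staggered sequences sharing only a 20-base core: under a
        # gap-friendly scheme the optimal alignment covers 50% of the
        # shorter sequence, so the pair fails the overlap test
        rng = np.random.default_rng(8)
        core = random_seq(rng, 20)
        a = rec("a", "A" * 20 + core)
        d = rec("d", core + "C" * 20)
        gappy = ScoringScheme(
            match_score=1, mismatch_score=-10, gap_open=-1, gap_extend=-1
        )
        out = compute_distances([a, d], [("a", "d")], gappy, min_overlap=0.9)
        assert out == {}
        out = compute_distances([a, d], [("a", "d")], gappy, min_overlap=0.4)
        assert out[("a", "d")].overlap_frac == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(9)
        recs = [rec(f"s{i:02d}", random_seq(rng, 80)) for i in range(12)]
        pairs = list(itertools.combinations(sorted(r.id for r in recs), 2))
        got = compute_distances(recs, pairs, min_overlap=0.0)
        by_id = {r.id: r for r in recs}
        for a, b in pairs:
            aln = nw_align(by_id[a].residues, by_id[b].residues)
            mm, ov, _ = motu_distance(
                aln.a, aln.b, by_id[a].length, by_id[b].length
            )
            assert got[(a, b)].mismatches == mm
            assert got[(a, b)].overlap_frac == pytest.approx(ov)

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            compute_distances([rec("a", "ACGT")], [("a", "zz")])
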