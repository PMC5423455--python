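"""Seeding, chaining, extension and mapping quality.

The SMEM finder and the banded extension are each checked against an
independently coded brute-force oracle (quadratic substring enumeration and
full unbanded Smith-Waterman DP respectively).
"""

import random

import numpy as np
import pytest

from protaln._kernels import banded_sw
from protaln.alphabet import encode_aa
from protaln.index import ProteinEntry, ProteinReference, build_fm_index
from protaln.orf_translate import GeneticCode, OrfPolicy
from protaln.seed_align import (
    AlignParams,
    SubstitutionMatrix,
    align_read,
    chain_seeds,
    extend_chain,
    find_smems,
    score_to_mapq,
)

MAT = SubstitutionMatrix.blosum62()
CODE = GeneticCode.standard()


def _ref(*seqs):
    return ProteinReference(
        [ProteinEntry(f"p{i}", "", s) for i, s in enumerate(seqs)]
    )


def brute_force_smems(seqs, query, min_len):
    """Quadratic oracle: all exact matches maximal in both directions, with
    contained matches removed."""

    def occurs(p):
        return any(p in s for s in seqs)

    n = len(query)
    mems = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            if not occurs(query[i:j]):
                break
            left = i > 0 and occurs(query[i - 1 : j])
            right = j < n and occurs(query[i : j + 1])
            if not left and not right:
                mems.append((i, j))
    mems = sorted(set(mems))
    out = [
        (i, j)
        for (i, j) in mems
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in mems)
    ]
    return [(i, j) for (i, j) in out if j - i >= min_len]


def full_smith_waterman(q, r, matrix, gap_open, gap_extend):
    """Unbanded affine-gap local alignment score (independent DP oracle)."""
    Q, R = encode_aa(q), encode_aa(r)
    m, n = len(Q), len(R)
    NEG = -(10**8)
    H = np.zeros((m + 1, n + 1), dtype=int)
    E = np.full((m + 1, n + 1), NEG, dtype=int)
    F = np.full((m + 1, n + 1), NEG, dtype=int)
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i - 1, j] - gap_open - gap_extend, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - gap_open - gap_extend, F[i, j - 1] - gap_extend)
            H[i, j] = max(
                0, H[i - 1, j - 1] + matrix.scores[Q[i - 1], R[j - 1]], E[i, j], F[i, j]
            )
            best = max(best, H[i, j])
    return best


class TestFindSmems:
    def test_single_internal_seed(self):
        idx = build_fm_index(_ref("MKVLAGK"))
        seeds = find_smems(idx, "KVL", min_seed_len=1)
        assert len(seeds) == 1
        assert (seeds[0].query_begin, seeds[0].query_end) == (0, 3)
        assert seeds[0].ref_positions == [(0, 1)]

    def test_full_query_self_match(self):
        idx = build_fm_index(_ref("MKVLAGK"))
        seeds = find_smems(idx, "MKVLAGK", min_seed_len=1)
        assert len(seeds) == 1
        assert (seeds[0].query_begin, seeds[0].query_end) == (0, 7)

    def test_stop_symbol_breaks_matches(self):
        idx = build_fm_index(_ref("MKVLAGK"))
        seeds = find_smems(idx, "MKV*AGK", min_seed_len=2)
        spans = sorted((s.query_begin, s.query_end) for s in seeds)
        assert spans == [(0, 3), (4, 7)]

    def test_matches_never_span_entries(self):
        idx = build_fm_index(_ref("MKV", "LAG"))
        assert find_smems(idx, "MKVLAG", min_seed_len=4) == []

    def test_equals_brute_force_oracle(self):
        rng = random.Random(7)
        for _ in range(30):
            seqs = [
                "".join(rng.choice("ACDEFGHIKL") for _ in range(rng.randint(30, 300)))
                for _ in range(rng.randint(1, 3))
            ]
            idx = build_fm_index(_ref(*seqs))
            if rng.random() < 0.5:
                q = "".join(rng.choice("ACDEFGHIKL") for _ in range(rng.randint(5, 60)))
            else:  # mutated reference slice: long shared substrings
                s = rng.choice(seqs)
                a = rng.randrange(max(1, len(s) - 60))
                q = list(s[a : a + 60])
                for _ in range(3):
                    q[rng.randrange(len(q))] = rng.choice("ACDEFGHIKL")
                q = "".join(q)
            got = sorted((s.query_begin, s.query_end) for s in find_smems(idx, q, 1, 10**6))
            assert got == brute_force_smems(seqs, q, 1)


class TestChainSeeds:
    def test_same_diagonal_seeds_merge(self):
        idx = build_fm_index(_ref("MKVLAGKWMKYDEF"))
        seeds = find_smems(idx, "MKVLAGKWMKY", min_seed_len=2)
        chains = chain_seeds(seeds, idx.reference, diag_tolerance=5)
        assert chains[0].entry_index == 0

    def test_different_entries_different_chains(self):
        from protaln.seed_align import Seed

        ref = _ref("MKVLA", "MKVLA")
        seeds = [Seed(0, 4, [(0, 0), (1, 0)])]
        chains = chain_seeds(seeds, ref)
        assert len(chains) == 2
        assert {c.entry_index for c in chains} == {0, 1}

    def test_tie_break_order(self):
        from protaln.seed_align import Seed

        ref = _ref("MKVLA", "MKVLA")
        seeds = [Seed(0, 4, [(1, 0), (0, 0)])]
        chains = chain_seeds(seeds, ref)
        assert [c.entry_index for c in chains] == [0, 1]  # by entry id asc


class TestExtendChain:
    def test_exact_match_score_is_diagonal_sum(self):
        ref = _ref("MKV")
        idx = build_fm_index(ref)
        seeds = find_smems(idx, "MKV", 1)
        chains = chain_seeds(seeds, ref)
        aln = extend_chain(ref, chains[0], "MKV", AlignParams(min_score_threshold=0), MAT)
        expected = sum(MAT.pair_score(c, c) for c in "MKV")
        assert aln.raw_score == expected
        assert aln.cigar == [("M", 3)]

    def test_substitution_scores_lower_than_self(self):
        ref = _ref("MKVAAAAA")
        idx = build_fm_index(ref)
        params = AlignParams(min_score_threshold=0, min_seed_len=3)
        exact = extend_chain(
            ref, chain_seeds(find_smems(idx, "MKVAAAAA", 3), ref)[0],
            "MKVAAAAA", params, MAT,
        )
        mut = extend_chain(
            ref, chain_seeds(find_smems(idx, "MAVAAAAA", 3), ref)[0],
            "MAVAAAAA", params, MAT,
        )
        assert mut.raw_score < exact.raw_score

    def test_banded_equals_full_dp_when_band_covers_query(self):
        rng = random.Random(11)
        for _ in range(25):
            q = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(3, 40)))
            r = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(3, 40)))
            oracle = full_smith_waterman(q, r, MAT, 6, 1)
            score = banded_sw(
                encode_aa(q), encode_aa(r), MAT.scores, 6, 1, 0, len(q) + len(r)
            )[0]
            assert score == oracle

    def test_banded_never_exceeds_full_dp(self):
        rng = random.Random(13)
        for _ in range(15):
            q = "".join(rng.choice("ACDEF") for _ in range(20))
            r = "".join(rng.choice("ACDEF") for _ in range(25))
            oracle = full_smith_waterman(q, r, MAT, 6, 1)
            for band in (1, 3, 8):
                score = banded_sw(encode_aa(q), encode_aa(r), MAT.scores, 6, 1, 0, band)[0]
                assert score <= oracle


class TestScoreToMapq:
    def test_tie_gives_zero(self):
        assert score_to_mapq(100, 100, 1.0, AlignParams()) == 0

    def test_unique_gives_cap(self):
        assert score_to_mapq(100, None, 0.5, AlignParams()) == 60

    def test_monotone_in_gap(self):
        p = AlignParams()
        assert score_to_mapq(100, 50, 1.0, p) > score_to_mapq(100, 90, 1.0, p)

    def test_contract_violation(self):
        with pytest.raises(ValueError):
            score_to_mapq(50, 100, 1.0, AlignParams())

    def test_bounds(self):
        p = AlignParams()
        for second in (0, 10, 50, 99, 100):
            assert 0 <= score_to_mapq(100, second, 1.0, p) <= 60


class TestAlignRead:
    def test_error_free_read_maps_uniquely(self, sim_dataset):
        genome = sim_dataset["genome"]
        idx = sim_dataset["index"]
        entry, cds = next(iter(sorted(genome.cds_nt.items())))
        read = cds[30:280]
        res = align_read("r1", read, idx, CODE, OrfPolicy(), AlignParams(), MAT)
        assert res.mapped
        assert res.alignment.entry_id == entry
        assert res.alignment.mapq == 60
        assert res.alignment.frame_id == 1  # offset 30 is in frame +1
        assert res.alignment.ref_begin == 10  # 30 nt / 3

    def test_reverse_strand_read_maps(self, sim_dataset):
        from protaln.orf_translate import reverse_complement

        genome = sim_dataset["genome"]
        idx = sim_dataset["index"]
        entry, cds = next(iter(sorted(genome.cds_nt.items())))
        read = reverse_complement(cds[30:280])
        res = align_read("r1", read, idx, CODE, OrfPolicy(), AlignParams(), MAT)
        assert res.mapped
        assert res.alignment.entry_id == entry
        assert res.alignment.frame_id < 0

    def test_all_stop_read_is_orf_discarded(self):
        idx = build_fm_index(_ref("MKVLAGKWMKYDEFMKVLAGKW"))
        rng = random.Random(17)
        nt = None
        from protaln.orf_translate import six_frame

        while nt is None:  # seeded search for a read with stops in all frames
            cand = "".join(rng.choice("ACGT") for _ in range(90))
            fs = six_frame("r", cand, CODE, OrfPolicy("relative", relative_fraction=0.9))
            if not fs.passing():
                nt = cand
        res = align_read("r1", nt, idx, CODE,
                         OrfPolicy("relative", relative_fraction=0.9))
        assert not res.mapped
        assert res.unmapped_cause == "orf_filter"

    def test_duplicated_entry_gives_mapq_zero(self):
        seq = "MKVLAGKWMKYDEFILPQRSTVWY" * 4
        ref = ProteinReference(
            [ProteinEntry("a", "", seq), ProteinEntry("b", "", seq)]
        )
        idx = build_fm_index(ref)
        from protaln.simulate import _codon_choices

        nt = "".join(_codon_choices(CODE)[aa][0] for aa in seq)
        res = align_read("r1", nt, idx, CODE, OrfPolicy(), AlignParams(), MAT)
        assert res.mapped
        assert res.alignment.mapq == 0

    def test_deterministic(self, sim_dataset):
        idx = sim_dataset["index"]
        r = sim_dataset["reads"][0]
        a = align_read(r.name, r.seq1, idx, CODE, OrfPolicy(), AlignParams(), MAT)
        b = align_read(r.name, r.seq1, idx, CODE, OrfPolicy(), AlignParams(), MAT)
        assert a == b

    def test_raising_threshold_never_maps_more(self, sim_dataset):
        idx = sim_dataset["index"]
        reads = sim_dataset["reads"][:20]
        mapped_at = []
        for thr in (5, 20, 40):
            params = AlignParams(min_score_threshold=thr)
            n = sum(
                align_read(r.name, r.seq1, idx, CODE, OrfPolicy(), params, MAT).mapped
                for r in reads
            )
            mapped_at.append(n)
        assert mapped_at == sorted(mapped_at, reverse=True)


def test_substitution_matrix_properties():
    assert np.array_equal(MAT.scores, MAT.scores.T)
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        assert MAT.pair_score(aa, aa) > 0
    assert MAT.pair_score("X", "A") == -1
    assert MAT.pair_score("*", "W") == -1


def test_matrix_loadable_from_ncbi_file(tmp_path):
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    p = tmp_path / "blosum62.txt"
    p.write_text(str(mat))
    loaded = SubstitutionMatrix.from_ncbi_file(p)
    assert np.array_equal(loaded.scores, MAT.scores)
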