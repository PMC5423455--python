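"""SMEM seeding, chaining, banded Smith-Waterman extension and MAPQ.

A translated frame is matched against the protein FM-index by computing its
matching statistics (longest exact match ending at every query position)
with backward search.  A match that is the longest one ending at its right
end and whose right extension fails is maximal in both directions; taking
the right-most end for each distinct left end yields exactly the
super-maximal exact matches (SMEMs): no reported match is contained in
another on the query.

SMEM occurrences are chained per (entry, diagonal), each chain is extended
with a banded affine-gap local alignment under BLOSUM scoring, and the best
frame's candidate wins.  Mapping quality follows the usual best-vs-second
Phred-style recipe capped at 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels
from .alphabet import AA_LETTERS, STOP_CODE, encode_aa
from .index import FMIndex, ProteinReference
from .orf_translate import GeneticCode, OrfPolicy, six_frame

CIGAR_OPS = "MIDS"


class SubstitutionMatrix:
    """Integer residue-pair scores over the internal 23-code alphabet.

    Codes: 0 sentinel (never scored), 1..21 residues (incl. X), 22 stop.
    X and '*' score -1 against everything, including themselves, so frames
    containing stops or unknowns are merely penalised, never rewarded.
    """

    def __init__(self, scores: np.ndarray, name: str):
        assert scores.shape == (STOP_CODE + 1, STOP_CODE + 1)
        if not np.array_equal(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.scores = scores.astype(np.int32)
        self.name = name

    @classmethod
    def from_biopython(cls, mat, name: str) -> "SubstitutionMatrix":
        scores = np.full((STOP_CODE + 1, STOP_CODE + 1), -1, dtype=np.int32)
        letters = mat.alphabet
        for i, a in enumerate(AA_LETTERS):
            for j, b in enumerate(AA_LETTERS):
                if a == "X" or b == "X":
                    continue
                if a in letters and b in letters:
                    scores[i + 1, j + 1] = int(mat[a, b])
        return cls(scores, name)

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return cls.from_biopython(substitution_matrices.load("BLOSUM62"), "BLOSUM62")

    @classmethod
    def from_ncbi_file(cls, path) -> "SubstitutionMatrix":
        with open(path) as fh:
            mat = substitution_matrices.read(fh)
        return cls.from_biopython(mat, str(path))

    def pair_score(self, a: str, b: str) -> int:
        ca, cb = int(encode_aa(a)[0]), int(encode_aa(b)[0])
        return int(self.scores[ca, cb])


@dataclass
class AlignParams:
    min_seed_len: int = 5
    gap_open: int = 6
    gap_extend: int = 1
    clip_penalty: int = 5
    min_score_threshold: int = 15
    band_width: int = 15
    max_hits_per_seed: int = 500
    max_chains_per_frame: int = 8
    mapq_cap: int = 60

    def __post_init__(self):
        if min(self.gap_open, self.gap_extend, self.clip_penalty) < 0:
            raise ValueError("penalties must be non-negative")
        if self.min_score_threshold < 0:
            raise ValueError("min_score_threshold must be non-negative")


@dataclass
class Seed:
    """One SMEM: query interval plus its reference occurrences."""

    query_begin: int
    query_end: int
    ref_positions: list[tuple[int, int]]  # (entry index, local offset)
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.query_end - self.query_begin


def find_smems(
    index: FMIndex,
    aa: str,
    min_seed_len: int = 5,
    max_hits_per_seed: int = 500,
) -> list[Seed]:
    """All super-maximal exact matches of ``aa`` in the indexed reference."""
    q = encode_aa(aa)
    n = q.size
    if n == 0:
        return []
    starts = index.forward.matching_statistics(q)
    seeds = []
    for j in range(1, n + 1):
        s = int(starts[j])
        if s >= j:  # empty match at this end
            continue
        if j < n and int(starts[j + 1]) <= s:
            continue  # right-extensible: a longer match ending later covers it
        if j - s < min_seed_len:
            continue
        l, r = index.forward.backward_search(q[s:j])
        truncated = (r - l) > max_hits_per_seed
        rows = range(l, min(r, l + max_hits_per_seed))
        positions = sorted(index.locate(row) for row in rows)
        seeds.append(Seed(s, j, positions, truncated))
    return seeds


@dataclass
class Chain:
    entry_index: int
    seeds: list[tuple[int, int, int]]  # (query_begin, query_end, ref_offset)
    score: int = 0

    @property
    def ref_begin(self) -> int:
        return min(s[2] for s in self.seeds)

    @property
    def query_coverage_intervals(self) -> list[tuple[int, int]]:
        return [(s[0], s[1]) for s in self.seeds]


def chain_seeds(
    seeds: list[Seed],
    ref: ProteinReference,
    diag_tolerance: int = 15,
) -> list[Chain]:
    """Group seed occurrences by (entry, diagonal) within a tolerance.

    Chains are scored by summed seed lengths and returned in deterministic
    order: score descending, then entry id, then reference start.
    """
    occs = []  # (entry, diag, qb, qe, ro)
    for s in seeds:
        for entry, ro in s.ref_positions:
            occs.append((entry, ro - s.query_begin, s.query_begin, s.query_end, ro))
    occs.sort()
    chains: list[Chain] = []
    cur: list = []

    def flush():
        if cur:
            ch = Chain(cur[0][0], [(qb, qe, ro) for (_e, _d, qb, qe, ro) in cur])
            ch.score = sum(qe - qb for (_e, _d, qb, qe, _ro) in cur)
            chains.append(ch)

    for o in occs:
        if cur and (o[0] != cur[-1][0] or o[1] - cur[-1][1] > diag_tolerance):
            flush()
            cur = []
        cur.append(o)
    flush()
    chains.sort(
        key=lambda c: (-c.score, ref.entries[c.entry_index].id, c.ref_begin)
    )
    return chains


@dataclass
class Alignment:
    read_id: str
    entry_id: str
    entry_index: int
    ref_begin: int  # 0-based residue offset in the entry
    frame_id: int
    cigar: list[tuple[str, int]]
    raw_score: int
    mapq: int = 0
    secondary_score: int = 0
    aligned_aa: str = ""
    penalized_score: int = 0
    seed_coverage: float = 0.0

    @property
    def ref_end(self) -> int:
        return self.ref_begin + sum(n for op, n in self.cigar if op in "MD")

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def extend_chain(
    ref: ProteinReference,
    chain: Chain,
    frame_aa: str,
    params: AlignParams,
    matrix: SubstitutionMatrix,
) -> Alignment | None:
    """Banded affine-gap local extension of a chain; None if under threshold."""
    entry = ref.entries[chain.entry_index]
    q = encode_aa(frame_aa)
    ecodes = encode_aa(entry.sequence)
    qlen = q.size
    diags = [ro - qb for qb, _qe, ro in chain.seeds]
    dlo, dhi = min(diags), max(diags)
    wlo = max(0, dlo - params.band_width - 1)
    whi = min(ecodes.size, dhi + qlen + params.band_width + 1)
    r = ecodes[wlo:whi]
    d0 = (dlo + dhi) // 2 - wlo
    band = params.band_width + (dhi - dlo + 1) // 2
    score, qb, qe, rb, re_, ops, lens, n_ops = _kernels.banded_sw(
        q, r, matrix.scores, params.gap_open, params.gap_extend, d0, band
    )
    if score < params.min_score_threshold or n_ops == 0:
        return None
    cigar: list[tuple[str, int]] = []
    if qb > 0:
        cigar.append(("S", qb))
    cigar.extend((CIGAR_OPS[ops[k]], int(lens[k])) for k in range(n_ops))
    if qe < qlen:
        cigar.append(("S", qlen - qe))
    clipped_ends = (qb > 0) + (qe < qlen)
    covered = _interval_union_len(chain.query_coverage_intervals)
    return Alignment(
        read_id="",
        entry_id=entry.id,
        entry_index=chain.entry_index,
        ref_begin=wlo + rb,
        frame_id=0,
        cigar=cigar,
        raw_score=int(score),
        aligned_aa=frame_aa,
        penalized_score=int(score) - params.clip_penalty * clipped_ends,
        seed_coverage=covered / max(qlen, 1),
    )


def _interval_union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for b, e in sorted(intervals):
        if b > end:
            total += e - b
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def score_to_mapq(
    best: int,
    second: int | None,
    seed_coverage: float,
    params: AlignParams,
) -> int:
    """Phred-style mapping quality from the best/second score gap.

    0 when tied, the cap when unique; otherwise proportional to the relative
    score gap scaled by how much of the query the seeds covered.
    """
    if second is None:
        return params.mapq_cap
    if best < second:
        raise ValueError("best score must be >= second score")
    if best <= 0:
        return 0
    mapq = round(params.mapq_cap * (best - second) / best * seed_coverage)
    return int(min(max(mapq, 0), params.mapq_cap))


FRAME_ORDER = {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}


@dataclass
class ReadResult:
    """Outcome for one read: an alignment, or a distinguishable unmapped cause."""

    read_id: str
    nt: str
    alignment: Alignment | None
    unmapped_cause: str | None = None  # orf_filter | no_seed | low_score

    @property
    def mapped(self) -> bool:
        return self.alignment is not None


def _overlaps(a: Alignment, b: Alignment) -> bool:
    if a.entry_index != b.entry_index:
        return False
    lo = max(a.ref_begin, b.ref_begin)
    hi = min(a.ref_end, b.ref_end)
    shorter = min(a.ref_end - a.ref_begin, b.ref_end - b.ref_begin)
    return shorter > 0 and (hi - lo) * 2 >= shorter


def align_read(
    read_id: str,
    nt: str,
    index: FMIndex,
    code: GeneticCode | None = None,
    policy: OrfPolicy | None = None,
    params: AlignParams | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> ReadResult:
    """ORF-filter, seed, chain and extend one read; keep the best frame.

    Ties break toward the earlier frame in the order +1,+2,+3,-1,-2,-3,
    then the lexicographically smaller entry id, then the smaller start.
    The second-best distinct locus across all frames feeds the MAPQ.
    """
    code = code or GeneticCode.standard()
    policy = policy or OrfPolicy()
    params = params or AlignParams()
    matrix = matrix or SubstitutionMatrix.blosum62()

    frameset = six_frame(read_id, nt, code, policy)
    passing = frameset.passing()
    if not passing:
        return ReadResult(read_id, nt, None, "orf_filter")

    candidates: list[tuple[tuple, Alignment]] = []
    any_seed = False
    for frame in passing:
        seeds = find_smems(
            index, frame.aa, params.min_seed_len, params.max_hits_per_seed
        )
        if not seeds:
            continue
        any_seed = True
        chains = chain_seeds(seeds, index.reference, params.band_width)
        for chain in chains[: params.max_chains_per_frame]:
            aln = extend_chain(index.reference, chain, frame.aa, params, matrix)
            if aln is None:
                continue
            aln.read_id = read_id
            aln.frame_id = frame.frame_id
            key = (
                -aln.penalized_score,
                FRAME_ORDER[frame.frame_id],
                aln.entry_id,
                aln.ref_begin,
            )
            candidates.append((key, aln))
    if not candidates:
        cause = "no_seed" if not any_seed else "low_score"
        return ReadResult(read_id, nt, None, cause)

    candidates.sort(key=lambda t: t[0])
    kept: list[Alignment] = []
    for _key, aln in candidates:
        if not any(_overlaps(aln, k) for k in kept):
            kept.append(aln)
        if len(kept) >= 2:
            break
    best = kept[0]
    second = kept[1].raw_score if len(kept) > 1 else None
    if second is not None and second > best.raw_score:
        second = best.raw_score  # penalized ordering may invert raw scores
    best.secondary_score = second or 0
    best.mapq = score_to_mapq(best.raw_score, second, best.seed_coverage, params)
    return ReadResult(read_id, nt, best)
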