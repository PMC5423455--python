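"""Protein reference loading and FM-index construction.

Three reference types can be indexed: a protein FASTA (sequences used as-is),
a transcriptome FASTA (each record translated in frame +1), and a genome
FASTA with a GFF3 annotation (CDS features extracted, spliced and
translated).  The packed reference text concatenates all protein entries,
each terminated by a sentinel so exact matches can never span two proteins.

The FM-index couples a Burrows-Wheeler transform with occurrence
checkpoints and a sampled suffix array; a second index over the
per-entry-reversed text is kept alongside for forward extension.
Sentinels are given mutually distinct ranks (by entry order) during suffix
sorting, which keeps the LF mapping a single cycle over the whole text.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from . import _kernels
from .alphabet import AA_LETTERS, encode_aa, normalize_protein

INDEX_MAGIC = "PROTALN-IDX"
INDEX_VERSION = 1

DEFAULT_OCC_STRIDE = 128
DEFAULT_SA_RATE = 32


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


class CorruptIndexError(IOError):
    """Persisted index failed its magic/version/integrity checks."""


@dataclass
class ProteinEntry:
    id: str
    description: str
    sequence: str


@dataclass
class ProteinReference:
    """Ordered, uniquely named amino-acid sequences plus their provenance."""

    entries: list[ProteinEntry]
    source_mode: str = "protein"  # protein | transcriptome | genome_gff
    internal_stop_warnings: int = 0

    def __post_init__(self):
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ReferenceError(f"duplicate reference ids: {dup}")
        for e in self.entries:
            if not e.sequence:
                raise ReferenceError(f"empty sequence for entry {e.id!r}")

    def __len__(self):
        return len(self.entries)

    def get(self, entry_id: str) -> ProteinEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)


@dataclass
class PackedText:
    """Concatenated coded sequences, one sentinel (code 0) after each."""

    codes: np.ndarray  # int8, sentinel = 0
    boundaries: np.ndarray  # int64 start offset of each entry

    @property
    def n(self) -> int:
        return int(self.codes.size)

    def locate(self, offset: int) -> tuple[int, int]:
        """Map a global text offset to (entry index, local offset)."""
        idx = int(np.searchsorted(self.boundaries, offset, side="right")) - 1
        return idx, offset - int(self.boundaries[idx])


def pack_reference(ref: ProteinReference) -> PackedText:
    parts = []
    bounds = []
    pos = 0
    for e in ref.entries:
        bounds.append(pos)
        c = encode_aa(e.sequence)
        parts.append(c)
        parts.append(np.zeros(1, dtype=np.int8))
        pos += c.size + 1
    return PackedText(np.concatenate(parts), np.asarray(bounds, dtype=np.int64))


# ---------------------------------------------------------------------------
# reference loaders


def _read_fasta(path) -> list[tuple[str, str, str]]:
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if len(rec.seq) == 0:
                raise ReferenceError(f"record {rec.id!r} has an empty sequence")
            out.append((rec.id, rec.description, str(rec.seq)))
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ReferenceError(f"malformed FASTA in {path}: {exc}") from exc
    if not out:
        raise ReferenceError(f"no FASTA records found in {path}")
    return out


def load_protein_fasta(path) -> ProteinReference:
    """Load a protein FASTA; strips a trailing '*', folds ambiguity codes."""
    entries = [
        ProteinEntry(rid, desc, normalize_protein(seq))
        for rid, desc, seq in _read_fasta(path)
    ]
    return ProteinReference(entries, source_mode="protein")


_NT_VALID = set("ACGTUNRYSWKMBDHV")


def _check_nt(seq: str, rid: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _NT_VALID
    if bad:
        raise ReferenceError(
            f"record {rid!r} contains non-nucleotide characters: {sorted(bad)}"
        )
    return seq


def load_transcriptome(path, code=None) -> ProteinReference:
    """Translate every nucleotide record in frame +1 (trailing codon dropped)."""
    from .orf_translate import GeneticCode

    code = code or GeneticCode.standard()
    entries = []
    for rid, desc, seq in _read_fasta(path):
        nt = _check_nt(seq, rid)
        aa = code.translate(nt[: len(nt) - len(nt) % 3])
        entries.append(ProteinEntry(rid, desc, normalize_protein(aa)))
    return ProteinReference(entries, source_mode="transcriptome")


def load_genome_with_gff(fasta_path, gff_path, code=None) -> ProteinReference:
    """Extract CDS features from a GFF3 annotation and translate them.

    CDS segments sharing an ID (or Parent) attribute are spliced in
    coordinate order; '-' strand groups are reverse-complemented and the
    first segment's phase (in translation orientation) is applied.  Internal
    stops are replaced by 'X' and counted as warnings.
    """
    import gffutils

    from .orf_translate import GeneticCode, reverse_complement

    code = code or GeneticCode.standard()
    genomes = {rid: _check_nt(seq, rid) for rid, _d, seq in _read_fasta(fasta_path)}

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    groups: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        # segments of one coding sequence share Parent (or failing that, ID)
        attrs = feat.attributes
        key = attrs.get("Parent", attrs.get("ID", [feat.id]))[0]
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(feat)

    entries = []
    warnings = 0
    for key in order:
        feats = sorted(groups[key], key=lambda f: f.start)
        strand = feats[0].strand
        chrom = feats[0].seqid
        if chrom not in genomes:
            raise ReferenceError(f"CDS {key!r} references missing seqid {chrom!r}")
        spliced = "".join(genomes[f.seqid][f.start - 1 : f.end] for f in feats)
        if strand == "-":
            spliced = reverse_complement(spliced)
            phase_feat = feats[-1]
        else:
            phase_feat = feats[0]
        phase = int(phase_feat.frame) if phase_feat.frame not in (None, ".") else 0
        spliced = spliced[phase:]
        spliced = spliced[: len(spliced) - len(spliced) % 3]
        aa = code.translate(spliced)
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            warnings += aa.count("*")
            aa = aa.replace("*", "X")
        if aa:
            entries.append(ProteinEntry(key, f"CDS {chrom}:{feats[0].start}", aa))
    ref = ProteinReference(entries, source_mode="genome_gff")
    ref.internal_stop_warnings = warnings
    return ref


# ---------------------------------------------------------------------------
# suffix array / BWT


def build_suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n); correctness first).

    ``codes`` must make all suffixes distinct (our sentinels are ranked
    distinct before calling), so the sort is total.
    """
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes.astype(np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        diff = np.empty(n, dtype=np.int64)
        diff[0] = 0
        diff[1:] = (rank[order[1:]] != rank[order[:-1]]) | (
            second[order[1:]] != second[order[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(diff)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


@dataclass
class _FMCore:
    """BWT + rank checkpoints + sampled SA for one text direction."""

    bwt: np.ndarray  # int8; sentinels collapsed to 0
    counts_before: np.ndarray  # int64 per symbol code (the C array)
    occ_ck: np.ndarray  # int32 (n_blocks+1, 22)
    sent_rows: np.ndarray  # rows whose BWT symbol is a sentinel (sorted)
    sent_ids: np.ndarray  # entry index of each such sentinel
    sampled: np.ndarray  # uint8 mask over rows
    sample_rank: np.ndarray  # int64 prefix index into samples
    samples: np.ndarray  # int64 sampled SA values
    occ_stride: int
    sa_sample_rate: int

    @property
    def n(self) -> int:
        return int(self.bwt.size)

    @classmethod
    def build(cls, packed: PackedText, occ_stride: int, sa_rate: int) -> "_FMCore":
        codes = packed.codes
        n = codes.size
        n_letters = len(AA_LETTERS)
        # rank sentinels distinct, by text order, below every letter
        sent_pos = np.flatnonzero(codes == 0)
        m = sent_pos.size
        ranked = codes.astype(np.int64) + m
        ranked[sent_pos] = np.arange(m)
        sa = build_suffix_array(ranked)

        prev = sa - 1
        prev[prev < 0] = n - 1
        bwt = codes[prev]
        sent_rows = np.flatnonzero(bwt == 0).astype(np.int64)
        # entry index of the sentinel found at text position prev[row]
        sent_entry_of_pos = {int(p): i for i, p in enumerate(sent_pos)}
        sent_ids = np.array(
            [sent_entry_of_pos[int(prev[r])] for r in sent_rows], dtype=np.int64
        )

        counts = np.bincount(bwt, minlength=n_letters + 1).astype(np.int64)
        counts_before = np.zeros(n_letters + 2, dtype=np.int64)
        counts_before[1:-1] = np.cumsum(counts)[:-1]
        counts_before[-1] = n  # stop code: empty interval

        n_blocks = n // occ_stride + 1
        occ_ck = np.zeros((n_blocks + 1, n_letters + 1), dtype=np.int32)
        onehot = np.zeros((n, n_letters + 1), dtype=np.int32)
        onehot[np.arange(n), bwt] = 1
        csum = np.cumsum(onehot, axis=0)
        for b in range(1, n_blocks + 1):
            end = min(b * occ_stride, n)
            occ_ck[b] = csum[end - 1]

        sampled = (sa % sa_rate == 0).astype(np.uint8)
        sample_rank = np.zeros(n, dtype=np.int64)
        sample_rank[sampled == 1] = np.arange(int(sampled.sum()))
        samples = sa[sampled == 1].astype(np.int64)
        return cls(
            bwt.astype(np.int8), counts_before, occ_ck, sent_rows, sent_ids,
            sampled, sample_rank, samples, occ_stride, sa_rate,
        )

    # --- queries -----------------------------------------------------------

    def backward_search(self, pattern_codes: np.ndarray) -> tuple[int, int]:
        return _kernels.backward_search(
            pattern_codes, self.bwt, self.occ_ck, self.occ_stride,
            self.counts_before, self.n,
        )

    def count(self, pattern_codes: np.ndarray) -> int:
        l, r = self.backward_search(pattern_codes)
        return r - l

    def matching_statistics(self, query_codes: np.ndarray) -> np.ndarray:
        return _kernels.matching_statistics(
            query_codes, self.bwt, self.occ_ck, self.occ_stride,
            self.counts_before, self.n,
        )

    def sa_value(self, row: int) -> int:
        return int(
            _kernels.sa_lookup(
                row, self.bwt, self.occ_ck, self.occ_stride, self.counts_before,
                self.sent_rows, self.sent_ids, self.sampled, self.sample_rank,
                self.samples,
            )
        )

    def lf(self, row: int) -> int:
        return int(
            _kernels.lf(
                row, self.bwt, self.occ_ck, self.occ_stride, self.counts_before,
                self.sent_rows, self.sent_ids,
            )
        )


@dataclass
class FMIndex:
    """FM-index over the packed protein text plus its reversed twin."""

    reference: ProteinReference
    packed: PackedText
    forward: _FMCore
    reverse_index: _FMCore
    occ_stride: int = DEFAULT_OCC_STRIDE
    sa_sample_rate: int = DEFAULT_SA_RATE

    def locate(self, row: int) -> tuple[int, int]:
        """Resolve a forward-index row to (entry index, local offset)."""
        return self.packed.locate(self.forward.sa_value(row))

    def count(self, aa: str) -> int:
        return self.forward.count(encode_aa(aa))


def build_fm_index(
    ref: ProteinReference,
    occ_stride: int = DEFAULT_OCC_STRIDE,
    sa_sample_rate: int = DEFAULT_SA_RATE,
) -> FMIndex:
    if occ_stride < 1 or sa_sample_rate < 1:
        raise ValueError("occ_stride and sa_sample_rate must be positive")
    if not ref.entries:
        raise ReferenceError("cannot index an empty reference")
    packed = pack_reference(ref)
    forward = _FMCore.build(packed, occ_stride, sa_sample_rate)
    rev_entries = [
        ProteinEntry(e.id, e.description, e.sequence[::-1]) for e in ref.entries
    ]
    rev_packed = pack_reference(
        ProteinReference(rev_entries, source_mode=ref.source_mode)
    )
    reverse = _FMCore.build(rev_packed, occ_stride, sa_sample_rate)
    return FMIndex(ref, packed, forward, reverse, occ_stride, sa_sample_rate)


# ---------------------------------------------------------------------------
# persistence

_CORE_FIELDS = (
    "bwt", "counts_before", "occ_ck", "sent_rows", "sent_ids",
    "sampled", "sample_rank", "samples",
)


def save_index(index: FMIndex, path) -> None:
    arrays = {
        "magic": np.array(INDEX_MAGIC),
        "version": np.array(INDEX_VERSION, dtype=np.int64),
        "source_mode": np.array(index.reference.source_mode),
        "ids": np.array([e.id for e in index.reference.entries]),
        "descriptions": np.array([e.description for e in index.reference.entries]),
        "sequences": np.array([e.sequence for e in index.reference.entries]),
        "params": np.array([index.occ_stride, index.sa_sample_rate], dtype=np.int64),
        "packed_codes": index.packed.codes,
        "packed_bounds": index.packed.boundaries,
    }
    for tag, core in (("fwd", index.forward), ("rev", index.reverse_index)):
        for f in _CORE_FIELDS:
            arrays[f"{tag}_{f}"] = getattr(core, f)
    with open(path, "wb") as fh:
        np.savez_compressed(fh, **arrays)


def load_index(path) -> FMIndex:
    try:
        with np.load(path, allow_pickle=False) as z:
            if "magic" not in z or str(z["magic"]) != INDEX_MAGIC:
                raise CorruptIndexError(f"{path}: not a protaln index (bad magic)")
            if int(z["version"]) != INDEX_VERSION:
                raise CorruptIndexError(
                    f"{path}: unsupported index version {int(z['version'])}"
                )
            entries = [
                ProteinEntry(str(i), str(d), str(s))
                for i, d, s in zip(z["ids"], z["descriptions"], z["sequences"])
            ]
            ref = ProteinReference(entries, source_mode=str(z["source_mode"]))
            stride, rate = (int(v) for v in z["params"])
            packed = PackedText(z["packed_codes"], z["packed_bounds"])
            cores = {}
            for tag in ("fwd", "rev"):
                fields = {f: z[f"{tag}_{f}"] for f in _CORE_FIELDS}
                cores[tag] = _FMCore(
                    occ_stride=stride, sa_sample_rate=rate, **fields
                )
    except CorruptIndexError:
        raise
    except Exception as exc:
        raise CorruptIndexError(f"{path}: corrupt or truncated index ({exc})") from exc
    return FMIndex(ref, packed, cores["fwd"], cores["rev"], stride, rate)
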