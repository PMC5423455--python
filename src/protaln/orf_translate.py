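"""Six-frame translation of DNA reads and the stop-codon ORF filter.

A read is only worth aligning in protein space if at least one of its six
reading frames looks like it came from a coding region, i.e. contains a
sufficiently long stop-free stretch.  Reads failing this in every frame are
discarded before seeding, which is where most of the aligner's speed on
non-coding input comes from.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio.Data import CodonTable

FRAME_IDS = (1, 2, 3, -1, -2, -3)

_IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def reverse_complement(nt: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    invalid = set(nt.upper()) - set(_IUPAC_NT)
    if invalid:
        raise ValueError(f"invalid nucleotide characters: {sorted(invalid)}")
    return nt.translate(_COMPLEMENT)[::-1]


class GeneticCode:
    """Codon -> amino-acid mapping with IUPAC-ambiguity resolution.

    Ambiguous codons translate to a single letter only when every expansion
    agrees (e.g. GGN -> G); otherwise 'X'.  Stops are '*'.
    """

    def __init__(self, table: dict[str, str], name: str):
        if len([c for c in table if set(c) <= set("ACGT")]) != 64:
            raise ValueError("genetic code must map all 64 unambiguous codons")
        self.table = table
        self.name = name

    @classmethod
    def from_ncbi_table(cls, table_id: int) -> "GeneticCode":
        bio = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(bio.forward_table)
        for stop in bio.stop_codons:
            table[stop] = "*"
        return cls(table, bio.names[0])

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_table(1)

    def codon(self, c: str) -> str:
        c = c.upper().replace("U", "T")
        aa = self.table.get(c)
        if aa is not None:
            return aa
        try:
            expansions = {
                self.table["".join(e)]
                for e in itertools.product(*(_IUPAC_NT[b] for b in c))
            }
        except KeyError as exc:
            raise ValueError(f"invalid codon {c!r}") from exc
        return expansions.pop() if len(expansions) == 1 else "X"

    def translate(self, nt: str) -> str:
        nt = nt.upper().replace("U", "T")
        return "".join(self.codon(nt[i : i + 3]) for i in range(0, len(nt) - 2, 3))


def translate_frame(nt: str, frame_id: int, code: GeneticCode) -> str:
    """Translate one of the six frames; negative frames use the reverse
    complement.  Short input yields an empty string."""
    if frame_id not in FRAME_IDS:
        raise ValueError(f"frame_id must be one of {FRAME_IDS}")
    seq = nt if frame_id > 0 else reverse_complement(nt)
    offset = abs(frame_id) - 1
    return code.translate(seq[offset:])


@dataclass
class OrfPolicy:
    """Minimum stop-free length required for a frame to pass, either as an
    absolute nucleotide length or a fraction of the read length."""

    mode: str = "relative"  # absolute | relative
    absolute_nt: int = 250
    relative_fraction: float = 0.80

    def threshold_nt(self, read_len: int) -> int:
        if self.mode == "absolute":
            return self.absolute_nt
        if self.mode == "relative":
            return int(self.relative_fraction * read_len)
        raise ValueError(f"unknown ORF policy mode {self.mode!r}")

    def threshold_residues(self, read_len: int) -> int:
        return self.threshold_nt(read_len) // 3


@dataclass
class FrameRecord:
    frame_id: int
    aa: str
    longest_stop_free_run: int
    passes_orf: bool


@dataclass
class ReadFrameSet:
    read_id: str
    nt: str
    frames: list[FrameRecord]

    def passing(self) -> list[FrameRecord]:
        return [f for f in self.frames if f.passes_orf]


def longest_stop_free_run(aa: str) -> int:
    return max((len(run) for run in aa.split("*")), default=0)


def six_frame(
    read_id: str, nt: str, code: GeneticCode, policy: OrfPolicy
) -> ReadFrameSet:
    """Translate all six frames and apply the ORF filter to each."""
    thr = policy.threshold_residues(len(nt))
    frames = []
    for fid in FRAME_IDS:
        aa = translate_frame(nt, fid, code)
        run = longest_stop_free_run(aa)
        frames.append(FrameRecord(fid, aa, run, bool(aa) and run >= thr))
    return ReadFrameSet(read_id, nt, frames)


def filter_read(frameset: ReadFrameSet) -> list[FrameRecord]:
    """Frames that survive the ORF filter; empty means the read is dropped
    before alignment (tallied as ORF-discarded by the caller)."""
    return frameset.passing()
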