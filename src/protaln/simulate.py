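"""Synthetic mock-metagenome generator with embedded ground truth.

Emulates the positive-control construction used to validate translated-read
alignment: a pool of annotated coding sequences, a nucleotide genome with a
GFF3 annotation derived from them, and 250 bp paired-end reads carrying an
Illumina-like error profile (substitution rate ramping up toward the 3'
end, rare short indels).  Every read name encodes its source entry, start
offset and strand (``sim|<entry>|<start>|<strand>|<serial>``) so downstream
evaluation can decide correctness without any side table.

A divergence operator produces a homolog-only reference (residues
substituted with BLOSUM-biased draws, ids suffixed ``_hom``) so mapping can
be tested on functional similarity rather than sequence identity.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import AA_LETTERS
from .index import ProteinEntry, ProteinReference
from .orf_translate import GeneticCode, reverse_complement

# UniProt-wide average amino-acid composition (percent)
AA_FREQS = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic positive control."""

    n_proteins: int = 50
    #: lognormal length distribution (log-space mean/sigma), floored so a
    #: protein can host at least one full sequencing fragment
    protein_log_mean: float = math.log(300.0)
    protein_log_sigma: float = 0.25
    min_protein_len: int = 230
    read_length: int = 250
    n_read_pairs: int = 10_000
    insert_mean: float = 600.0
    insert_sd: float = 60.0
    #: mean per-base substitution error; ramps linearly 5'->3'
    error_rate: float = 0.01
    indel_rate: float = 1e-4
    divergence: float = 0.0
    n_genomes: int = 1
    minus_strand_fraction: float = 0.5
    intergenic_len: int = 120
    seed: int = 0

    def __post_init__(self):
        for r in (self.error_rate, self.indel_rate, self.divergence):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthRecord:
    read_id: str
    true_entry: str
    true_start: int  # nt offset of the fragment in its CDS
    strand: str  # fragment orientation relative to the CDS


READ_NAME_PREFIX = "sim"


def make_read_name(entry: str, start: int, strand: str, serial: int) -> str:
    return f"{READ_NAME_PREFIX}|{entry}|{start}|{strand}|{serial}"


def parse_read_name(name: str) -> TruthRecord:
    parts = name.split("|")
    if len(parts) != 5 or parts[0] != READ_NAME_PREFIX:
        raise ValueError(f"read name {name!r} does not carry simulation truth")
    return TruthRecord(name, parts[1], int(parts[2]), parts[3])


# ---------------------------------------------------------------------------
# toy ontology


def make_toy_ontology(n_children: int = 4, n_grandchildren: int = 5) -> str:
    """OBO 1.2 text for a three-namespace toy ontology (two levels deep)."""
    namespaces = ["biological_process", "molecular_function", "cellular_component"]
    lines = ["format-version: 1.2", "ontology: toy-go", ""]
    counter = 1

    def term(name, namespace, parent=None):
        nonlocal counter
        tid = f"GO:{counter:07d}"
        counter += 1
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {namespace}")
        if parent:
            lines.append(f"is_a: {parent} ! parent")
        lines.append("")
        return tid

    leaves = []
    for ns in namespaces:
        root = term(ns, ns)
        for c in range(n_children):
            child = term(f"{ns} child {c}", ns, root)
            for g in range(n_grandchildren):
                leaves.append(term(f"{ns} leaf {c}.{g}", ns, child))
    return "\n".join(lines)


def toy_ontology_leaves(obo_text: str) -> list[str]:
    """Terms that never appear as an is_a parent, in id order."""
    ids, parents = [], set()
    for line in obo_text.splitlines():
        if line.startswith("id: "):
            ids.append(line[4:].strip())
        elif line.startswith("is_a: "):
            parents.add(line[6:].split("!")[0].strip())
    return [t for t in ids if t not in parents]


# ---------------------------------------------------------------------------
# proteome generation


def generate_proteome(
    config: SimConfig,
) -> tuple[ProteinReference, dict[str, set[str]], str]:
    """Random proteome + GO assignments + toy ontology OBO text.

    Residues follow the average database composition; each protein carries
    1-5 leaf terms of the toy ontology so the similarity index is defined.
    """
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(AA_FREQS))
    probs = np.array(list(AA_FREQS.values()))
    probs = probs / probs.sum()
    obo = make_toy_ontology()
    leaves = toy_ontology_leaves(obo)
    entries = []
    go: dict[str, set[str]] = {}
    for i in range(config.n_proteins):
        length = max(
            config.min_protein_len,
            int(rng.lognormal(config.protein_log_mean, config.protein_log_sigma)),
        )
        seq = "".join(rng.choice(letters, size=length, p=probs))
        pid = f"prot{i:04d}"
        n_terms = int(rng.integers(1, 6))
        terms = set(rng.choice(leaves, size=n_terms, replace=False))
        entries.append(ProteinEntry(pid, f"synthetic protein {i}", seq))
        go[pid] = terms
    return ProteinReference(entries, source_mode="protein"), go, obo


# ---------------------------------------------------------------------------
# reverse translation to genome + GFF


def _codon_choices(code: GeneticCode) -> dict[str, list[str]]:
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(code.table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa


@dataclass
class SyntheticGenome:
    chromosomes: list[tuple[str, str]]  # (chrom id, sequence)
    gff_lines: list[str]
    cds_nt: dict[str, str]  # entry id -> spliced CDS in coding orientation
    entry_genome: dict[str, str]

    def gff_text(self) -> str:
        return "\n".join(["##gff-version 3"] + self.gff_lines) + "\n"

    def fasta_text(self) -> str:
        out = []
        for cid, seq in self.chromosomes:
            out.append(f">{cid}")
            out.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
        return "\n".join(out) + "\n"


def reverse_translate(
    proteome: ProteinReference,
    codon_usage: dict[str, list[str]] | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
) -> SyntheticGenome:
    """Emit a genome FASTA + GFF3 whose CDS translate back to the proteome.

    Codons are drawn uniformly among synonyms unless a usage table is
    given; a stop codon terminates each CDS; a configurable fraction of CDS
    land on the '-' strand.
    """
    config = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed + 7)
    code = GeneticCode.standard()
    choices = codon_usage or _codon_choices(code)
    nt_alpha = np.array(list("ACGT"))
    chroms: list[tuple[str, str]] = []
    gff: list[str] = []
    cds_nt: dict[str, str] = {}
    entry_genome: dict[str, str] = {}
    per_genome = math.ceil(len(proteome.entries) / config.n_genomes)
    for g in range(config.n_genomes):
        chrom_id = f"genome{g + 1}"
        parts = []
        pos = 0
        for e in proteome.entries[g * per_genome : (g + 1) * per_genome]:
            spacer = "".join(
                rng.choice(nt_alpha, size=config.intergenic_len)
            )
            parts.append(spacer)
            pos += len(spacer)
            codons = [
                choices[aa][rng.integers(0, len(choices[aa]))]
                for aa in e.sequence
            ]
            codons.append(choices["*"][rng.integers(0, len(choices["*"]))])
            cds = "".join(codons)
            cds_nt[e.id] = cds
            entry_genome[e.id] = chrom_id
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            emitted = reverse_complement(cds) if strand == "-" else cds
            start = pos + 1  # GFF3 is 1-based inclusive
            end = pos + len(cds)
            gff.append(
                "\t".join(
                    [
                        chrom_id, "protaln-sim", "CDS", str(start), str(end),
                        ".", strand, "0", f"ID={e.id};Parent={e.id}",
                    ]
                )
            )
            parts.append(emitted)
            pos = end
        parts.append("".join(rng.choice(nt_alpha, size=config.intergenic_len)))
        chroms.append((chrom_id, "".join(parts)))
    return SyntheticGenome(chroms, gff, cds_nt, entry_genome)


# ---------------------------------------------------------------------------
# read simulation

_NT = np.array(list("ACGT"))
_NT_IDX = {c: i for i, c in enumerate("ACGT")}


@dataclass
class SimulatedRead:
    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def _ramp_rates(length: int, mean_rate: float) -> np.ndarray:
    """Linear 5'->3' substitution-rate ramp with the requested mean."""
    if length == 1:
        return np.array([mean_rate])
    ramp = np.linspace(1.0 / 3.0, 5.0 / 3.0, length)
    return np.clip(mean_rate * ramp, 0.0, 0.95)


def _apply_errors(seq: str, rates: np.ndarray, indel_rate: float, rng) -> tuple[str, str]:
    out = []
    quals = []
    i = 0
    n = len(seq)
    while i < n and len(out) < n:
        p = rates[len(out)]
        r = rng.random()
        if r < indel_rate / 2:  # deletion
            i += 1
            continue
        if r < indel_rate:  # insertion
            out.append(str(rng.choice(_NT)))
        else:
            base = seq[i]
            if rng.random() < p and base in _NT_IDX:
                alt = _NT[(rng.integers(1, 4) + _NT_IDX[base]) % 4]
                out.append(str(alt))
            else:
                out.append(base)
            i += 1
        q = int(min(40, max(2, round(-10 * math.log10(max(p, 1e-4))))))
        quals.append(chr(q + 33))
    # pad if deletions shortened the read (keeps read length constant)
    while len(out) < n:
        out.append(str(rng.choice(_NT)))
        quals.append(chr(2 + 33))
    return "".join(out), "".join(quals)


def simulate_reads(
    genome: SyntheticGenome,
    config: SimConfig,
) -> tuple[list[SimulatedRead], list[TruthRecord]]:
    """Paired 250 bp reads sampled uniformly from the CDS pool.

    Mate 1 reads the fragment's 5' end forward; mate 2 reads the 3' end on
    the opposite strand.  Fragment orientation relative to the CDS is
    random and recorded in the truth (and the read name).
    """
    rng = np.random.default_rng(config.seed + 13)
    entries = sorted(genome.cds_nt)
    reads: list[SimulatedRead] = []
    truth: list[TruthRecord] = []
    L = config.read_length
    for serial in range(config.n_read_pairs):
        entry = entries[int(rng.integers(0, len(entries)))]
        cds = genome.cds_nt[entry]
        insert = int(
            min(len(cds), max(L, rng.normal(config.insert_mean, config.insert_sd)))
        )
        start = int(rng.integers(0, len(cds) - insert + 1))
        frag = cds[start : start + insert]
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            frag = reverse_complement(frag)
        name = make_read_name(entry, start, strand, serial)
        r1 = frag[:L]
        r2 = reverse_complement(frag[-L:])
        rates = _ramp_rates(L, config.error_rate)
        s1, q1 = _apply_errors(r1, rates, config.indel_rate, rng)
        s2, q2 = _apply_errors(r2, rates, config.indel_rate, rng)
        reads.append(SimulatedRead(name, s1, q1, s2, q2))
        truth.append(TruthRecord(name, entry, start, strand))
    return reads, truth


# ---------------------------------------------------------------------------
# reference divergence


def _blosum_transition_probs() -> tuple[np.ndarray, dict[str, int]]:
    """P(b | a substituted), b != a, proportional to 2^(BLOSUM62[a,b]/2)."""
    mat = substitution_matrices.load("BLOSUM62")
    letters = [a for a in AA_FREQS]
    idx = {a: i for i, a in enumerate(letters)}
    probs = np.zeros((20, 20))
    for a in letters:
        w = np.array(
            [0.0 if b == a else 2.0 ** (mat[a, b] / 2.0) for b in letters]
        )
        probs[idx[a]] = w / w.sum()
    return probs, idx


def diverge_reference(
    proteome: ProteinReference,
    divergence: float,
    seed: int = 0,
    go: dict[str, set[str]] | None = None,
) -> tuple[ProteinReference, dict[str, set[str]] | None]:
    """Homolog-only reference: substitute residues with probability
    ``divergence`` using BLOSUM-biased draws; ids gain a ``_hom`` suffix."""
    rng = np.random.default_rng(seed + 29)
    probs, idx = _blosum_transition_probs()
    letters = list(AA_FREQS)
    entries = []
    for e in proteome.entries:
        seq = list(e.sequence)
        for i, a in enumerate(seq):
            if a in idx and rng.random() < divergence:
                seq[i] = letters[
                    int(rng.choice(20, p=probs[idx[a]]))
                ]
        entries.append(ProteinEntry(e.id + "_hom", e.description, "".join(seq)))
    hom_go = (
        {e.id + "_hom": set(go[e.id]) for e in proteome.entries} if go else None
    )
    return ProteinReference(entries, source_mode="protein"), hom_go


# ---------------------------------------------------------------------------
# file emission


def write_fastq_pair(reads: list[SimulatedRead], path1, path2) -> None:
    def opener(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")

    with opener(path1) as f1, opener(path2) as f2:
        for r in reads:
            f1.write(f"@{r.name}/1\n{r.seq1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.name}/2\n{r.seq2}\n+\n{r.qual2}\n")


def write_truth_tsv(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttrue_entry\ttrue_start\tstrand\n")
        for t in truth:
            fh.write(f"{t.read_id}\t{t.true_entry}\t{t.true_start}\t{t.strand}\n")


def write_proteome_fasta(ref: ProteinReference, path) -> None:
    with open(path, "w") as fh:
        for e in ref.entries:
            fh.write(f">{e.id} {e.description}\n")
            for i in range(0, len(e.sequence), 70):
                fh.write(e.sequence[i : i + 70] + "\n")


def write_go_tsv(go: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for key in sorted(go):
            fh.write(f"{key}\t{','.join(sorted(go[key]))}\n")
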