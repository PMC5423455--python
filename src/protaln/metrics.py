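"""Evaluation statistics for simulated-truth runs and cross-tool comparison.

Two summaries are produced.  ``evaluate`` scores an alignment run against
the simulator's embedded truth: percent mapped, percent correctly mapped,
mean mapping quality, distinct proteins detected above a quality cutoff,
and the GO-closure similarity index.  ``consensus`` compares a run against
another aligner's output: the fraction of high-confidence alignments both
tools agree on, and the quality magnitude — the base-10
order-of-magnitude gap between the mean bit score of consensus alignments
(a) and of the best alignments the other tool produced for reads this
aligner rejected (b), computed as (a - b) * log10(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pysam

from .go_similarity import GOGraph, closure, jaccard
from .simulate import parse_read_name

# Karlin-Altschul constants for gapped BLOSUM62 (gap open 11, extend 1)
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass
class EvalSummary:
    reads_total: int
    reads_mapped_pct: float
    correctly_mapped_pct: float
    mean_mapq: float
    detected_proteins: int
    similarity_index: float
    orf_discarded_count: int
    excluded_from_similarity: int = 0


def _strip_hom(entry_id: str) -> str:
    return entry_id[:-4] if entry_id.endswith("_hom") else entry_id


def _iter_sam(path):
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_secondary or seg.is_supplementary:
                continue
            cause = seg.get_tag("YU") if seg.has_tag("YU") else None
            yield (
                seg.query_name,
                None if seg.is_unmapped else seg.reference_name,
                seg.mapping_quality,
                cause,
            )


def _iter_results(results):
    for item in results:
        for res in item if isinstance(item, tuple) else (item,):
            if res.mapped:
                yield res.read_id, res.alignment.entry_id, res.alignment.mapq, None
            else:
                yield res.read_id, None, 0, res.unmapped_cause


def evaluate(
    source,
    annotations: dict[str, set[str]] | None = None,
    graph: GOGraph | None = None,
    q_detect: int = 20,
) -> EvalSummary:
    """Score a run whose read names carry simulation truth.

    ``source`` is a SAM path or a list of read results.  ``annotations``
    maps entry id -> GO terms (used for both the true and the mapped side;
    homolog ``_hom`` ids are normalized).  A read is correctly mapped when
    its target entry equals its true source entry.
    """
    rows = (
        _iter_sam(source)
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__")
        else _iter_results(source)
    )
    total = mapped = correct = orf_discarded = 0
    mapq_sum = 0
    detected: set[str] = set()
    sims = []
    excluded = 0
    for name, entry, mapq, cause in rows:
        total += 1
        truth = parse_read_name(name.split("/")[0])
        if entry is None:
            if cause == "orf_filter":
                orf_discarded += 1
            continue
        mapped += 1
        mapq_sum += mapq
        if mapq >= q_detect:
            detected.add(entry)
        if _strip_hom(entry) == truth.true_entry:
            correct += 1
        if annotations is not None and graph is not None:
            true_terms = annotations.get(truth.true_entry, set())
            mapped_terms = annotations.get(
                entry, annotations.get(_strip_hom(entry), set())
            )
            if not true_terms:
                excluded += 1
                continue
            j = jaccard(closure(graph, true_terms), closure(graph, mapped_terms or set()))
            if math.isnan(j):
                excluded += 1
            else:
                sims.append(j)
    if total == 0:
        raise ValueError("no reads to evaluate")
    return EvalSummary(
        reads_total=total,
        reads_mapped_pct=100.0 * mapped / total,
        correctly_mapped_pct=100.0 * correct / total,
        mean_mapq=(mapq_sum / mapped) if mapped else 0.0,
        detected_proteins=len(detected),
        similarity_index=(sum(sims) / len(sims)) if sims else math.nan,
        orf_discarded_count=orf_discarded,
        excluded_from_similarity=excluded,
    )


# ---------------------------------------------------------------------------
# cross-tool comparison


@dataclass
class ComparisonSummary:
    consensus_pct: float
    mean_bits_consensus: float  # a
    mean_bits_unmapped: float  # b
    quality_magnitude: float  # (a - b) * log10(2)
    n_consensus: int
    n_unmapped_scored: int


def quality_magnitude(a: float, b: float) -> float:
    """Base-10 order-of-magnitude of a mean bit-score gap."""
    return (a - b) * math.log10(2.0)


def raw_score_to_bits(
    raw_score: float, lambda_: float = DEFAULT_LAMBDA, K: float = DEFAULT_K
) -> float:
    """Karlin-Altschul bit score: (lambda*S - ln K) / ln 2."""
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    return (lambda_ * raw_score - math.log(K)) / math.log(2.0)


def load_blast_tabular(path) -> dict[str, tuple[str, float]]:
    """Best (highest bit score) alignment per read from BLAST-style
    12-column tabular output (qseqid sseqid ... bitscore)."""
    best: dict[str, tuple[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            q, s, bits = f[0], f[1], float(f[-1])
            if q not in best or bits > best[q][1]:
                best[q] = (s, bits)
    return best


def consensus(
    pal,
    other: dict[str, tuple[str, float]],
    q_high: int = 50,
) -> ComparisonSummary:
    """Agreement between this aligner's high-quality mappings and another
    tool's best-per-read alignments (entry ids compared after '_hom'
    normalization)."""
    rows = (
        _iter_sam(pal)
        if isinstance(pal, (str, bytes)) or hasattr(pal, "__fspath__")
        else _iter_results(pal)
    )
    cons_bits = []
    unmapped_bits = []
    n_high_shared = 0
    n_agree = 0
    for name, entry, mapq, _cause in rows:
        key = name
        hit = other.get(key) or other.get(key.split("/")[0])
        if entry is not None and mapq >= q_high:
            if hit is None:
                continue
            n_high_shared += 1
            if _strip_hom(hit[0]) == _strip_hom(entry):
                n_agree += 1
                cons_bits.append(hit[1])
        else:
            if hit is not None:
                unmapped_bits.append(hit[1])
    if not cons_bits:
        raise ValueError(
            "no consensus reads: check that read names match between inputs "
            "and that the quality filter is not too strict"
        )
    a = sum(cons_bits) / len(cons_bits)
    b = sum(unmapped_bits) / len(unmapped_bits) if unmapped_bits else 0.0
    return ComparisonSummary(
        consensus_pct=100.0 * n_agree / n_high_shared,
        mean_bits_consensus=a,
        mean_bits_unmapped=b,
        quality_magnitude=quality_magnitude(a, b),
        n_consensus=len(cons_bits),
        n_unmapped_scored=len(unmapped_bits),
    )


def effective_rate(total_time_min: float, load_time_min: float, n_reads: int) -> float:
    """Alignments per minute after subtracting reference-load time."""
    if total_time_min < load_time_min:
        raise ValueError("total time must be >= load time")
    if total_time_min == load_time_min:
        raise ValueError("effective time is zero; rate undefined")
    return n_reads / (total_time_min - load_time_min)
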