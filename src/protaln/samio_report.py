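"""SAM emission and the tab-delimited functional report.

Alignments are written as standards-compliant SAM with coordinates and
CIGAR in amino-acid units over the kept frame's translation; the winning
frame is recorded in the ``YF`` tag, the original nucleotides in ``YN``,
and an unmapped read's cause (ORF filter, no seed, low score) in ``YU``.

The report groups primary alignments by target protein, giving per-protein
read counts (abundance) and mean mapping quality, optionally joined with
offline annotation (UniProt-style FASTA headers or a TSV table).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
import pysam

from .index import ProteinReference
from .seed_align import ReadResult

REPORT_COLUMNS = [
    "accession", "count", "mean_mapq", "gene", "description", "organism",
    "go_terms",
]


def sam_header(ref: ProteinReference) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": e.id, "LN": len(e.sequence)} for e in ref.entries
            ],
            "PG": [{"ID": "protaln", "PN": "protaln", "VN": "0.1.0"}],
        }
    )


def _to_segment(
    res: ReadResult,
    header: pysam.AlignmentHeader,
    mate: ReadResult | None = None,
    first_in_pair: bool | None = None,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = res.read_id
    flag = 0
    if first_in_pair is not None:
        flag |= 1 | (64 if first_in_pair else 128)
        if mate is not None and not mate.mapped:
            flag |= 8
    aln = res.alignment
    if aln is None:
        seg.flag = flag | 4
        seg.query_sequence = res.nt
        seg.set_tag("YU", res.unmapped_cause or "unknown", "Z")
        return seg
    if (
        mate is not None
        and mate.mapped
        and mate.alignment.entry_id == aln.entry_id
    ):
        flag |= 2
    seg.flag = flag
    seg.reference_id = header.get_tid(aln.entry_id)
    seg.reference_start = aln.ref_begin
    seg.mapping_quality = aln.mapq
    seg.cigarstring = aln.cigar_string()
    seg.query_sequence = aln.aligned_aa
    seg.set_tag("AS", aln.raw_score, "i")
    seg.set_tag("YF", f"{aln.frame_id:+d}", "Z")
    seg.set_tag("YN", res.nt, "Z")
    if aln.secondary_score:
        seg.set_tag("XS", aln.secondary_score, "i")
    return seg


def write_sam(
    results: list[ReadResult | tuple[ReadResult, ReadResult]],
    ref: ProteinReference,
    path,
) -> None:
    """Write read results (single reads or mate pairs) to a SAM file."""
    header = sam_header(ref)
    known = {e.id for e in ref.entries}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for item in results:
            if isinstance(item, tuple):
                r1, r2 = item
                segs = [
                    _to_segment(r1, header, mate=r2, first_in_pair=True),
                    _to_segment(r2, header, mate=r1, first_in_pair=False),
                ]
            else:
                segs = [_to_segment(item, header)]
            for res, seg in zip(
                item if isinstance(item, tuple) else (item,), segs
            ):
                if res.mapped and res.alignment.entry_id not in known:
                    raise ValueError(
                        f"alignment references unknown entry "
                        f"{res.alignment.entry_id!r}"
                    )
                out.write(seg)


@dataclass
class UniProtHeader:
    db: str = ""
    accession: str = ""
    entry_name: str = ""
    description: str = ""
    organism: str = ""
    gene: str = ""


_UNIPROT_RE = re.compile(r"^(sp|tr)\|([^|]+)\|(\S+)\s*(.*)$")


def parse_uniprot_header(text: str) -> UniProtHeader:
    """Best-effort parse of a UniProt-style FASTA header; never raises."""
    text = text.lstrip(">").strip()
    h = UniProtHeader()
    m = _UNIPROT_RE.match(text)
    if m:
        h.db, h.accession, h.entry_name, rest = m.groups()
    else:
        parts = text.split(None, 1)
        if not parts:
            return h
        h.accession = parts[0]
        rest = parts[1] if len(parts) > 1 else ""
    os_m = re.search(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)", rest)
    gn_m = re.search(r"\bGN=(\S+)", rest)
    if os_m:
        h.organism = os_m.group(1).strip()
    if gn_m:
        h.gene = gn_m.group(1)
    h.description = re.split(r"(?:^|\s)[A-Z]{2}=", rest)[0].strip()
    return h


def format_uniprot_header(h: UniProtHeader) -> str:
    core = f"{h.db}|{h.accession}|{h.entry_name}" if h.db else h.accession
    parts = [core]
    if h.description:
        parts.append(h.description)
    if h.organism:
        parts.append(f"OS={h.organism}")
    if h.gene:
        parts.append(f"GN={h.gene}")
    return " ".join(parts)


def load_annotation_tsv(path) -> pd.DataFrame:
    """Offline annotation table: accession, gene, description, organism,
    go_terms (comma-separated GO ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "accession" not in df.columns:
        raise ValueError(f"annotation table {path} lacks an 'accession' column")
    return df.set_index("accession")


def generate_report(
    source,
    annotation: pd.DataFrame | None = None,
    min_mapq: int = 0,
    ref: ProteinReference | None = None,
) -> pd.DataFrame:
    """Aggregate primary alignments per protein.

    ``source`` is a SAM path or a list of :class:`ReadResult`.  Rows are
    sorted by read count descending, then accession; mean_mapq is the
    arithmetic mean over contributing alignments.
    """
    rows = []
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as sam:
            for seg in sam:
                if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                    continue
                if seg.mapping_quality < min_mapq:
                    continue
                rows.append((seg.reference_name, seg.mapping_quality))
    else:
        for res in source:
            for r in res if isinstance(res, tuple) else (res,):
                if r.mapped and r.alignment.mapq >= min_mapq:
                    rows.append((r.alignment.entry_id, r.alignment.mapq))
    df = pd.DataFrame(rows, columns=["entry_id", "mapq"])
    if df.empty:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    grouped = (
        df.groupby("entry_id")
        .agg(count=("mapq", "size"), mean_mapq=("mapq", "mean"))
        .reset_index()
    )

    headers = {}
    if ref is not None:
        for e in ref.entries:
            headers[e.id] = parse_uniprot_header(f"{e.id} {e.description}")
    out = []
    for _, row in grouped.iterrows():
        entry_id = row["entry_id"]
        h = headers.get(entry_id, UniProtHeader(accession=entry_id))
        acc = h.accession or entry_id
        rec = {
            "accession": acc,
            "count": int(row["count"]),
            "mean_mapq": float(row["mean_mapq"]),
            "gene": h.gene,
            "description": h.description,
            "organism": h.organism,
            "go_terms": "",
        }
        if annotation is not None:
            for key in (acc, entry_id):
                if key in annotation.index:
                    ann = annotation.loc[key]
                    for col in ("gene", "description", "organism", "go_terms"):
                        if col in annotation.columns and ann[col]:
                            rec[col] = ann[col]
                    break
        out.append(rec)
    result = pd.DataFrame(out, columns=REPORT_COLUMNS)
    return result.sort_values(
        ["count", "accession"], ascending=[False, True]
    ).reset_index(drop=True)


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.2f")
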