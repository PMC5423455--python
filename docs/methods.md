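# Methods

## Model and pipeline

`protaln` treats read mapping as local alignment of translated reads
against a protein database. The pipeline is: six-frame translation →
stop-codon ORF filter → SMEM seeding on an amino-acid FM-index → per-
diagonal chaining → banded affine-gap Smith–Waterman extension →
best-frame selection → SAM + per-protein report. The guiding assumption
is that coding DNA diverges much faster than the proteins it encodes, so
matching in residue space recovers homologs that nucleotide mappers miss.
The aligner makes no attempt to model frameshifts inside a read: a frame
broken by an indel simply scores lower over its frameshifted tail, and
the intact portion determines the mapping. Remote homologs whose
similarity is structural rather than sequence-level are out of reach by
construction.

## Reference indexing

Three reference types are accepted: protein FASTA (used as-is),
transcriptome FASTA (each record translated in frame +1; reads still get
all six frames, so the sensitivity cost of fixing the reference frame is
limited to reference preparation), and genome FASTA + GFF3 (CDS features
grouped by `Parent`/`ID`, spliced in coordinate order, strand- and
phase-corrected, then translated; internal stops become `X` and are
counted as warnings).

The internal alphabet is the 20 canonical residues plus `X`; input
ambiguity codes are folded (`B→D, Z→E, J→L, U→C, O→K`) so BLOSUM scoring
stays defined everywhere. Entries are concatenated with one sentinel per
entry so exact matches can never span two proteins. For suffix sorting
the sentinels are ranked distinct (by entry order, below all residues),
which keeps every rotation distinct and the LF mapping a single cycle;
in the stored BWT they share one symbol and per-sentinel ranks are kept
in a small side table. The suffix array is built by prefix doubling —
O(n log² n), chosen for transparency over speed since desk-scale
references dominate the intended use. Rank checkpoints default to a
stride of 128 and suffix-array samples to every 32nd text position
(standard FM-index practice; both are parameters). A second index over
the per-entry-reversed text is built and persisted alongside; SMEM
discovery as implemented needs only the forward index (matching
statistics walk right-to-left), and the reverse index serves as a
cross-check and as room for a bidirectional extension strategy.

Indexes persist as a single versioned container (NumPy archive with a
magic tag); loading verifies magic and version and reports truncation or
foreign files as corrupt.

## ORF filter

A frame passes when its longest stop-free run, converted to nucleotides,
reaches the threshold; the threshold is absolute (nt) or relative to the
read length. The residue threshold is `floor(T_nt / 3)`. The default is
relative mode at 0.80 of read length: on 250 bp reads this demands a
66-residue stop-free run, long enough to reject most non-coding frames
while tolerating one error-induced stop near a read end. We measure the
*longest run anywhere in the frame* rather than requiring the first `T`
nt to be stop-free; the two readings coincide for clean coding reads and
the longest-run form is the more permissive (and testable) one. The
genetic code defaults to the standard table; table 11 and others are
exposed, though code choice only affects stop/start sets this method
never uses beyond stops.

## Seeding and SMEMs

For each passing frame we compute matching statistics: for every query
position `j`, the smallest `s(j)` such that `q[s(j):j]` occurs in the
reference, found by fresh backward search per endpoint (cost proportional
to the summed match lengths; negligible at read scale). The match ending
at `j` is kept when `s(j+1) > s(j)` — that inequality is exactly
right-maximality, left-maximality is automatic for a longest match ending
at `j`, and strict monotonicity of `s` among kept endpoints rules out
containment. The kept set therefore equals the brute-force SMEM
enumeration, which the test suite verifies on randomized instances.
Occurrences per seed are capped (default 500) with a truncation flag.

## Chaining, extension, scoring

Seed occurrences sharing a reference entry and lying within a diagonal
tolerance (the band width) form a chain, scored by summed seed lengths;
chain order is deterministic (score desc, entry id, start). Each of the
top chains (default 8 per frame) is extended by banded affine-gap local
DP over a reference window spanning the chain's diagonals ± band; gap of
length k costs `open + k·extend` (defaults 6 + k·1) under BLOSUM62 with
`X` and `*` scoring −1 against everything. The band is a performance
device only: with band ≥ query length the score provably equals unbanded
Smith–Waterman, and the suite checks this against an independent full-DP
oracle. Uncovered query ends are soft-clipped; at candidate-ranking time
each clipped end costs a clip penalty (default 5, applied per end), so an
end-to-end alignment is preferred over a marginally higher-scoring
clipped one. The reported raw score is the unpenalised local score, and
the minimum reported score defaults to 15 — the scale point around which
mapped fraction, similarity and quality trade off best in this scoring
regime.

Mapping quality is `round(60·(best−second)/best·c)` clipped to [0, 60],
where `c` is the fraction of the query covered by the winning chain's
seeds, `second` is the best score at a distinct reference locus across
all frames (overlapping candidates are deduplicated), 60 is returned for
unique hits and 0 for exact ties. The 0–60 Phred-style scale is the SAM
convention; the exact shape inside it is this package's choice.

## SAM and report conventions

Coordinates, CIGAR and SEQ are in amino-acid units over the kept frame's
translation; the frame is in `YF`, original nucleotides in `YN`, and for
unmapped reads the cause (`orf_filter`, `no_seed`, `low_score`) in `YU`,
so evaluation can distinguish filter rejections from scoring failures.
Mates are aligned independently; a proper-pair flag is set when both map
to the same entry (no pairing rescue). Abundance counts primary
alignments only, filtered at MAPQ ≥ 20 by default in the report and in
the detected-protein count.

## Evaluation metrics

GO similarity uses `is_a` edges only (the uncontroversial subsumption
relation; `part_of` would mix partonomy into the closure), pools the
three namespaces into one closure per read, and averages per-read Jaccard
coefficients over reads that mapped and carry truth terms; reads with an
undefined coefficient (both closures empty) are excluded and counted.
Cross-tool comparison takes the other tool's best alignment per read
(BLAST-style tabular input), computes consensus among this aligner's
MAPQ ≥ 50 mappings, and summarises the bit-score gap as
`(a − b)·log10(2)` — the base-10 order-of-magnitude equivalent of a mean
bit (base-2) score difference. Raw scores convert to bits via
Karlin–Altschul `(λS − ln K)/ln 2` with gapped-BLOSUM62 defaults
λ = 0.267, K = 0.041. Effective alignment rate subtracts index-load time
before dividing reads by time; it is reported, never asserted, because it
is hardware-bound.

## Synthetic data generator

The generator stands in for a real annotated-genome positive control.
Proteins draw residues i.i.d. from average database composition with
lognormal lengths (median 300, σ_log 0.25, floored at 230 so a full
600 nt fragment fits); each gets 1–5 leaf terms of a three-namespace toy
ontology. Reverse translation picks uniform synonymous codons, appends a
stop, places CDS on either strand with intergenic spacers, and emits
FASTA + GFF3 that round-trip exactly through the genome loader. Reads are
250 bp pairs from ~600 ± 60 nt fragments sampled uniformly over CDS;
substitution errors follow a linear 5'→3' ramp (read-average 1% by
default, end rate 5× the start rate) with uniform rare indels (1e-4) and
qualities consistent with the per-base rate. The ramp preserves the one
property of real Illumina error that matters here — errors concentrated
late in reads, where they truncate stop-free runs and seed matches — but
it is not an empirical quality model: no quality-profile files, no
GC bias, no duplicates, no chimeras. The divergence operator substitutes
residues with probability d using BLOSUM62-biased replacement
(P(b|a) ∝ 2^(score/2), never the identity), preserving GO terms and
suffixing ids with `_hom`; truth comparison normalises that suffix.

Passing the synthetic benchmark therefore shows algorithmic correctness
(seeding, extension, frame logic, metrics) and robustness to point error
and moderate homolog divergence. It does not demonstrate performance on
real metagenomes: real references have repeat families, shared domains
and skewed composition that compress MAPQ and inflate ambiguity relative
to i.i.d. proteins.

## Problem sizes and numerics

The shipped acceptance run uses 50 proteins and 10,000 read pairs with
seed-pinned RNG; all generators are deterministic per seed, and the
aligner itself contains no randomness (every tie-break is explicit:
penalised score, then frame order +1,+2,+3,−1,−2,−3, then entry id, then
start). Degenerate inputs behave conservatively: empty frames never pass
the ORF filter, queries containing `*` split seeds at the stop, an empty
reference refuses to index, and both-empty GO closures are excluded
rather than scored. Inner loops (rank queries, matching statistics,
banded DP) are JIT-compiled; everything else is plain NumPy/Python.
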