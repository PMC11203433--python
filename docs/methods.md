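# Methods

## Problem setting

TP53 is the most frequently mutated gene across human cancers, and in
colorectal carcinoma its somatic mutations concentrate unevenly across the
coding exons. Given per-exon nucleotide sequences for a cohort of tumor
samples and a reference coding sequence, the package locates every
difference, names it in cDNA (c.) coordinates, and asks where in the gene
mutation events cluster. A parallel "healthy" cohort carrying only
synonymous variants serves as the contrast: variants there fall in similar
regions without implying pathology.

## Gene model and coordinates

All positions are 1-based cDNA coordinates with c.1 the first base of the
coding sequence. The default model is a TP53-like layout of ten coding
exons tiling a 1182-nt CDS:

| exon | 2 | 3 | 4 | 5 | 6 | 7 | 8 | 9 | 10 | 11 |
|------|---|---|---|---|---|---|---|---|----|----|
| span | 1–74 | 75–96 | 97–375 | 376–560 | 561–672 | 673–782 | 783–919 | 920–993 | 994–1100 | 1101–1182 |

Exon 1 of TP53 is non-coding and is omitted rather than modeled as UTR;
introns are not modeled, so intronic and splice-site variants are out of
scope. Spans must be contiguous and tile the reference exactly; the loader
validates this and reports the offending exon otherwise. The layout is
consistent with public annotation of the TP53 reference transcript
(NM_000546-style CDS), but the bundled reference sequence itself is
synthetic (below) — no accession download is required or performed.

## Alignment and identity score

Each sample exon is aligned to the reference exon with global
(end-to-end) alignment under affine gap penalties, computed by Biopython's
`PairwiseAligner`. The scheme is match +1, mismatch −1, gap open −2, gap
extend −0.5; a gap of length L costs `open + (L−1)·extend`, end gaps
included. These defaults make a substitution (−1 in one column) always
preferable to a spurious insertion/deletion pair (−4), which keeps point
mutations ungapped; they are configurable everywhere and echoed into every
output header. The identity score is the number of columns with identical
unambiguous residues divided by the total number of alignment columns.
Counting gap columns in the denominator is a deliberate reading of
"residues compared": it makes the score penalize indels, and 1.0 is reached
exactly when the rows are identical and gap-free. The score is reported for
fidelity with the interactive workflow it replaces but drives no downstream
logic. An 'N' in a sample is accepted, scores as a mismatch, never counts
as identical, and is excluded from variant calling with a logged warning.

## Variant calling and 3′ normalization

Alignment columns are classified once, left to right: a mismatch column is
a substitution; maximal runs of sample-gap columns become one deletion;
maximal runs of reference-gap columns become one insertion anchored between
its two flanking reference bases. Adjacent substitution columns stay
separate single-nucleotide events (no delins type — the catalogue this
package targets contains only SNVs and simple indels).

Indels in repeat context are ambiguous; the package adopts the HGVS rule of
placing them at the 3′-most equivalent position within the exon. A deletion
`[s..e]` slides right while the base at `e+1` equals the base at `s`; an
insertion slides right while the next reference base equals the first
inserted base, rotating the inserted string. Two guards apply:

- The slide never crosses the next called event in the same exon, because
  the shift equivalence assumes the sample matches the reference in the
  shifted-through region — a property-based test caught exactly this
  interaction (a deletion normalized onto a substituted position).
- The slide never leaves the exon, since input is per-exon; a deletion
  spanning an exon boundary cannot be represented and is rejected, as is an
  insertion that cannot be anchored at or after the exon's first base.

Normalization is idempotent, and re-applying all called variants to the
reference reconstructs the sample sequence exactly (tested for random
sequence pairs and for ≥1000 seeded spike-ins).

Names are formatted in two dialects: the default catalogue dialect
(`c.404G>T`, `c.80delC`, `c.450_478del29` with a length suffix,
`c.622_623insGATA`) and strict HGVS (`c.80del`, `c.450_478del`). The parser
accepts both; deletion names that omit the deleted bases require the gene
model to recover them.

## Cohort aggregation and hotspots

`compare_cohort` runs align → call → normalize for every sample × exon and
accumulates: event count per exon (zero rows kept — an exon with no events
is a finding, not missing data), event count per cDNA start position, the
flat event list, and the altered/unaltered sample split (a sample is
altered if any exon yields ≥1 event). Counting is per event, so a sample
with variants in two exons contributes to both exons but is one altered
sample. A missing or empty exon sequence is logged and excluded rather
than fatal. Conservation (Σ exon counts = Σ position counts = total
events) is asserted at construction.

Recurrence reports positions hit in ≥ `min_count` (default 2) independent
events, sorted by count then position. Hotspots are detected by sliding a
width-*w* window (default 50 nt) in 1-nt steps across the cDNA; windows
holding ≥ *k* events (default 4) qualify, overlapping qualifying windows
merge, and each merged run is reported as the span of the mutated positions
it contains, its event count, its recurrent positions, and the exon of its
peak position (ties to the leftmost). The 50/4 defaults are a design
choice tuned to flag a dozen events clustered within ~100 nt while leaving
four events spread over 80 nt unflagged; both knobs are CLI-configurable,
and no statistical significance is attached to a window.

Healthy-cohort summaries are computed separately from tumor summaries and
never pooled.

## Synthetic cohorts

The generator exists so the whole pipeline is testable end to end with a
known ground truth. `build_fixture_cohort(seed)` produces the canonical
fixture: 50 tumor samples carrying 48 events (42 samples altered, six of
them with events in two different exons, assigned deterministically by
sample index; 8 samples untouched) and 50 healthy samples of which 30
carry one synonymous-style substitution each, three per exon.

The tumor catalogue plants the named hotspot variants at their catalogued
positions and multiplicities (e.g., c.404G>T twice in exon 5; c.818G>A and
c.818G>C twice each and c.844C>T twice in exon 8; the 29-nt deletion
c.450_478del29; the insertion c.622_623insGATA), then adds filler
substitutions at fixed positions inside each exon's narrative range to
reach the per-exon totals {e2:1, e3:2, e4:6, e5:12, e6:6, e7:4, e8:12,
e9:0, e10:4, e11:1}. Filler positions (see
`synthetic_data.FILLER_POSITIONS`) are fixture decisions: distinct from
the named positions and from each other, so they add no unintended
recurrence. Variants catalogued as bare positions (69, 96, 108, 639, 994,
1169) lack published alleles and are planted as transitions of the
reference base.

The reference is seeded-random ACGT except at *constrained sites*, which
are pinned so the catalogue is self-consistent: printed reference alleles
(G at 404 and 818, C at 844, T at 487, …), a CCC homopolymer at 453–455
with a non-C at 456 so that a single-C loss there 3′-normalizes to
c.455delC, and non-matching flanks at 81, 255, 479 and 623 so that
c.80delC, c.254delC, c.450_478del29 and c.622_623insGATA are already
3′-normal. Consequently the catalogue layout — sample assignment,
positions, kinds, constrained alleles — is identical for every seed; the
seed varies only the unconstrained reference composition (and with it the
alleles of events whose reference base is free). The healthy cohort keeps
the four catalogued synonymous variants (c.447C>G, c.465C>G, c.483C>G,
c.822T>A) and fills the remaining exons with invented synonymous-style
substitutions at fixed mid-exon positions; synonymy itself is not computed
(no protein-level reasoning anywhere in the package).

What the fixture does **not** emulate: sequencing error, read-level data,
coverage dropouts, heterozygous mixtures, intronic context, or the real
NM_000546 sequence. Passing the fixture round trip therefore demonstrates
the correctness of alignment, calling, normalization and aggregation on
clean per-exon sequences — not robustness to noisy real-world chromatograms.

`random_cohort` plants at most one variant per sample per exon (uniform
interior positions, two bases clear of each boundary; configurable indel
fraction, deletions 1–3 nt, insertions 1–4 nt) and returns the
3′-normalized plant list for round-trip checks. Dense planting (per-exon
rate > 0.5) triggers a warning because interacting events in repeat context
can make normalization ambiguous.

## Numerical and testing choices

Ties among co-optimal alignments are resolved deterministically by the
aligner's iteration order; which co-optimal alignment is chosen is
immaterial because indel calls are re-normalized. The unit suite checks the
aligner against two independent hand-written oracles: a literal enumeration
of every alignment (feasible to length ~4) and a three-state affine (Gotoh)
recursion validated against that enumeration and then swept over all
sequence pairs of length ≤ 8 on a two-letter alphabet (~260k pairs, about a
minute). Cohort-scale tests run the 50-sample fixture (500 alignments,
seconds) and a ~1000-event spike-in recovery (~103 samples × 10 exons);
problem sizes were chosen so the whole suite completes in about a minute on
one CPU. All randomness is seeded; identical inputs produce byte-identical
output files (no timestamps in outputs).

## Known limitations

- Per-exon input only: variants spanning exon boundaries, intronic and
  splice-site changes are unrepresentable and rejected.
- No protein (p.) consequences, rsID annotation, pathogenicity calls, or
  external-database frequency lookups.
- Hotspot detection is descriptive (window counting), not a significance
  test; window parameters change what is flagged.
- A sample sequence with unmatched extra bases before an exon's first base
  cannot be anchored and is rejected rather than guessed at.
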