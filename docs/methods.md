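# Methods

## Problem and approach

Structural-variant (SV) benchmarking by callset intersection is brittle in
repetitive DNA: the same variant can be represented at several equally valid
breakpoints, or fragmented into multiple records, so call-to-call matching
under- or over-counts. `asmsv` instead asks a content question: *if this call
were true, would editing the reference accordingly make it look like the
assembly?* Given a haplotype-resolved assembly aligned to the reference, each
candidate call is applied as an edit to its local reference window and the
edited window is compared against the orthologous assembly sequence. No
candidate is ever compared against another callset.

## Orthology map and lift-over

Contig-to-reference alignments (SAM/BAM, produced externally) are reduced to
a unique mapping: when two contigs of one haplotype overlap on the reference,
the alignment of the shorter *contig* is trimmed to exclude the overlap
(fully contained alignments are removed); pairs are processed in descending
contig length, so the longest contig is never modified. The trimmed-away
reference intervals are retained, because truth variants there may exist in
duplicate representations and are excluded from recall accounting.

From the overlap-free alignments an orthology map is sampled at fixed
reference spacing (20 bp default): each grid position stores the contig
coordinate obtained by walking the CIGAR; positions inside
deletions-from-reference map to the deletion's left edge so the map is total
over covered blocks. `lookup(chrom, pos)` returns the record at the last
grid point at or before `pos` within the same aligned block, hence a bounded
error of at most one spacing. Insertions-to-reference of ≥20 bp encountered
during the walk are annotated per block; these intervals later serve as the
"inserted relative to the reference" annotation for duplication validation.
Maps serialize to a TSV (`chrom ref_pos contig contig_pos strand hap`); a
map rebuilt from TSV loses the exact insertion annotations and falls back to
inferring them from grid-coordinate jumps.

## Assembly QC and the high-confidence filter

A 100-bp assembly window counts as supported when at least five reads align
starting ≥1 kb before it and ending ≥1 kb after it. Maximal runs of
unsupported windows are flagged as possible misassemblies only when every
window whose start lies 1–3 kb outside the run, on both sides, is supported.
The flank test is evaluated against the failing *run*, not per window:
spanning coverage necessarily collapses in the ~read-length neighbourhood of
a genuine misjoin, so a per-window flank test could never fire; conversely a
broad mapping-artifact region fails the flank test and stays unflagged.
Flags are lifted to reference coordinates through the map grid with one
spacing of padding.

The high-confidence filter is the set of reference positions where
validation is trusted: autosomes (plus X under the female sample rule) minus
centromeres (BED, required input), minus positions not covered by *both*
haplotype maps, minus lifted misassembly flags; chrY is always excluded. A
call overlapping any excluded base is NA — conservative, since partial
overlap already means the evidence window is partly untrusted. The reported
NA reason is the one covering the most excluded bases, with ties broken by
the fixed precedence coverage > centromere > misassembly. Read-based QC is a
refinement, not a gate, and can be skipped (`--skip-qc`).

## Evidence statistics

For a call on `[s, e)` the default window is `[s−w, e+w)` with `w = 500`,
lifted through the map to a contig interval. Two statistics compare contig
content with the edited reference:

    relative length  rl = (contig interval length − reference interval length) / svlen
    relative score   rs = (score_after − score_before) / |score_before|

`svlen` is signed (negative for deletions) so a true call of any type has
rl ≈ +1. Scores are global affine-gap alignments of the contig interval
against the window before/after the edit; the scheme is fixed at match +1,
mismatch −1, gap open −2, gap extend −0.5 (a gap of length L costs
2 + 0.5·(L−1)), making results bit-reproducible. Because rs is a ratio, the
classification is insensitive to the particular affine scheme. A zero
baseline score yields ±∞ with the sign of `score_after`.

Edits: DEL removes `[s, e)`; sequence-resolved INS inserts its ALT at `s`;
INV reverse-complements in place; tandem DUP inserts a copy of `[s, e)`
immediately after `e` (tail-to-head), so a true tandem duplication lifts to
a contig interval containing both copies and rl ≈ 1 with svlen = e−s.

## Breakpoint search

In tandem repeats the alignment behind the map and the alignment behind the
call may place the same event at different phases, so the gap can fall
partly outside the default window and rl collapses toward 0. Candidate
left/right boundaries are enumerated on the map grid within
`search_radius = 10` steps (±200 bp at 20-bp spacing) of the default
flanks, ranked by |rl − 1| then by distance from the defaults. Alignment
scores are computed lazily in that order and the search stops at the first
combination that classifies TP; otherwise up to `top_k = 5` combinations
(at most two per distinct rl, since length-tied windows differ only by a
few grid steps) are scored and the winner maximizes the lexicographic
objective (|rl − 1| minimized, then rs maximized, with rs compared at 0.01
resolution so that the ratio's mild preference for smaller windows does not
override boundary parsimony).

Windows longer than `align_cap = 6000` bases are not aligned; such calls
are validated by relative length alone. This keeps the quadratic aligner
within a single-CPU budget; the cap is a parameter, and rl is the axis that
remains informative for large events.

## Classification

For DEL, sequence-resolved INS, and tandem DUP, the TP region in the
(rl, rs) plane is a cone around rl = 1 that widens with rs up to a cap,
then a fixed band:

    1 − (α·rs + β) ≤ rl ≤ 1 + (α·rs + β)   for 0 ≤ rs ≤ γ
    1 − δ ≤ rl ≤ 1 + δ                      for rs > γ

with defaults α = 2, β = 0.2, γ = 0.6, δ = 0.1 (empirical; exposed as
configuration). Insertions without an ALT sequence (common from short-read
callers) use the 1 ± δ band on rl alone; inversions change no length and
use the score sign alone (rs > 0).

A duplication failing the tandem test is re-tried as interspersed: the
source sequence `ref[s:e)` is aligned (semi-global, both orientations,
banded at 20% edit distance) into assembly intervals annotated as
insertions; TP when ≥90% of the duplicated length falls inside such an
insertion on either haplotype. No constraint is placed on the target site.
If no insertion hosts it but the sequence aligns at its source locus, the
call is FP; a sequence under 50 bp or alignable nowhere is NA.

A call is TP when it validates on either haplotype. The inferred genotype
is 1/1 when both haplotypes validate, 0/1 when exactly one does;
concordance is reported against the called genotype when present.

## Recall

Optionally, an assembly-derived truth callset (≥50 bp, autosomes + X,
outside trimmed-out regions) is matched against validated TP candidates: a
truth variant is matched when some TP call lies within 1 kb (gap between
closest interval endpoints; 0 when overlapping). Matching is deliberately
not one-to-one and type-blind by default, because fragmented and
alternately-represented calls are the norm; a strict-type mode exists.

## Synthetic data

The generator builds everything the validator consumes from one seed:
i.i.d. uniform ACGT reference (real repeat structure must be planted
explicitly — `repeat_spec` writes perfect tandem arrays), haplotypes
produced by applying truth SVs as edits, and contig alignments whose CIGARs
come from the edit script, so the map ground truth is exact by
construction. Candidate callsets replay the truth with optional breakpoint
jitter, insertion fragmentation, and random false calls placed in SV-free
regions, each labeled in an audit sidecar. Reads are tiled along contigs
(default length 5000 at coverage 15, giving an expected spanning support of
≈8.7 per window, comfortably above the ≥5 threshold) and reads crossing a
planted misjoin are dropped. The duplication protocol copies reference
segments, lengths uniform over a range, into random distant loci of
haplotype 1.

Study conditions shipped as defaults: the end-to-end benchmark uses a 2-Mb
diploid with 100 implanted SVs (even DEL/INS/INV/DUP mix, lengths
log-uniform 50–1000, half heterozygous), 100 random false calls, and
10+10 calls inside a planted centromere and a hap2-uncovered region. The
repeat fixture plants 20 perfect 30×60 VNTR arrays with 300-bp deletions
whose candidate representation is displaced 620 bp, so the gap leaves the
default window but stays within search range. The scaled duplication
simulation uses 100 true + 100 false events with lengths uniform on
[100, 20 000] over a 5-Mb genome — 200 disjoint sources at the full
protocol's 100-kb maximum cannot fit 5 Mb, so the analog scales length,
not count.

What synthetic fixtures do *not* emulate: sequencing error, alignment
ambiguity from diverged repeats (fixture CIGARs are exact), segmental
duplications with <100% identity, multi-chromosome genomes, and caller
noise beyond jitter/fragmentation. Passing these conditions shows the
machinery is correct and calibrated on unambiguous content; it does not
bound performance on real assemblies, where map errors and diverged repeats
add failure modes.

## Numerical and degenerate-input choices

0-based half-open coordinates internally; VCF anchor-base convention at I/O
(END beats inconsistent SVLEN, logged). Mapping-quality-0 alignments are
retained; secondary alignments dropped; supplementary alignments treated as
independent blocks. Empty alignment set gives an empty map (warning).
Contigs shorter than 6 kb can never be misassembly-flagged. Batch
validation never aborts on a bad record: parse failures are skipped with
reasons, per-call errors produce NA("error").

## Known limitations

- Translocations/breakends and chrY calls are out of scope by design.
- Nested or overlapping SVs are validated independently; no complex-event
  grammar.
- Above `align_cap` the score axis is unavailable, so a length-preserving
  miscall (e.g. a large false inversion) inside a huge window would be
  undecidable; in practice INV windows are capped separately by being
  score-only and large INVs beyond the cap return NA-like FP evidence.
- The genotype inference assumes the two haplotype assemblies are truly
  haplotype-resolved; switch errors would scramble 0/1 inference.
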