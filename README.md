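# asmsv

Content-based validation of structural variant (SV) calls against
haplotype-resolved genome assemblies.

## The problem

SV callsets are usually benchmarked by intersecting them with another
callset. In repetitive DNA — where most SVs live — the same variant can be
reported at several equally valid breakpoints or split into fragments, so
call-to-call matching misjudges correct calls. When a haplotype-resolved
assembly of the same sample exists, a stronger question can be asked of each
candidate call directly: *if this call were true, would editing the
reference accordingly make the local sequence match the assembly?*

`asmsv` answers that question per call. It is written for people who build
or evaluate SV callers and have a diploid assembly (e.g. hifiasm/trio
assemblies) aligned to the reference.

## Method in brief

1. **Orthology map.** Contig-to-reference alignments are made unique
   (overlaps trimmed from the shorter contig) and sampled every 20 bp into a
   reference→contig coordinate map, `Lookup(c, p)`.
2. **High-confidence filter.** Calls in centromeres, regions not covered by
   both haplotypes, or assembly intervals that raw reads fail to span
   (&lt;5 reads with 1-kb margins, with supported 1–3-kb flanks) are **NA**.
3. **Evidence.** For a call on [s, e) the window [s−w, e+w), w = 500, is
   lifted to the assembly and two statistics are computed against the
   SV-edited reference:

       rl = (contig interval length − reference interval length) / svlen
       rs = (score_after − score_before) / |score_before|

   with a fixed affine-gap global aligner (match +1, mismatch −1, gap open
   −2, extend −0.5). svlen is signed (negative for deletions) so a true
   call of any type has rl ≈ +1. Window boundaries are searched on the map
   grid (±10 steps) to absorb breakpoint displacement inside tandem repeats.
4. **Classification.** DEL, sequence-resolved INS, and tandem DUP are TP
   inside the region
   {1−(α·rs+β) ≤ rl ≤ 1+(α·rs+β), 0 ≤ rs ≤ γ} ∪ {|rl−1| ≤ δ, rs > γ}
   (α=2, β=0.2, γ=0.6, δ=0.1 by default). Length-only insertions use the
   1±δ band; inversions use rs > 0; duplications failing the tandem test
   are re-tried as interspersed (≥90% of the source sequence must align
   inside assembly sequence annotated as inserted relative to the
   reference). A call validating on either haplotype is TP; 1/1 vs 0/1 is
   inferred from which haplotypes validate.
5. **Recall (optional).** Truth variants (≥50 bp) unmatched by any TP call
   within 1 kb are reported as FN.

See `docs/methods.md` for assumptions, parameters, and limitations.

## Worked example

Everything the pipeline consumes can be simulated from a seed — a 500-kb
diploid genome with 12 implanted SVs, 8 false calls, 20 calls in planted
exclusion zones, exact contig alignments, and reads:

```sh
asmsv simulate --seed 7 --out-dir demo --genome-len 500000 --n-svs 12 --fp-count 8
asmsv run \
    --reference demo/ref.fa --asm-hap1 demo/hap1.fa --asm-hap2 demo/hap2.fa \
    --aln-hap1 demo/hap1.sam --aln-hap2 demo/hap2.sam \
    --calls demo/candidates.vcf --centromeres demo/centromeres.bed \
    --reads-bam demo/reads.sam --truth demo/truth.vcf --out-dir demo/out
```

prints

```json
{
 "n_calls": 40,
 "skipped_records": 0,
 "TP": 12,
 "FP": 8,
 "NA": 20,
 "na_reasons": {
  "centromere": 10,
  "not-covered-by-hap2": 10
 },
 "gt_match_rate": 1.0,
 "recall": 1.0,
 "truth_total": 12,
 "fn": 0
}
```

All 12 implanted SVs validate (TP) with concordant genotypes, all 8 random
calls are rejected (FP), and the 20 calls placed in the planted centromere
and the hap2-uncovered region are NA with the matching reason. Per-call
evidence lands in `demo/out/validation.tsv`:

```
call_id      chrom  start  end    type  classification  na_reason  rel_len  rel_score  hap  gt_match
call_00000   chr1   9713   9714   INS   TP              .          1.0000   1.7458     1    1
call_00013   chr1   12074  12590  DUP   FP              .          0.0000   -0.1730    1    .
call_00001   chr1   19893  20478  DUP   TP              .          1.0000   0.6835     2    1
```

A true insertion changes the lifted interval by exactly its length
(rel_len 1.0) and the edited reference aligns far better than the original
(rel_score 1.75); the false duplication changes nothing (rel_len 0.0) and
the edit only hurts (rel_score −0.17).

The library surface mirrors the stages (`asmsv.liftover`, `asmsv.qc`,
`asmsv.svmodel`, `asmsv.validate`, `asmsv.recall`, `asmsv.simulate`) and the
subcommands `liftover`, `qc`, `validate`, `recall`, `simulate` run them
separately, exchanging a lift-over TSV / BED / VCF between stages.

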