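# Methods

## The problem this package models

In exome sequencing (ES), structural-variant breakpoints are detectable by
paired-end and soft-clip signals only when they fall inside (or very near)
captured target regions.  Across a large cohort of unsolved rare-disease
patients, the raw per-sample SV callsets are therefore small in sensitivity
but large in noise: common structural polymorphisms, capture- and
alignment-driven artifact hotspots that recur at near-identical positions
across many samples, and inversions reported only as breakend (BND) mate
pairs.  The package implements the cohort-level machinery that turns such
callsets into short, reviewable candidate lists: breakpoint
allele-frequency estimation across the whole cohort, a fixed filter
cascade, inheritance-based tiering, breakend algebra, reconciliation with
read-depth (RD) copy-number calls, and clinician-style reporting.

## Cohort breakpoint allele frequency

The unit of counting is the *dataset* (one sequenced exome), not the raw
breakpoint record.  Every breakend of every call — PASS and non-PASS,
affected and unaffected individuals alike — is inserted into a
per-chromosome sorted index, with per-dataset deduplication of identical
(chromosome, position) entries.  The count of a focal breakpoint is the
number of distinct datasets with at least one breakpoint within ±W bp,
window closed at both ends, W = 20 by default.  W is matched to the
breakpoint confidence intervals a PE/SC caller reports (median width
≈ 17 bp, ≈ 60% narrower than 40 bp): a much larger window would merge
unrelated breakpoints and overestimate frequency, a much smaller one would
split jittered observations of the same allele and underestimate it.

An SV has two breakends; its cohort count is the **maximum** of the two
per-breakend counts.  This is a deliberate design choice (the alternatives
`min` and `mean` are exposed as configuration): an SV that shares *either*
breakpoint with many datasets is, for prioritization purposes, a
polymorphism or a recurrent artifact.  Counting is SV-type-agnostic,
because artifact hotspots present with mixed types at the same position.
Non-PASS calls contribute to the index (frequency is estimated across the
complete dataset, and artifact evidence is evidence regardless of the
caller's own filter) while the PASS requirement applies only to the focal
candidate set; this too is configurable.

The rarity filter keeps calls with count ≤ 20.  Out of 9351 datasets this
is an allele frequency of ≈ 0.21% — high enough to tolerate a large family
segregating one variant, low enough to exclude common polymorphisms.

## The filter cascade

Stages run in a fixed order; each stage's output is a subset of its input
(except breakend pairing, which merges records):

1. **PASS filter** — caller-PASS records only (configurable off).
2. **Rarity filter** — cohort count ≤ `max_cohort_count` (20).
3. **Breakend pairing** — BND records are resolved into mate pairs (by
   MATEID, else by reciprocal positions within tolerance) and inversion
   quartets are merged into INV calls (below).  Running this before gene
   annotation lets reconstructed inversions be annotated by their span.
4. **Panel overlap** — a spanned SV (DEL/DUP/INV) hits a gene when its
   closed span intersects an exon padded by 5 bp on each side; a BND/INS
   hits when its breakend position, expanded by its confidence interval
   plus the pad, does.  CI expansion is deliberately *not* applied to the
   span edges of DEL/DUP/INV: it would make the 5 bp rule
   uninterpretable.  Calls hitting at least one gene on the submitting
   group's panel survive.
5. **Chromosome QC** — a sample whose surviving candidates span more than
   5 distinct chromosomes is dropped entirely; many independent rare SVs
   in one genome indicate DNA or sequencing quality failure, not biology.
   This stage is sample-level and must run after panel filtering (it does
   not commute with record-level filters; PASS and rarity commute with
   each other).
6. **Tiering** — dominant/X-linked: any hit gene with an AD, XLD or XLR
   inheritance mode and cohort count strictly below 4 (i.e. 1–3 datasets:
   one family, or very few independent patients).  Zygosity is not used
   for this tier.  Compound heterozygotes: a heterozygous SV candidate
   pairing with a heterozygous HIGH-impact or known-pathogenic-missense
   short variant in the same autosomal-recessive gene and sample;
   co-occurrence, not phase, defines the pairing.

Candidate tables are produced for affected samples of the four panel
groups; unaffected relatives contribute to the frequency index and to
segregation logic only.

## Breakend algebra and inversion reconstruction

The four bracketed breakend ALT forms are parsed into two bits: which side
of the junction the local sequence anchors (`t[p[`/`t]p]` anchor left,
`]p]t`/`[p[t` anchor right) and whether the joined mate segment is
reverse-complemented (`t]p]` and `[p[t`).  In two-strand junction
notation: `t[p[` = +−, `]p]t` = −+, `t]p]` = ++, `[p[t` = −−.

An inversion of the segment [B, E] is encoded as four BND records forming
two junctions: head-to-head at (B−1, E), both records `t]p]` (++), and
tail-to-tail at (B, E+1), both `[p[t` (−−).  Reconstruction inverts this:
a ++ mate pair at positions (p₁ < p₂) implies the span (p₁+1, p₂), a −−
pair implies (q₁, q₂−1); when a ++ and a −− pair agree within
`bnd_pair_tolerance_bp` (default 50 bp, informed by CI widths) at both
ends, they are merged into one INV call spanning the union of the two
implied spans.  On exact quartets this is the identity on spans
(property-tested); partial quartets and unmatched records remain BNDs and
are annotated by breakend position instead.

## Reconciliation with read-depth CNV segments

Against same-sample RD segments, every SV receives exactly one category:

* **simple CNV** — a DEL/DUP matching a same-state segment at ≥ 0.5
  reciprocal overlap (`rd_support = True`), or a DEL/DUP with *no* RD
  signal anywhere near (`rd_support = False`): small events, typically
  single-exon or sub-exon, are genuinely invisible to RD callers, so
  absence of RD support must not demote an otherwise clean CNV call;
* **complex SV** — an RD segment of any state overlaps the span or lies
  within `adjacency_window_bp` (default 1000 bp; "next to" is not given a
  number by convention, so it is exposed in configuration) of a breakend
  without matching the call — the PE/SC call and the RD segment together
  indicate a composite rearrangement;
* **copy-number neutral** — an INV or BND with no RD segment overlapping
  or adjacent;
* **unclassified** — an insertion with no nearby RD signal.

The 0.5 reciprocal-overlap equivalence is the standard community
convention for "same event".  The package reports adjacency evidence; it
does not attempt to assemble a full complex allele from partial
breakpoints, which exome data rarely supports.

The **clear-cut** flag is the conjunction of four criteria: multi-signal
support (supplied as an RD/evidence flag), phenotype match (supplied
externally — automated HPO matching is out of scope), segregation
(every affected relative carries the variant; for the dominant/XL tier no
unaffected relative does; a missing genotype fails the criterion), and
clean visual inspection (external flag).  Recessive candidates tolerate
carrier parents.  Incomplete penetrance is out of scope.

## IGV batch scripts

One script per candidate, in the `new / genome / load / snapshotDirectory
/ goto / snapshot` dialect: left breakpoint ± flank (500 bp default),
right breakpoint ± flank, and the full span padded on each side by 10% of
the SV length or the flank, whichever is larger.  Coordinates clamp at 1.
For a BND with an unresolvable mate only the breakend view is emitted,
with a comment noting the omission.

## Summary arithmetic

Per-group summary rows carry integer counts (affected individuals, index
families, panel genes, candidates, samples with candidates, solved index
families, solved affected individuals) and two percentages recomputed from
those same integers: solved-index fraction rounded to two significant
figures, and causal-among-investigated fraction truncated (not rounded) to
two decimals — truncation is the convention that reproduces such summary
tables exactly from their printed integers (e.g. 11/798 → 1.37%, not
1.38%).

## The synthetic cohort generator

The generator defines the study conditions the pipeline is tested under;
its defaults are fixed, not tuning knobs.

* **Genome**: three synthetic contigs ("1", "2", "X"; ~10 Mb total) with
  50 genes of 6–12 exons (80–300 bp) separated by 1.0–2.6 kb introns.  No
  real reference sequence is shipped or needed — the pipeline is purely
  coordinate-based.  Panels and inheritance modes cycle deterministically
  across genes so that every submitting group has dominant and recessive
  panel genes.
* **Cohort**: 200 families by default; 30% trios (proband + two unaffected
  parents), the rest affected singletons — roughly the unaffected-relative
  fraction of a large reanalysis consortium.  Group membership is drawn
  with weights RND 0.376, ITHACA 0.304, NMD 0.262, GENTURIS 0.058.
* **Confidence intervals**: widths are drawn from a discretized log-normal
  with exactly two free parameters pinned by the two published summaries —
  median 17 bp and P(width < 40) = 0.60 (μ = ln 17, σ = ln(40/17)/z₀.₆₀
  ≈ 3.38) — then clipped at 1000 bp, which moves neither summary.
* **Polymorphic loci** (30): a fixed position and type per locus, 21–100
  carriers drawn from the whole cohort, per-carrier breakpoint jitter
  bounded by min(CI half-width, 10 bp) so that all observations of a locus
  fall within one ±20 bp window and the rarity filter separates classes
  exactly (every polymorphism ≥ 21 carriers, every causal event ≤ 3).
* **Artifact hotspots** (15): 30–120 samples each emit a call of random
  type (DEL/DUP/INS) within ±5 bp of the hotspot, 30% non-PASS —
  "systematic errors" whose signature is positional recurrence with
  incoherent typing.
* **Background noise**: per sample, Poisson(3) random private SVs
  (including unmatched BNDs), 10% non-PASS.  Background calls are
  suppressed inside a causal carrier's planted-gene region so that truth
  evaluation is not confounded by coincidental private calls.
* **Planted causal events** (affected probands only, one family per
  event, each on a panel gene of the proband's own group): single-exon
  deletions of 66, 800 and 3077 bp spanning the small and large end of the
  single-exon size range; a 9563 bp multi-exon deletion in a recessive
  gene paired with a heterozygous pathogenic missense variant on the other
  allele; a 40 kb duplication with an adjacent RD deletion segment
  (complex); inversions of 1.5 Mb (a contig-scale stand-in for the
  multi-megabase case) and 180 kb, emitted as canonical BND quartets; and
  a simple 25 kb duplication.  RD segments are emitted for planted CNVs at
  or above 5 kb (with ±300 bp boundary jitter) and deliberately omitted
  below that size and for inversions, giving the categorization logic
  positive and negative cases.
* **Determinism**: one `numpy` generator seeded from the config drives
  every draw in a fixed order; identical configs produce byte-identical
  bundles on disk.

What the generator does **not** emulate: capture bias and coverage noise
(no read-level simulation), mobile-element insertions, mosaicism,
incomplete penetrance, population structure beyond family grouping, and
breakpoint *sensitivity* (every planted event is "detected" by
construction).  Passing recovery tests therefore demonstrates the
correctness of the filtering, algebra and bookkeeping — not the upstream
caller's recall on real exomes, which targeted capture fundamentally
limits.

## Numerical and bookkeeping choices

* Internal coordinates are 1-based closed everywhere (VCF convention);
  BED-style half-open coordinates are converted at read/write boundaries
  only.  Chromosome names are compared as exact strings; an optional
  normalization table folds `chrN` onto `N`.
* Missing CIPOS/CIEND means an exact breakpoint, (0, 0).
* Non-PASS filter labels are preserved verbatim so the cascade log can say
  what was removed.
* `END` is written explicitly for spanned types and `SVLEN` only for
  insertions: recent htslib derives the record span from `SVLEN` for
  symbolic alleles, which would silently fight an explicit `END`.
* Reconstructed inversions take the PASS status only if all four
  constituent BNDs are PASS, and their cohort count is recomputed from the
  index rather than inherited.
* Candidate tables, reports and the cohort index are sorted
  deterministically (group, sample, chromosome, position, call id).

## Problem sizes

The default test-suite conditions are the generator defaults: 200 families
(~320 datasets, ~3800 calls), which the full cascade processes in well
under a minute on one core.  The oracle-equivalence suite checks the
breakpoint index against an all-pairs brute-force scan on 200 random
cohorts of up to 50 datasets; the inversion round-trip property runs over
100 random spans plus two real-data-scale spans (~9.8 Mb and ~180 kb); the
confidence-interval calibration uses 10,000 sampled widths.
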