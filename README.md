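# exomesv

Cohort-scale structural-variant (SV) prioritization for rare-disease exome
reanalysis.

Exome sequencing pipelines routinely detect single-nucleotide variants and
short indels, and often read-depth (RD) copy-number variants, but SVs whose
breakpoints happen to fall inside captured exonic regions can also be seen
through paired-end (PE) and soft-clipped (SC) read signals.  Mining those
calls across a large heterogeneous cohort of unsolved patients is mostly a
filtering problem: the raw callsets are dominated by polymorphisms and
recurrent artifacts, and inversions are reported as cryptic breakend (BND)
pairs rather than as interpretable events.  `exomesv` implements that
reanalysis workflow as a reusable, tested library for bioinformaticians
supporting clinical-research consortia:

* **Cohort breakpoint allele frequency.** Every breakend of every call in
  every dataset is indexed per chromosome.  The frequency of a breakpoint
  is the number of *distinct datasets* with a breakpoint within ±*W* bp
  (default *W* = 20, matching typical caller confidence-interval widths:
  median ≈ 17 bp, ~60% < 40 bp).  An SV is kept when its count *c* satisfies
  *c* ≤ 20; on a cohort of 9351 datasets this corresponds to an allele
  frequency of 100·20/9351 ≈ 0.21%.
* **Filter cascade.** Caller PASS filter → cohort rarity filter →
  breakend-pair → inversion reconstruction → disease-gene-panel overlap
  (an SV affects a gene if its span, or breakend ± CI for BND/INS, comes
  within 5 bp of an exon) → per-sample QC (samples with candidates on more
  than 5 chromosomes are dropped as likely quality failures).
* **Tiering.** Candidates in autosomal-dominant or X-linked genes seen
  fewer than 4 times cohort-wide form the dominant/XL review tier;
  heterozygous SVs pairing with a heterozygous HIGH-impact or
  known-pathogenic short variant in the same autosomal-recessive gene and
  sample become compound-heterozygote candidates.
* **BND → inversion algebra.** An inversion of `[B, E]` appears as two
  reciprocal breakend mate pairs — a head-to-head junction at `(B−1, E)`
  (`t]p]` ALTs) and a tail-to-tail junction at `(B, E+1)` (`[p[t` ALTs).
  `pair_bnd_to_inversion` recognizes the quartet and reconstructs the span
  exactly.
* **Reconciliation with read-depth CNV calls** into three event
  categories: *simple CNV* (deletion/duplication matching an RD segment by
  ≥ 0.5 reciprocal overlap, or plausibly missed by RD because of its
  size), *complex SV* (an RD segment of any state next to, but not
  matching, the call), and *copy-number-neutral* (inversions/breakends
  with no RD signal nearby).
* **Reporting.** Clinician-style candidate tables (breakpoints, cohort AF,
  affected status, HPO/ORDO, genes, samples sharing the SV, tier,
  category), IGV batch scripts snapshotting both breakpoints and the full
  span, per-group summary tables, and a "clear-cut" evidence flag
  (multi-signal support + phenotype match + segregation + clean visual
  inspection).
* **Synthetic cohort generator** (`exomesv.simulate`): trio/singleton
  families across four submitting networks (ERNs: RND, ITHACA, NMD,
  GENTURIS), polymorphic SV loci with 21–100 carriers, artifact hotspots
  emitting mixed-type calls at near-identical positions, calibrated
  confidence-interval widths, and planted causal events with a ground-truth
  table — so the full pipeline is testable without access-controlled
  patient data.

## Worked example

```python
from exomesv.simulate import SimConfig, simulate_cohort, evaluate_recovery
from exomesv.prioritize import run_prioritization

bundle = simulate_cohort(SimConfig(n_families=60, seed=7))
result = run_prioritization(bundle.callsets, bundle.samples, bundle.genes,
                            short_variants=bundle.short_variants)
print(result.cascade_log.to_string(index=False))
recovery = evaluate_recovery(result.all_candidates(), bundle.truth,
                             stage_survivors=result.stage_survivors)
print(recovery.per_class.to_string(index=False))
for rec, short in result.compound_het_pairs:
    print(f"compound het: {rec.sv.sample_id} {rec.sv.svtype.value} "
          f"{rec.sv.chrom}:{rec.sv.start}-{rec.sv.end} + missense in "
          f"{short.gene}")
```

prints (abridged to one group):

```
   group       stage  n_in  n_out  n_samples
     RND        pass   897    802         30
     RND        rare   802     86         27
     RND bnd_pairing    86     86         27
     RND       panel    86      4          4
     RND    chrom_qc     4      4          4
       class  n_planted  n_recovered  recall
      causal          8            8     1.0
polymorphism         30            0     0.0
    artifact         15            0     0.0
compound het: FAM0001_P DEL 2:2389800-2399362 + missense in GENE032
```

Reading the cascade log: of 897 raw RND calls, 802 were caller-PASS, 86
were rare (cohort count ≤ 20 — the rarity filter removes the planted
polymorphisms and artifact hotspots), 4 affected a panel gene, and no
sample failed chromosome QC.  All 8 planted causal events (including two
inversions encoded as BND quartets) survive to the candidate tables; the
multi-exon deletion pairs with the planted pathogenic missense variant in
the same recessive gene.

The same workflow is available from a shell:

```bash
exomesv simulate --families 60 --seed 7 --out bundle/
exomesv index --vcf-dir bundle/vcf --window 20 --out idx.tsv
exomesv prioritize --vcf-dir bundle/vcf --index idx.tsv \
    --panel bundle/gene_panel.tsv --samples bundle/samples.tsv \
    --short-variants bundle/short_variants.tsv \
    --cnv bundle/cnv_segments.tsv --out out/
exomesv report --vcf-dir bundle/vcf --panel bundle/gene_panel.tsv \
    --samples bundle/samples.tsv --cnv bundle/cnv_segments.tsv --out rep/
```

## File formats

All tabular inputs are single-header TSVs; coordinates are 1-based closed
except BED-style exon columns in the gene panel (0-based half-open,
converted on read).

| file | columns |
|---|---|
| sample sheet | `sample_id family_id affected group hpo ordo` (`hpo` semicolon-separated) |
| gene panel | `symbol chrom strand exon_starts exon_ends panels inheritance` (comma-separated lists; exon coordinates BED-style) |
| CNV segments | `sample_id chrom start end state caller` (`state` ∈ loss/gain) |
| short variants | `sample_id chrom pos gene category zygosity` (`category` ∈ high_impact/pathogenic_missense) |
| truth table | `event_id class svtype chrom start end gene carriers call_ids` |

SV callsets are VCF 4.1+ with `SVTYPE`, `END`, `SVLEN`, `CIPOS`, `CIEND`
and `MATEID` INFO keys, symbolic `<DEL>/<DUP>/<INS>/<INV>` ALTs and
bracketed breakend notation for BND records.

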