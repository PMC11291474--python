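"""The filter cascade turning raw per-sample SV callsets into candidate
tables for clinical review.

Stage order: caller PASS filter -> cohort rarity filter (breakpoint count
<= 20 of all datasets) -> breakend pairing into inversions -> exon-overlap
annotation against the submitting group's disease-gene panel (exons padded
by 5 bp) -> per-sample chromosome QC (samples with candidates on more than
5 chromosomes are dropped as likely quality failures) -> dominant/X-linked
tiering (cohort count < 4) -> compound-heterozygote pairing with short
variants in recessive genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .cohort_af import (
    CohortIndex,
    build_cohort_index,
    cohort_fraction_pct,
    samples_near,
    sv_cohort_count,
)
from .model import (
    DOMINANT_XL_MODES,
    PANEL_GROUPS,
    CandidateRecord,
    GeneModel,
    Genotype,
    Group,
    InheritanceMode,
    SVCall,
    SVType,
    SampleMeta,
    ShortVariant,
    Tier,
)
from .reconcile import ReconcileConfig, pair_bnd_to_inversion

logger = logging.getLogger(__name__)

#: Cascade stage names, in execution order.
STAGES = ("input", "pass", "rare", "bnd_pairing", "panel", "chrom_qc")


@dataclass
class PrioritizationConfig:
    """Thresholds of the filter cascade.

    ``max_cohort_count``: keep SVs seen in at most this many datasets
    (inclusive).  ``exon_pad_bp``: an SV within this many bp of an exon
    still counts as affecting it.  ``max_candidate_chromosomes``: samples
    with candidates on more chromosomes than this are dropped.
    ``dominant_tier_max_count``: exclusive bound; the dominant/XL tier is
    assigned iff cohort count < this value.
    """

    max_cohort_count: int = 20
    exon_pad_bp: int = 5
    max_candidate_chromosomes: int = 5
    dominant_tier_max_count: int = 4
    require_pass: bool = True
    count_combine: str = "max"

    def __post_init__(self) -> None:
        for name in ("max_cohort_count", "exon_pad_bp",
                     "max_candidate_chromosomes", "dominant_tier_max_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dominant_tier_max_count > self.max_cohort_count:
            raise ValueError(
                "dominant_tier_max_count must not exceed max_cohort_count")


class GeneIndex:
    """Interval-tree lookup from genomic intervals to gene exons."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self.by_symbol = {g.symbol: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for s, e in g.exons:
                tree.addi(s, e + 1, g.symbol)   # half-open for the tree

    def hits(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene symbols with an exon intersecting closed [start, end]."""
        tree = self._trees.get(chrom)
        if tree is None or end < start:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end + 1)})


def _as_gene_index(genes: Union[GeneIndex, Sequence[GeneModel]]) -> GeneIndex:
    return genes if isinstance(genes, GeneIndex) else GeneIndex(genes)


# ---------------------------------------------------------------------------
# individual cascade stages
# ---------------------------------------------------------------------------

def filter_pass(calls: Sequence[SVCall]) -> list[SVCall]:
    """Keep caller-PASS records, preserving order."""
    kept = [c for c in calls if c.is_pass]
    if len(kept) != len(calls):
        logger.debug("filter_pass removed %d of %d calls",
                     len(calls) - len(kept), len(calls))
    return kept


def filter_rare(calls: Sequence[SVCall], index: CohortIndex,
                config: Optional[PrioritizationConfig] = None
                ) -> list[SVCall]:
    """Keep SVs whose cohort breakpoint count is <= the rarity threshold.

    Attaches ``cohort_count`` to every retained call.
    """
    config = config or PrioritizationConfig()
    kept = []
    for call in calls:
        count = sv_cohort_count(index, call, combine=config.count_combine)
        call.cohort_count = count
        if count <= config.max_cohort_count:
            kept.append(call)
    return kept


def annotate_gene_overlap(call: SVCall,
                          genes: Union[GeneIndex, Sequence[GeneModel]],
                          config: Optional[PrioritizationConfig] = None
                          ) -> list[str]:
    """Gene symbols whose padded exons the SV affects.

    Spanned types (DEL/DUP/INV, including reconstructed inversions) hit a
    gene when their closed span intersects an exon expanded by
    ``exon_pad_bp``; single-breakend types (BND/INS) use the breakend
    position expanded by its confidence interval plus the pad.
    """
    config = config or PrioritizationConfig()
    gi = _as_gene_index(genes)
    pad = config.exon_pad_bp
    if call.svtype in (SVType.DEL, SVType.DUP, SVType.INV):
        return gi.hits(call.chrom, call.start - pad, call.end + pad)
    hits: set[str] = set()
    for be in call.breakends:
        hits.update(gi.hits(be.chrom, be.pos + be.ci_lo - pad,
                            be.pos + be.ci_hi + pad))
    return sorted(hits)


def filter_gene_panel(calls: Sequence[SVCall],
                      genes: Union[GeneIndex, Sequence[GeneModel]],
                      group: Group,
                      config: Optional[PrioritizationConfig] = None
                      ) -> list[SVCall]:
    """Keep SVs hitting at least one gene on the submitting group's panel.

    Attaches ``genes_hit`` (all hit genes, panel or not) to retained calls.
    """
    if group not in PANEL_GROUPS:
        raise ValueError(
            f"no gene panel for group {group!r}; panels exist for "
            f"{[g.value for g in PANEL_GROUPS]}")
    config = config or PrioritizationConfig()
    gi = _as_gene_index(genes)
    kept = []
    for call in calls:
        hit = annotate_gene_overlap(call, gi, config)
        on_panel = [s for s in hit if group in gi.by_symbol[s].panels]
        if on_panel:
            call.genes_hit = hit
            kept.append(call)
    return kept


def sample_chromosome_qc(candidates_by_sample: Mapping[str, Sequence[SVCall]],
                         config: Optional[PrioritizationConfig] = None
                         ) -> tuple[dict[str, list[SVCall]], dict[str, int]]:
    """Drop samples whose candidates span too many distinct chromosomes.

    Applied after panel filtering; returns ``(kept, dropped)`` where
    ``dropped`` maps sample id to its candidate-chromosome count.
    """
    config = config or PrioritizationConfig()
    kept: dict[str, list[SVCall]] = {}
    dropped: dict[str, int] = {}
    for sample, calls in candidates_by_sample.items():
        chroms = {c.chrom for c in calls}
        if len(chroms) > config.max_candidate_chromosomes:
            dropped[sample] = len(chroms)
            logger.info("sample %s dropped: candidates on %d chromosomes",
                        sample, len(chroms))
        else:
            kept[sample] = list(calls)
    return kept, dropped


def tier_dominant_xl(candidates: Sequence[CandidateRecord],
                     genes: Union[GeneIndex, Sequence[GeneModel]],
                     config: Optional[PrioritizationConfig] = None
                     ) -> list[CandidateRecord]:
    """Label candidates in dominant / X-linked genes seen < 4 times."""
    config = config or PrioritizationConfig()
    gi = _as_gene_index(genes)
    for rec in candidates:
        if rec.cohort_count >= config.dominant_tier_max_count:
            continue
        for symbol in rec.genes_hit:
            gene = gi.by_symbol.get(symbol)
            if gene and gene.inheritance_modes & DOMINANT_XL_MODES:
                rec.tier = Tier.DOMINANT_XL
                break
    return list(candidates)


def find_compound_het(candidates: Sequence[CandidateRecord],
                      short_variants: Sequence[ShortVariant],
                      genes: Union[GeneIndex, Sequence[GeneModel]]
                      ) -> list[tuple[CandidateRecord, ShortVariant]]:
    """Pair heterozygous SV candidates with heterozygous short variants in
    the same autosomal-recessive gene and sample.

    Matched candidates are tiered as recessive biallelic candidates.
    Co-occurrence, not phase, defines the pairing.
    """
    gi = _as_gene_index(genes)
    by_sample_gene: dict[tuple[str, str], list[ShortVariant]] = {}
    for sv in short_variants:
        if sv.zygosity is Genotype.HET:
            by_sample_gene.setdefault((sv.sample_id, sv.gene), []).append(sv)
    pairs: list[tuple[CandidateRecord, ShortVariant]] = []
    for rec in candidates:
        if rec.sv.genotype is not Genotype.HET:
            continue
        for symbol in rec.genes_hit:
            gene = gi.by_symbol.get(symbol)
            if gene is None or InheritanceMode.AR not in \
                    gene.inheritance_modes:
                continue
            for short in by_sample_gene.get((rec.sv.sample_id, symbol), []):
                pairs.append((rec, short))
                rec.tier = Tier.RECESSIVE_BIALLELIC
    pairs.sort(key=lambda p: (p[0].sv.sample_id, p[1].gene, p[1].pos))
    return pairs


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

@dataclass
class PrioritizationResult:
    """Per-group candidate tables plus the cascade bookkeeping."""

    tables: dict[Group, list[CandidateRecord]]
    cascade_log: pd.DataFrame
    dropped_samples: dict[str, int]
    compound_het_pairs: list[tuple[CandidateRecord, ShortVariant]]
    index: CohortIndex
    stage_survivors: list[tuple[str, set[tuple[str, str]]]] = \
        field(default_factory=list)

    def all_candidates(self) -> list[CandidateRecord]:
        out: list[CandidateRecord] = []
        for group in PANEL_GROUPS:
            out.extend(self.tables.get(group, []))
        return out


def _survivor_ids(calls: Iterable[SVCall]) -> set[tuple[str, str]]:
    ids: set[tuple[str, str]] = set()
    for c in calls:
        ids.add((c.sample_id, c.call_id))
        for src in c.source_ids:
            ids.add((c.sample_id, src))
    return ids


def run_prioritization(callsets: Mapping[str, Sequence[SVCall]],
                       samples: Sequence[SampleMeta],
                       genes: Sequence[GeneModel],
                       short_variants: Sequence[ShortVariant] = (),
                       index: Optional[CohortIndex] = None,
                       config: Optional[PrioritizationConfig] = None,
                       reconcile_config: Optional[ReconcileConfig] = None
                       ) -> PrioritizationResult:
    """Run the full cascade over a cohort.

    The cohort index is built over *all* datasets (affected and unaffected,
    PASS and non-PASS) while candidate tables are produced for affected
    samples of panel groups only; unaffected relatives inform frequencies
    and segregation, not candidate lists.
    """
    config = config or PrioritizationConfig()
    meta = {s.sample_id: s for s in samples}
    sheet_ids = set(meta)
    vcf_ids = set(callsets)
    if vcf_ids - sheet_ids or sheet_ids - vcf_ids:
        raise ValueError(
            "sample sheet and callsets disagree: "
            f"callsets without sheet entry: {sorted(vcf_ids - sheet_ids)}; "
            f"sheet entries without callset: {sorted(sheet_ids - vcf_ids)}")
    if index is None:
        index = build_cohort_index(callsets, window_bp=20)
    gi = GeneIndex(genes)

    focal = [s for s in samples if s.affected and s.group in PANEL_GROUPS]
    counts = {g: {stage: [0, set()] for stage in STAGES}
              for g in PANEL_GROUPS}
    survivors: dict[str, set[tuple[str, str]]] = {s: set() for s in STAGES}
    per_sample: dict[str, list[SVCall]] = {}

    def note(group: Group, stage: str, sample: str,
             calls: Sequence[SVCall]) -> None:
        counts[group][stage][0] += len(calls)
        if calls:
            counts[group][stage][1].add(sample)
        survivors[stage] |= _survivor_ids(calls)

    for s in focal:
        calls = list(callsets[s.sample_id])
        note(s.group, "input", s.sample_id, calls)
        if config.require_pass:
            calls = filter_pass(calls)
        note(s.group, "pass", s.sample_id, calls)
        calls = filter_rare(calls, index, config)
        note(s.group, "rare", s.sample_id, calls)
        bnds = [c for c in calls if c.svtype is SVType.BND]
        others = [c for c in calls if c.svtype is not SVType.BND]
        inversions, leftover = pair_bnd_to_inversion(bnds, reconcile_config)
        for inv in inversions:
            inv.cohort_count = sv_cohort_count(index, inv,
                                               combine=config.count_combine)
        calls = others + inversions + leftover
        note(s.group, "bnd_pairing", s.sample_id, calls)
        calls = filter_gene_panel(calls, gi, s.group, config)
        note(s.group, "panel", s.sample_id, calls)
        per_sample[s.sample_id] = calls

    kept, dropped = sample_chromosome_qc(per_sample, config)
    tables: dict[Group, list[CandidateRecord]] = {g: [] for g in PANEL_GROUPS}
    for sample_id, calls in kept.items():
        s = meta[sample_id]
        note(s.group, "chrom_qc", sample_id, calls)
        for call in calls:
            sharing = sorted({other
                              for be in call.breakends
                              for other in samples_near(index, be.chrom,
                                                        be.pos)
                              if other != sample_id})
            tables[s.group].append(CandidateRecord(
                sv=call,
                cohort_count=call.cohort_count,
                cohort_fraction_pct=cohort_fraction_pct(call.cohort_count,
                                                        index.n_datasets),
                genes_hit=list(call.genes_hit or []),
                sharing_samples=sharing,
                group=s.group,
            ))
    for group in PANEL_GROUPS:
        tables[group].sort(key=lambda r: (r.sv.sample_id, r.sv.chrom,
                                          r.sv.start, r.sv.call_id))
        tier_dominant_xl(tables[group], gi, config)
    pairs = find_compound_het(
        [r for g in PANEL_GROUPS for r in tables[g]], short_variants, gi)

    rows = []
    for group in PANEL_GROUPS:
        stage_counts = counts[group]
        for prev, stage in zip(STAGES, STAGES[1:]):
            rows.append({
                "group": group.value,
                "stage": stage,
                "n_in": stage_counts[prev][0],
                "n_out": stage_counts[stage][0],
                "n_samples": len(stage_counts[stage][1]),
            })
    log = pd.DataFrame(rows,
                       columns=["group", "stage", "n_in", "n_out",
                                "n_samples"])
    ordered = [(stage, survivors[stage]) for stage in STAGES]
    return PrioritizationResult(tables=tables, cascade_log=log,
                                dropped_samples=dropped,
                                compound_het_pairs=pairs,
                                index=index,
                                stage_survivors=ordered)
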