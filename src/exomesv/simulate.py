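"""Synthetic multi-sample exome SV cohort with a ground-truth table.

The generator emulates the statistical structure the reanalysis pipeline
assumes, at desk scale: a small synthetic genome (three contigs, ~10 Mb,
~50 genes), trio and singleton families submitted by four ERNs, polymorphic
SV loci shared by many carriers, recurrent artifact hotspots emitting
mixed-type calls at near-identical positions, caller-style breakpoint
confidence intervals (median ~17 bp, ~60% narrower than 40 bp), and a
plan of planted causal events in affected probands: single-exon deletions,
a multi-exon deletion forming a compound heterozygote with a pathogenic
missense variant, a duplication with an adjacent read-depth deletion
(complex SV), copy-number-neutral inversions encoded as breakend quartets,
and a simple duplication.

Read-depth CNV segments are emitted for planted CNVs at or above a size
floor and deliberately omitted below it (and for inversions), so the
event-categorization logic has positive and negative cases.  Everything is
deterministic given the seed.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import io as esv_io
from .model import (
    Breakend,
    CNState,
    CNVSegment,
    CandidateRecord,
    GeneModel,
    Genotype,
    Group,
    InheritanceMode,
    Orientation,
    SVCall,
    SVType,
    SampleMeta,
    ShortVariant,
    VariantCategory,
)

PathLike = Union[str, Path]

#: Synthetic genome: three contigs, ~10 Mb total.
CONTIGS: dict[str, int] = {"1": 4_000_000, "2": 4_000_000, "X": 2_000_000}

#: Cohort composition weights by submitting ERN (RND-heaviest, GENTURIS
#: smallest, mirroring typical rare-disease consortium proportions).
GROUP_WEIGHTS: dict[Group, float] = {
    Group.RND: 0.376,
    Group.ITHACA: 0.304,
    Group.NMD: 0.262,
    Group.GENTURIS: 0.058,
}

CAUSAL_KINDS = ("single_exon_del", "multi_exon_del_compound_het",
                "complex_del_dup", "inversion_bnd", "dup_simple")


@dataclass
class CIWidthModel:
    """Discretized log-normal model of breakpoint confidence-interval widths.

    Two summaries pin down the two parameters: the median width and the
    fraction of widths below 40 bp.  Widths are rounded to integers and
    clipped to ``max_width_bp`` (a numerical guard against the log-normal
    tail; it moves neither summary).
    """

    median_bp: float = 17.0
    frac_below_40: float = 0.60
    max_width_bp: int = 1000

    @property
    def mu(self) -> float:
        return math.log(self.median_bp)

    @property
    def sigma(self) -> float:
        z = norm.ppf(self.frac_below_40)
        if z == 0:
            raise ValueError("frac_below_40 must differ from 0.5")
        return (math.log(40.0) - self.mu) / z

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        widths = np.rint(rng.lognormal(self.mu, self.sigma, size))
        return np.clip(widths, 0, self.max_width_bp).astype(int)

    def sample_one(self, rng: np.random.Generator) -> int:
        return int(self.sample(rng, 1)[0])


def ci_from_width(width: int) -> tuple[int, int]:
    """Split a width into (ci_lo, ci_hi) CIPOS offsets around a position."""
    return -(width // 2), width - width // 2


@dataclass
class CausalSpec:
    """One planted causal event.

    ``gene=None`` lets the generator pick a suitable panel gene with the
    required inheritance mode; a named gene must exist in the panel.
    """

    kind: str
    gene: Optional[str] = None
    size_bp: int = 1000
    inheritance: InheritanceMode = InheritanceMode.AD

    def __post_init__(self) -> None:
        if self.kind not in CAUSAL_KINDS:
            raise ValueError(f"unknown causal kind {self.kind!r}; "
                             f"allowed: {CAUSAL_KINDS}")
        if isinstance(self.inheritance, str):
            self.inheritance = InheritanceMode(self.inheritance)
        if self.size_bp < 2:
            raise ValueError("size_bp must be >= 2")


def default_causal_plan() -> list[CausalSpec]:
    """Default plant: the causal-event archetypes the cascade must recover.

    Single-exon deletions at the small and large end of the reported size
    range (66 and 3077 bp), a 9563 bp multi-exon deletion paired with a
    pathogenic missense variant in the same recessive gene, a duplication
    with an adjacent read-depth deletion (complex), two copy-number-neutral
    inversions (one 180 kb; one 1.5 Mb, a contig-scale stand-in for the
    multi-megabase case), and a simple duplication.
    """
    return [
        CausalSpec("single_exon_del", size_bp=66),
        CausalSpec("single_exon_del", size_bp=800),
        CausalSpec("single_exon_del", size_bp=3077),
        CausalSpec("multi_exon_del_compound_het", size_bp=9563,
                   inheritance=InheritanceMode.AR),
        CausalSpec("complex_del_dup", size_bp=40_000),
        CausalSpec("inversion_bnd", size_bp=1_500_000),
        CausalSpec("inversion_bnd", size_bp=180_000),
        CausalSpec("dup_simple", size_bp=25_000),
    ]


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort."""

    n_families: int = 200
    trio_fraction: float = 0.3
    n_polymorphic_loci: int = 30
    polymorphism_carrier_range: tuple[int, int] = (21, 100)
    n_artifact_hotspots: int = 15
    artifact_recurrence_range: tuple[int, int] = (30, 120)
    causal_plan: list[CausalSpec] = field(default_factory=default_causal_plan)
    ci_width_model: CIWidthModel = field(default_factory=CIWidthModel)
    non_pass_rate: float = 0.1
    background_calls_mean: float = 3.0
    rd_min_size_bp: int = 5000
    n_cnv_noise_segments: int = 20
    n_short_variant_noise: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "n_polymorphic_loci",
                     "n_artifact_hotspots", "rd_min_size_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("trio_fraction", "non_pass_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["polymorphism_carrier_range"] = list(
            self.polymorphism_carrier_range)
        d["artifact_recurrence_range"] = list(self.artifact_recurrence_range)
        d["causal_plan"] = [
            {"kind": c.kind, "gene": c.gene, "size_bp": c.size_bp,
             "inheritance": c.inheritance.value}
            for c in self.causal_plan]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "polymorphism_carrier_range" in d:
            d["polymorphism_carrier_range"] = tuple(
                d["polymorphism_carrier_range"])
        if "artifact_recurrence_range" in d:
            d["artifact_recurrence_range"] = tuple(
                d["artifact_recurrence_range"])
        if "ci_width_model" in d and isinstance(d["ci_width_model"], dict):
            d["ci_width_model"] = CIWidthModel(**d["ci_width_model"])
        if "causal_plan" in d:
            d["causal_plan"] = [CausalSpec(**c) for c in d["causal_plan"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: PathLike) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return Path(path)


@dataclass
class TruthRecord:
    """Ground truth for one planted event (causal, polymorphism, artifact)."""

    event_id: str
    event_class: str            # causal | polymorphism | artifact
    svtype: str
    chrom: str
    start: int
    end: int
    gene: Optional[str]
    sample_ids: list[str]
    call_ids: list[tuple[str, str]]   # (sample_id, call_id)


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, plus the truth table."""

    samples: list[SampleMeta]
    genes: list[GeneModel]
    callsets: dict[str, list[SVCall]]
    cnv_segments: list[CNVSegment]
    short_variants: list[ShortVariant]
    truth: list[TruthRecord]
    config: SimConfig


# ---------------------------------------------------------------------------
# genome and cohort scaffolding
# ---------------------------------------------------------------------------

def _make_genes(rng: np.random.Generator) -> list[GeneModel]:
    """~50 genes across the synthetic contigs with panel/mode assignments.

    Panel and inheritance assignments cycle deterministically so every
    panel is guaranteed dominant and recessive genes; a random second panel
    mimics genes shared between ERN lists.
    """
    plan = [("1", 20), ("2", 20), ("X", 10)]
    panels = [Group.RND, Group.ITHACA, Group.NMD, Group.GENTURIS]
    autosomal_modes = [{InheritanceMode.AD}, {InheritanceMode.AR},
                       {InheritanceMode.AD, InheritanceMode.AR}]
    x_modes = [{InheritanceMode.XLD}, {InheritanceMode.XLR}]
    genes: list[GeneModel] = []
    idx = 0
    for chrom, count in plan:
        spacing = (CONTIGS[chrom] - 100_000) // count
        for i in range(count):
            region_start = 50_000 + i * spacing
            n_exons = int(rng.integers(6, 13))
            exon_lens = rng.integers(80, 301, n_exons)
            intron_lens = rng.integers(1000, 2601, n_exons - 1)
            exons = []
            pos = region_start
            for j in range(n_exons):
                exons.append((pos, pos + int(exon_lens[j]) - 1))
                pos = exons[-1][1] + 1
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_panels = {panels[idx % 4]}
            if rng.random() < 0.3:
                gene_panels.add(panels[int(rng.integers(4))])
            if chrom == "X":
                modes = set(x_modes[idx % 2])
            else:
                modes = set(autosomal_modes[idx % 3])
            genes.append(GeneModel(f"GENE{idx:03d}", chrom, strand, exons,
                                   gene_panels, modes))
            idx += 1
    return genes


def _make_samples(rng: np.random.Generator,
                  config: SimConfig) -> list[SampleMeta]:
    groups = list(GROUP_WEIGHTS)
    weights = np.array([GROUP_WEIGHTS[g] for g in groups])
    weights = weights / weights.sum()
    hpo_pool = [f"HP:{int(x):07d}"
                for x in rng.integers(1, 3_000_000, size=40)]
    samples: list[SampleMeta] = []
    for i in range(config.n_families):
        fam = f"FAM{i:04d}"
        group = groups[int(rng.choice(len(groups), p=weights))]
        trio = rng.random() < config.trio_fraction
        n_hpo = int(rng.integers(2, 5))
        hpo = sorted(rng.choice(hpo_pool, size=n_hpo, replace=False))
        ordo = (f"ORPHA:{int(rng.integers(1000, 99_999))}"
                if rng.random() < 0.6 else None)
        samples.append(SampleMeta(f"{fam}_P", fam, True, group,
                                  list(hpo), ordo))
        if trio:
            samples.append(SampleMeta(f"{fam}_F", fam, False, group))
            samples.append(SampleMeta(f"{fam}_M", fam, False, group))
    return samples


# ---------------------------------------------------------------------------
# inversion quartet
# ---------------------------------------------------------------------------

def plant_inversion_as_bnd(gene: GeneModel, span: tuple[int, int],
                           sample_id: str,
                           ids: Optional[Sequence[str]] = None,
                           cis: Optional[Sequence[tuple[int, int]]] = None
                           ) -> list[SVCall]:
    """Emit the canonical breakend quartet encoding an inversion of ``span``.

    The quartet comprises a head-to-head mate pair at ``(B-1, E)`` (ALT
    form ``t]p]``) and a tail-to-tail pair at ``(B, E+1)`` (``[p[t``),
    for span ``[B, E]``; :func:`exomesv.reconcile.pair_bnd_to_inversion`
    reconstructs exactly the input span from it.
    """
    b, e = span
    if b >= e:
        raise ValueError(f"degenerate inversion span {span}")
    if b < 2:
        raise ValueError("inversion span must start at position >= 2")
    if not (b <= gene.end and e >= gene.start):
        raise ValueError(
            f"span {span} does not overlap gene {gene.symbol} "
            f"({gene.start}-{gene.end})")
    chrom = gene.chrom
    if ids is None:
        ids = [f"{sample_id}_inv_{tag}" for tag in "wuvx"]
    if cis is None:
        cis = [(0, 0)] * 4
    specs = [
        # (pos, mate_pos, orientation, mate_id index)
        (b - 1, e, Orientation.LEFT_ANCHORED, 1),
        (e, b - 1, Orientation.LEFT_ANCHORED, 0),
        (b, e + 1, Orientation.RIGHT_ANCHORED, 3),
        (e + 1, b, Orientation.RIGHT_ANCHORED, 2),
    ]
    calls = []
    for k, (pos, mate_pos, orientation, mate_k) in enumerate(specs):
        lo, hi = cis[k]
        be = Breakend(chrom, pos, lo, hi, orientation=orientation,
                      mate_chrom=chrom, mate_pos=mate_pos,
                      mate_inverted=True)
        calls.append(SVCall(ids[k], sample_id, SVType.BND, chrom, pos, pos,
                            [be], filter_status="PASS",
                            genotype=Genotype.HET, mate_id=ids[mate_k]))
    return calls


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, config: SimConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.genes = _make_genes(self.rng)
        self.samples = _make_samples(self.rng, config)
        self.callsets: dict[str, list[SVCall]] = {
            s.sample_id: [] for s in self.samples}
        self.counters: dict[str, int] = {s.sample_id: 0
                                         for s in self.samples}
        self.cnv_segments: list[CNVSegment] = []
        self.short_variants: list[ShortVariant] = []
        self.truth: list[TruthRecord] = []
        self.used_genes: set[str] = set()
        self.used_families: set[str] = set()
        self.groups_available: set[Group] = {
            s.group for s in self.samples if s.affected}
        # breakpoints that polymorphisms/hotspots must stay away from
        self.reserved: dict[str, list[int]] = {c: [] for c in CONTIGS}
        # spans in carrier samples where background noise is suppressed
        self.guard: dict[str, list[tuple[str, int, int]]] = {}

    # -- low-level helpers -------------------------------------------------

    def next_id(self, sample: str) -> str:
        self.counters[sample] += 1
        return f"{sample}_{self.counters[sample]}"

    def draw_ci(self) -> tuple[int, int]:
        return ci_from_width(
            self.config.ci_width_model.sample_one(self.rng))

    def add_call(self, sample: str, svtype: SVType, chrom: str,
                 start: int, end: int, *, genotype: Genotype = Genotype.HET,
                 filter_status: str = "PASS",
                 length_bp: Optional[int] = None) -> SVCall:
        ci1, ci2 = self.draw_ci(), self.draw_ci()
        breakends = [Breakend(chrom, start, ci1[0], ci1[1],
                              orientation=Orientation.LEFT_ANCHORED)]
        if svtype in (SVType.DEL, SVType.DUP, SVType.INV):
            breakends.append(Breakend(chrom, end, ci2[0], ci2[1],
                                      orientation=Orientation.RIGHT_ANCHORED))
        call = SVCall(self.next_id(sample), sample, svtype, chrom, start,
                      end, breakends, filter_status=filter_status,
                      genotype=genotype, length_bp=length_bp)
        self.callsets[sample].append(call)
        return call

    def reserve(self, chrom: str, *positions: int) -> None:
        self.reserved[chrom].extend(positions)

    def free_position(self, min_dist: int = 300) -> tuple[str, int]:
        names = list(CONTIGS)
        lengths = np.array([CONTIGS[c] for c in names], dtype=float)
        probs = lengths / lengths.sum()
        for _ in range(500):
            chrom = names[int(self.rng.choice(len(names), p=probs))]
            pos = int(self.rng.integers(20_000, CONTIGS[chrom] - 20_000))
            if all(abs(pos - r) > min_dist for r in self.reserved[chrom]):
                return chrom, pos
        raise RuntimeError("could not place a locus away from reserved "
                           "breakpoints")

    def pick_gene(self, spec: CausalSpec,
                  min_span: int = 0) -> GeneModel:
        if spec.gene is not None:
            for g in self.genes:
                if g.symbol == spec.gene:
                    return g
            raise ValueError(
                f"causal plan references gene {spec.gene!r} absent from "
                "the generated panel")
        pool = [g for g in self.genes
                if g.symbol not in self.used_genes
                and spec.inheritance in g.inheritance_modes
                and g.panels & self.groups_available
                and g.end - g.start + 1 >= min_span]
        if not pool:
            raise ValueError(
                f"no unused gene with mode {spec.inheritance.value} and "
                f"span >= {min_span} available for {spec.kind}")
        return pool[int(self.rng.integers(len(pool)))]

    def pick_proband(self, gene: GeneModel) -> SampleMeta:
        panels = sorted(gene.panels & self.groups_available,
                        key=lambda g: g.value)
        if not panels:
            raise ValueError(f"no affected sample in any panel group of "
                             f"gene {gene.symbol}")
        group = panels[int(self.rng.integers(len(panels)))]
        probands = [s for s in self.samples
                    if s.affected and s.group is group]
        unused = [s for s in probands
                  if s.family_id not in self.used_families]
        # tiny cohorts: fall back to reusing a family rather than failing
        chosen = (unused or probands)[0]
        self.used_families.add(chosen.family_id)
        return chosen

    def guard_region(self, sample: str, chrom: str, lo: int,
                     hi: int) -> None:
        self.guard.setdefault(sample, []).append((chrom, lo - 2000,
                                                  hi + 2000))

    def guarded(self, sample: str, chrom: str, lo: int, hi: int) -> bool:
        for gc, gl, gh in self.guard.get(sample, []):
            if gc == chrom and lo <= gh and hi >= gl:
                return True
        return False

    # -- causal events -----------------------------------------------------

    def plant_causal(self) -> None:
        for k, spec in enumerate(self.config.causal_plan):
            eid = f"causal_{k:02d}"
            if spec.kind == "single_exon_del":
                self._plant_single_exon_del(eid, spec)
            elif spec.kind == "multi_exon_del_compound_het":
                self._plant_compound_het(eid, spec)
            elif spec.kind == "complex_del_dup":
                self._plant_complex(eid, spec)
            elif spec.kind == "inversion_bnd":
                self._plant_inversion(eid, spec)
            elif spec.kind == "dup_simple":
                self._plant_simple_dup(eid, spec)

    def _finish(self, eid: str, svtype: str, gene: Optional[GeneModel],
                chrom: str, start: int, end: int, sample: str,
                calls: Sequence[SVCall]) -> None:
        if gene is not None:
            self.used_genes.add(gene.symbol)
        self.reserve(chrom, start, end)
        self.guard_region(sample, chrom, start, end)
        self.truth.append(TruthRecord(
            eid, "causal", svtype, chrom, start, end,
            gene.symbol if gene else None, [sample],
            [(sample, c.call_id) for c in calls]))

    def _plant_single_exon_del(self, eid: str, spec: CausalSpec) -> None:
        size = spec.size_bp
        margin = 12          # keep > exon_pad_bp away from neighbour exons
        for _ in range(200):
            gene = self.pick_gene(spec)
            exon_order = self.rng.permutation(len(gene.exons))
            placed = None
            for ei in exon_order:
                s, e = gene.exons[ei]
                exon_len = e - s + 1
                if size <= exon_len - 2:
                    start = s + 1
                    placed = (start, start + size - 1)
                    break
                prev_end = gene.exons[ei - 1][1] if ei > 0 else s - 50_000
                next_start = (gene.exons[ei + 1][0]
                              if ei < len(gene.exons) - 1 else e + 50_000)
                avail_left = s - prev_end - 1 - margin
                avail_right = next_start - e - 1 - margin
                extra = size - exon_len
                if extra <= avail_left + avail_right and avail_left >= 0 \
                        and avail_right >= 0:
                    left = min(avail_left, max(0, extra - avail_right))
                    left = max(left, min(avail_left, extra // 2))
                    start = s - left
                    placed = (start, start + size - 1)
                    break
            if placed is not None:
                break
            self.used_genes.add(gene.symbol)   # unusable for this size
        else:
            raise RuntimeError(f"could not place single-exon deletion of "
                               f"{size} bp")
        proband = self.pick_proband(gene)
        call = self.add_call(proband.sample_id, SVType.DEL, gene.chrom,
                             placed[0], placed[1])
        self._finish(eid, "DEL", gene, gene.chrom, placed[0], placed[1],
                     proband.sample_id, [call])

    def _plant_compound_het(self, eid: str, spec: CausalSpec) -> None:
        size = spec.size_bp
        gene = self.pick_gene(spec, min_span=size + 1500)
        start = max(2, gene.exons[0][0] - 200)
        end = start + size - 1
        covered = [ex for ex in gene.exons if ex[1] <= end]
        if len(covered) < 2:
            raise RuntimeError("compound-het deletion does not cover two "
                               "exons; gene model too sparse")
        proband = self.pick_proband(gene)
        call = self.add_call(proband.sample_id, SVType.DEL, gene.chrom,
                             start, end)
        # read-depth support: the deletion is large enough for RD callers
        if size >= self.config.rd_min_size_bp:
            jitter = int(self.rng.integers(-300, 301))
            self.cnv_segments.append(CNVSegment(
                proband.sample_id, gene.chrom, max(1, start + jitter),
                end + int(self.rng.integers(-300, 301)), CNState.LOSS,
                "clincnv"))
        # the other allele: a known-pathogenic missense outside the deletion
        remaining = [ex for ex in gene.exons if ex[0] > end]
        if remaining:
            pos = remaining[0][0] + 5
        else:
            pos = gene.exons[-1][1] - 5
        self.short_variants.append(ShortVariant(
            proband.sample_id, gene.chrom, pos, gene.symbol,
            VariantCategory.PATHOGENIC_MISSENSE, Genotype.HET))
        self._finish(eid, "DEL", gene, gene.chrom, start, end,
                     proband.sample_id, [call])

    def _plant_complex(self, eid: str, spec: CausalSpec) -> None:
        gene = self.pick_gene(spec)
        start = max(2, gene.start - 1000)
        end = start + spec.size_bp - 1
        proband = self.pick_proband(gene)
        call = self.add_call(proband.sample_id, SVType.DUP, gene.chrom,
                             start, end)
        # RD sees a deletion next to the detected duplication, not the
        # duplication itself: together they form a complex SV.
        self.cnv_segments.append(CNVSegment(
            proband.sample_id, gene.chrom, end + 300, end + 15_300,
            CNState.LOSS, "exomedepth"))
        self._finish(eid, "DUP", gene, gene.chrom, start, end,
                     proband.sample_id, [call])

    def _plant_inversion(self, eid: str, spec: CausalSpec) -> None:
        length = spec.size_bp
        gene = self.pick_gene(spec)
        contig_len = CONTIGS[gene.chrom]
        if length > contig_len - 40_000:
            raise ValueError(f"inversion of {length} bp does not fit on "
                             f"contig {gene.chrom}")
        start = max(2, gene.start - length // 3)
        if start + length - 1 > contig_len - 20_000:
            start = contig_len - 20_000 - length + 1
        end = start + length - 1
        proband = self.pick_proband(gene)
        widths = self.config.ci_width_model.sample(self.rng, 4)
        ids = [self.next_id(proband.sample_id) for _ in range(4)]
        calls = plant_inversion_as_bnd(
            gene, (start, end), proband.sample_id, ids=ids,
            cis=[ci_from_width(int(w)) for w in widths])
        self.callsets[proband.sample_id].extend(calls)
        self.reserve(gene.chrom, start - 1, start, end, end + 1)
        self._finish(eid, "INV", gene, gene.chrom, start, end,
                     proband.sample_id, calls)

    def _plant_simple_dup(self, eid: str, spec: CausalSpec) -> None:
        gene = self.pick_gene(spec)
        start = max(2, gene.start - 500)
        end = start + spec.size_bp - 1
        proband = self.pick_proband(gene)
        call = self.add_call(proband.sample_id, SVType.DUP, gene.chrom,
                             start, end)
        if spec.size_bp >= self.config.rd_min_size_bp:
            self.cnv_segments.append(CNVSegment(
                proband.sample_id, gene.chrom,
                max(1, start + int(self.rng.integers(-300, 301))),
                end + int(self.rng.integers(-300, 301)),
                CNState.GAIN, "conifer"))
        self._finish(eid, "DUP", gene, gene.chrom, start, end,
                     proband.sample_id, [call])

    # -- recurrent non-causal structure ------------------------------------

    def plant_polymorphisms(self) -> None:
        lo, hi = self.config.polymorphism_carrier_range
        all_ids = [s.sample_id for s in self.samples]
        hi = min(hi, len(all_ids))
        lo = min(lo, hi)
        for k in range(self.config.n_polymorphic_loci):
            chrom, pos = self.free_position()
            length = int(self.rng.integers(500, 5001))
            svtype = SVType.DEL if self.rng.random() < 0.6 else SVType.DUP
            width = self.config.ci_width_model.sample_one(self.rng)
            jitter_max = min(width // 2, 10)
            n_carriers = int(self.rng.integers(lo, hi + 1))
            carriers = sorted(self.rng.choice(all_ids, size=n_carriers,
                                              replace=False))
            call_ids = []
            for sample in carriers:
                ds = int(self.rng.integers(-jitter_max, jitter_max + 1))
                de = int(self.rng.integers(-jitter_max, jitter_max + 1))
                genotype = (Genotype.HOM if self.rng.random() < 0.1
                            else Genotype.HET)
                call = self.add_call(sample, svtype, chrom, pos + ds,
                                     pos + length - 1 + de,
                                     genotype=genotype)
                call_ids.append((sample, call.call_id))
            self.reserve(chrom, pos, pos + length - 1)
            self.truth.append(TruthRecord(
                f"poly_{k:02d}", "polymorphism", svtype.value, chrom, pos,
                pos + length - 1, None, list(carriers), call_ids))

    def plant_artifacts(self) -> None:
        lo, hi = self.config.artifact_recurrence_range
        all_ids = [s.sample_id for s in self.samples]
        hi = min(hi, len(all_ids))
        lo = min(lo, hi)
        for k in range(self.config.n_artifact_hotspots):
            chrom, pos = self.free_position()
            n = int(self.rng.integers(lo, hi + 1))
            carriers = sorted(self.rng.choice(all_ids, size=n,
                                              replace=False))
            call_ids = []
            for sample in carriers:
                jitter = int(self.rng.integers(-5, 6))
                svtype = (SVType.DEL, SVType.DUP,
                          SVType.INS)[int(self.rng.integers(3))]
                start = pos + jitter
                if svtype is SVType.INS:
                    end = start
                else:
                    end = start + int(self.rng.integers(100, 1001))
                status = ("PASS" if self.rng.random() < 0.7 else "MinGQ")
                call = self.add_call(sample, svtype, chrom, start, end,
                                     filter_status=status)
                call_ids.append((sample, call.call_id))
            self.reserve(chrom, pos)
            self.truth.append(TruthRecord(
                f"artifact_{k:02d}", "artifact", "MIXED", chrom, pos, pos,
                None, list(carriers), call_ids))

    def plant_background(self) -> None:
        names = list(CONTIGS)
        lengths = np.array([CONTIGS[c] for c in names], dtype=float)
        probs = lengths / lengths.sum()
        for s in self.samples:
            n = int(self.rng.poisson(self.config.background_calls_mean))
            for _ in range(n):
                chrom = names[int(self.rng.choice(len(names), p=probs))]
                pos = int(self.rng.integers(20_000,
                                            CONTIGS[chrom] - 20_000))
                r = self.rng.random()
                if r < 0.5:
                    svtype = SVType.DEL
                elif r < 0.75:
                    svtype = SVType.DUP
                elif r < 0.9:
                    svtype = SVType.INS
                else:
                    svtype = SVType.BND
                length = int(self.rng.integers(100, 10_001))
                end = pos + length - 1 if svtype in (SVType.DEL,
                                                     SVType.DUP) else pos
                status = ("MinGQ"
                          if self.rng.random() < self.config.non_pass_rate
                          else "PASS")
                if self.guarded(s.sample_id, chrom, pos, end):
                    continue
                if svtype is SVType.BND:
                    mate_chrom = names[int(self.rng.integers(len(names)))]
                    mate_pos = int(self.rng.integers(
                        20_000, CONTIGS[mate_chrom] - 20_000))
                    lo_w, hi_w = self.draw_ci()
                    be = Breakend(chrom, pos, lo_w, hi_w,
                                  orientation=(Orientation.LEFT_ANCHORED
                                               if self.rng.random() < 0.5
                                               else
                                               Orientation.RIGHT_ANCHORED),
                                  mate_chrom=mate_chrom, mate_pos=mate_pos,
                                  mate_inverted=bool(self.rng.random()
                                                     < 0.5))
                    self.callsets[s.sample_id].append(SVCall(
                        self.next_id(s.sample_id), s.sample_id, SVType.BND,
                        chrom, pos, pos, [be], filter_status=status,
                        genotype=Genotype.HET))
                else:
                    self.add_call(s.sample_id, svtype, chrom, pos, end,
                                  filter_status=status)

    def plant_noise_tables(self) -> None:
        unaffected = [s.sample_id for s in self.samples if not s.affected]
        callers = ["clincnv", "exomedepth", "conifer"]
        if unaffected:
            for _ in range(self.config.n_cnv_noise_segments):
                sample = unaffected[int(self.rng.integers(len(unaffected)))]
                chrom = list(CONTIGS)[int(self.rng.integers(len(CONTIGS)))]
                start = int(self.rng.integers(20_000,
                                              CONTIGS[chrom] - 80_000))
                length = int(self.rng.integers(5000, 50_001))
                state = (CNState.LOSS if self.rng.random() < 0.5
                         else CNState.GAIN)
                self.cnv_segments.append(CNVSegment(
                    sample, chrom, start, start + length - 1, state,
                    callers[int(self.rng.integers(3))]))
            for _ in range(self.config.n_short_variant_noise):
                sample = unaffected[int(self.rng.integers(len(unaffected)))]
                gene = self.genes[int(self.rng.integers(len(self.genes)))]
                exon = gene.exons[int(self.rng.integers(len(gene.exons)))]
                self.short_variants.append(ShortVariant(
                    sample, gene.chrom, exon[0] + 2, gene.symbol,
                    VariantCategory.HIGH_IMPACT, Genotype.HET))

    def build(self) -> CohortBundle:
        self.plant_causal()
        self.plant_polymorphisms()
        self.plant_artifacts()
        self.plant_background()
        self.plant_noise_tables()
        return CohortBundle(self.samples, self.genes, self.callsets,
                            self.cnv_segments, self.short_variants,
                            self.truth, self.config)


def simulate_cohort(config: Optional[SimConfig] = None) -> CohortBundle:
    """Generate a deterministic synthetic cohort bundle from ``config``."""
    return _Builder(config or SimConfig()).build()


# ---------------------------------------------------------------------------
# bundle serialization
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["event_id", "class", "svtype", "chrom", "start", "end",
                 "gene", "carriers", "call_ids"]


def write_truth_table(truth: Sequence[TruthRecord], path: PathLike) -> Path:
    rows = [{
        "event_id": t.event_id,
        "class": t.event_class,
        "svtype": t.svtype,
        "chrom": t.chrom,
        "start": t.start,
        "end": t.end,
        "gene": t.gene or "",
        "carriers": ";".join(t.sample_ids),
        "call_ids": ";".join(f"{s}:{c}" for s, c in t.call_ids),
    } for t in truth]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)
    return Path(path)


def read_truth_table(path: PathLike) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        call_ids = []
        for token in row["call_ids"].split(";"):
            if token:
                s, c = token.split(":", 1)
                call_ids.append((s, c))
        out.append(TruthRecord(
            row["event_id"], row["class"], row["svtype"], row["chrom"],
            int(row["start"]), int(row["end"]), row["gene"] or None,
            [s for s in row["carriers"].split(";") if s], call_ids))
    return out


def write_bundle(bundle: CohortBundle, outdir: PathLike) -> Path:
    """Write the bundle in exactly the formats the IO layer reads."""
    outdir = Path(outdir)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    for s in bundle.samples:
        esv_io.write_sv_vcf(bundle.callsets[s.sample_id],
                            vcf_dir / f"{s.sample_id}.vcf",
                            sample_id=s.sample_id, contigs=CONTIGS)
    esv_io.write_sample_sheet(bundle.samples, outdir / "samples.tsv")
    esv_io.write_gene_models(bundle.genes, outdir / "gene_panel.tsv")
    esv_io.write_cnv_segments(bundle.cnv_segments,
                              outdir / "cnv_segments.tsv")
    esv_io.write_short_variants(bundle.short_variants,
                                outdir / "short_variants.tsv")
    write_truth_table(bundle.truth, outdir / "truth.tsv")
    bundle.config.to_yaml(outdir / "sim_config.yaml")
    return outdir


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

@dataclass
class RecoveryResult:
    """Recovery of planted events by the pipeline's candidate tables."""

    per_class: pd.DataFrame
    per_event: pd.DataFrame

    def recall(self, event_class: str) -> float:
        row = self.per_class[self.per_class["class"] == event_class]
        if row.empty:
            return float("nan")
        return float(row["recall"].iloc[0])


def _candidate_matches(rec: CandidateRecord, truth: TruthRecord,
                       window: int) -> bool:
    if rec.sv.sample_id not in truth.sample_ids:
        return False
    if rec.sv.chrom != truth.chrom:
        return False
    positions = [p for _, p in rec.sv.breakpoints()]
    near = any(abs(p - t) <= window
               for p in positions for t in (truth.start, truth.end))
    if not near:
        return False
    if truth.gene is not None and truth.gene not in rec.genes_hit:
        return False
    return True


def evaluate_recovery(candidates: Sequence[CandidateRecord],
                      truth: Sequence[TruthRecord],
                      window_bp: int = 20,
                      stage_survivors: Optional[
                          Sequence[tuple[str, set[tuple[str, str]]]]] = None
                      ) -> RecoveryResult:
    """Score pipeline output against the truth table.

    A planted event counts as recovered when any candidate from one of its
    carrier samples matches a planted breakpoint within ``window_bp`` and
    (for causal events) lists the planted gene.  For lost events the first
    cascade stage at which every matching call disappeared is named, when
    per-stage survivor sets are supplied.
    """
    event_rows = []
    for t in truth:
        recovered = any(_candidate_matches(rec, t, window_bp)
                        for rec in candidates)
        stage_lost = ""
        if not recovered and stage_survivors:
            ids = set(t.call_ids)
            for stage, survivors in stage_survivors:
                if not ids & survivors:
                    stage_lost = stage
                    break
        event_rows.append({
            "event_id": t.event_id,
            "class": t.event_class,
            "recovered": recovered,
            "stage_lost": stage_lost,
        })
    per_event = pd.DataFrame(event_rows,
                             columns=["event_id", "class", "recovered",
                                      "stage_lost"])
    class_rows = []
    for cls in ("causal", "polymorphism", "artifact"):
        sub = per_event[per_event["class"] == cls]
        n = len(sub)
        rec = int(sub["recovered"].sum())
        class_rows.append({
            "class": cls,
            "n_planted": n,
            "n_recovered": rec,
            "recall": rec / n if n else 0.0,
        })
    per_class = pd.DataFrame(class_rows,
                             columns=["class", "n_planted", "n_recovered",
                                      "recall"])
    return RecoveryResult(per_class=per_class, per_event=per_event)
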