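"""Core domain model for cohort-scale exome structural-variant (SV) reanalysis.

The pipeline consumes per-sample SV callsets produced by a paired-end /
soft-clip caller (Manta-style VCF), gene panels with exon coordinates,
a sample sheet describing families and submitting European Reference
Networks (ERNs), read-depth CNV segment tables and short-variant tables.
All genomic coordinates are held internally as 1-based closed intervals
(VCF convention); BED-style half-open coordinates are converted at the
read/write boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Group(str, Enum):
    """Submitting ERN (European Reference Network) of a sample."""

    RND = "RND"
    ITHACA = "ITHACA"
    NMD = "NMD"
    GENTURIS = "GENTURIS"
    OTHER = "OTHER"


#: ERNs with a disease-gene panel; samples from these groups are prioritized.
PANEL_GROUPS: tuple[Group, ...] = (
    Group.RND,
    Group.ITHACA,
    Group.NMD,
    Group.GENTURIS,
)


class SVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    BND = "BND"


#: SV types represented by a chromosomal span rather than a single breakend.
SPANNED_TYPES = frozenset({SVType.DEL, SVType.DUP, SVType.INV})


class Orientation(str, Enum):
    """Side of the novel junction on which the local segment is anchored.

    ``LEFT_ANCHORED``: the locally retained sequence lies to the left of the
    junction (VCF breakend ALT forms ``t[p[`` and ``t]p]``).
    ``RIGHT_ANCHORED``: the retained sequence lies to the right (forms
    ``]p]t`` and ``[p[t``).
    """

    LEFT_ANCHORED = "left_anchored"
    RIGHT_ANCHORED = "right_anchored"


class Genotype(str, Enum):
    HET = "het"
    HOM = "hom"
    UNKNOWN = "unknown"


class Tier(str, Enum):
    DOMINANT_XL = "dominant_xl"
    RECESSIVE_BIALLELIC = "recessive_biallelic_candidate"
    OTHER = "other"


class Category(str, Enum):
    """Reconciliation of a PE/SC SV call with read-depth CNV evidence."""

    SIMPLE_CNV = "simple_cnv"
    COMPLEX_SV = "complex_sv"
    CN_NEUTRAL = "cn_neutral"
    UNCLASSIFIED = "unclassified"


class CNState(str, Enum):
    LOSS = "loss"
    GAIN = "gain"


class VariantCategory(str, Enum):
    HIGH_IMPACT = "high_impact"
    PATHOGENIC_MISSENSE = "pathogenic_missense"


class InheritanceMode(str, Enum):
    AD = "AD"
    AR = "AR"
    XLD = "XLD"
    XLR = "XLR"


#: Modes evaluated under the dominant / X-linked tier (AD plus X-linked,
#: both dominant and recessive, mirroring OMIM-based review practice).
DOMINANT_XL_MODES = frozenset(
    {InheritanceMode.AD, InheritanceMode.XLD, InheritanceMode.XLR}
)


@dataclass
class SampleMeta:
    """One sequenced dataset: family membership, phenotype, submitting ERN."""

    sample_id: str
    family_id: str
    affected: bool
    group: Group
    hpo_terms: list[str] = field(default_factory=list)
    ordo_code: Optional[str] = None


@dataclass
class Breakend:
    """One side of an SV junction with its positional confidence interval.

    ``ci_lo``/``ci_hi`` are signed offsets around ``pos`` (CIPOS semantics,
    ``ci_lo <= 0 <= ci_hi``).  ``mate_*`` fields are populated for BND
    records only; ``mate_inverted`` is True when the joined mate segment is
    reverse-complemented (bracket forms ``t]p]`` and ``[p[t``).
    """

    chrom: str
    pos: int
    ci_lo: int = 0
    ci_hi: int = 0
    orientation: Orientation = Orientation.LEFT_ANCHORED
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None
    mate_inverted: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if not (self.ci_lo <= 0 <= self.ci_hi):
            raise ValueError(
                f"confidence interval must satisfy ci_lo <= 0 <= ci_hi, "
                f"got ({self.ci_lo}, {self.ci_hi})"
            )

    @property
    def junction_code(self) -> str:
        """Two-strand junction code: '+-', '++', '-+' or '--'.

        '+-' is a deletion-like junction, '-+' duplication-like, and
        '++'/'--' the two reciprocal inverted junctions.
        """
        if self.orientation is Orientation.LEFT_ANCHORED:
            return "++" if self.mate_inverted else "+-"
        return "--" if self.mate_inverted else "-+"


@dataclass
class SVCall:
    """One structural-variant record from one sample.

    ``start``/``end`` follow VCF POS/END (1-based, inclusive); ``end`` equals
    ``start`` for INS and BND.  ``cohort_count`` and ``genes_hit`` are
    annotations attached during prioritization, never parsed from input.
    """

    call_id: str
    sample_id: str
    svtype: SVType
    chrom: str
    start: int
    end: int
    breakends: list[Breakend] = field(default_factory=list)
    filter_status: str = "PASS"
    genotype: Genotype = Genotype.UNKNOWN
    mate_id: Optional[str] = None
    length_bp: Optional[int] = None
    source_ids: tuple[str, ...] = ()
    cohort_count: Optional[int] = None
    genes_hit: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.svtype in SPANNED_TYPES and self.start > self.end:
            raise ValueError(
                f"{self.call_id}: start must be <= end for {self.svtype.value}"
            )
        if not self.breakends:
            if self.svtype is SVType.BND:
                raise ValueError(
                    f"{self.call_id}: BND calls require an explicit breakend"
                )
            self.breakends = self._default_breakends()
        n = len(self.breakends)
        expected = 2 if self.svtype in SPANNED_TYPES else 1
        if n != expected:
            raise ValueError(
                f"{self.call_id}: {self.svtype.value} requires {expected} "
                f"breakend(s), got {n}"
            )
        if self.length_bp is None:
            if self.svtype in SPANNED_TYPES:
                self.length_bp = abs(self.end - self.start) + 1
            else:
                self.length_bp = 0

    def _default_breakends(self) -> list[Breakend]:
        first = Breakend(self.chrom, self.start,
                         orientation=Orientation.LEFT_ANCHORED)
        if self.svtype in SPANNED_TYPES:
            second = Breakend(self.chrom, self.end,
                              orientation=Orientation.RIGHT_ANCHORED)
            return [first, second]
        return [first]

    @property
    def is_pass(self) -> bool:
        return self.filter_status == "PASS"

    def breakpoints(self) -> list[tuple[str, int]]:
        """(chrom, pos) of every breakend of this call."""
        return [(be.chrom, be.pos) for be in self.breakends]


@dataclass
class GeneModel:
    """A disease gene with exon intervals, panel membership and inheritance.

    Exons are 1-based closed intervals, sorted and non-overlapping.
    """

    symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    panels: set[Group] = field(default_factory=set)
    inheritance_modes: set[InheritanceMode] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.symbol}: strand must be '+' or '-'")
        for s, e in self.exons:
            if s > e:
                raise ValueError(
                    f"gene {self.symbol}: exon with end < start ({s}, {e})"
                )
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"gene {self.symbol}: overlapping exons "
                    f"({s1}-{e1}, {s2}-{e2})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class CNVSegment:
    """A read-depth-based copy-number call (1-based closed interval)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: CNState
    caller: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"CNV segment start must be <= end ({self.start}, {self.end})"
            )


@dataclass
class ShortVariant:
    """A short variant used for compound-heterozygote pairing."""

    sample_id: str
    chrom: str
    pos: int
    gene: str
    category: VariantCategory
    zygosity: Genotype

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("short variant must carry a gene symbol")


@dataclass
class CandidateRecord:
    """An SV surviving the filter cascade, with its clinical annotations."""

    sv: SVCall
    cohort_count: int
    cohort_fraction_pct: float
    genes_hit: list[str]
    tier: Tier = Tier.OTHER
    category: Category = Category.UNCLASSIFIED
    sharing_samples: list[str] = field(default_factory=list)
    clear_cut: Optional[bool] = None
    rd_support: Optional[bool] = None
    group: Optional[Group] = None

    def __post_init__(self) -> None:
        if self.cohort_count < 1:
            raise ValueError(
                "cohort_count must be >= 1 (the focal sample counts itself)"
            )
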