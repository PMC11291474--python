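"""Breakend pairing, inversion reconstruction and CNV reconciliation.

Exome SV callers report inversions as reciprocal breakend (BND) mate pairs
rather than as INV records: an inversion of the segment ``[B, E]`` appears
as four BND records forming two junctions, a head-to-head junction at
``(B-1, E)`` (both ALTs of the ``t]p]`` form, '++') and a tail-to-tail
junction at ``(B, E+1)`` (both ``[p[t``, '--').  :func:`pair_bnd_to_inversion`
recognizes this quartet and reconstructs the INV span.

:func:`categorize_event` reconciles a paired-end/soft-clip SV call with
read-depth (RD) CNV segments from the same sample into three event classes:
a simple CNV (deletion/duplication confirmed or plausibly missed by RD),
part of a complex SV (RD change next to, but not matching, the call), or a
copy-number-neutral event.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import (
    Breakend,
    CNState,
    CNVSegment,
    CandidateRecord,
    Category,
    Orientation,
    SVCall,
    SVType,
    SampleMeta,
    Tier,
)

logger = logging.getLogger(__name__)


@dataclass
class ReconcileConfig:
    """Tolerances for breakend pairing and SV/CNV reconciliation.

    ``bnd_pair_tolerance_bp`` bounds the positional disagreement between the
    two junctions of one inversion (informed by caller confidence-interval
    widths).  ``cnv_match_reciprocal_overlap`` defines when an RD segment is
    "the same event" as an SV call; ``adjacency_window_bp`` operationalizes
    an RD segment lying "next to" a breakend.
    """

    bnd_pair_tolerance_bp: int = 50
    cnv_match_reciprocal_overlap: float = 0.5
    adjacency_window_bp: int = 1000

    def __post_init__(self) -> None:
        if self.bnd_pair_tolerance_bp < 0 or self.adjacency_window_bp < 0:
            raise ValueError("tolerances must be >= 0")
        if not (0 < self.cnv_match_reciprocal_overlap <= 1):
            raise ValueError("reciprocal overlap fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# BND mate pairing and inversion reconstruction
# ---------------------------------------------------------------------------

def _resolve_mate_pairs(bnds: Sequence[SVCall], tol: int
                        ) -> tuple[list[tuple[SVCall, SVCall]], list[SVCall]]:
    """Group BND records into mate pairs by MATEID, else reciprocal position."""
    by_id = {b.call_id: b for b in bnds}
    paired: set[str] = set()
    pairs: list[tuple[SVCall, SVCall]] = []
    leftovers: list[SVCall] = []
    for b in bnds:
        if b.call_id in paired:
            continue
        if b.mate_id is not None:
            mate = by_id.get(b.mate_id)
            if mate is None:
                logger.warning("BND %s: MATEID %s not found; kept as leftover",
                               b.call_id, b.mate_id)
                leftovers.append(b)
                paired.add(b.call_id)
                continue
            if mate.call_id not in paired:
                pairs.append((b, mate))
                paired.update({b.call_id, mate.call_id})
                continue
        # positional fallback: reciprocal coordinates within tolerance
        found = None
        for other in bnds:
            if other.call_id in paired or other.call_id == b.call_id:
                continue
            if other.mate_id is not None:
                continue
            be, oe = b.breakends[0], other.breakends[0]
            if (be.mate_chrom == other.chrom and oe.mate_chrom == b.chrom
                    and abs(be.mate_pos - other.start) <= tol
                    and abs(oe.mate_pos - b.start) <= tol):
                found = other
                break
        if found is not None:
            pairs.append((b, found))
            paired.update({b.call_id, found.call_id})
        else:
            leftovers.append(b)
            paired.add(b.call_id)
    return pairs, leftovers


def _junction_kind(pair: tuple[SVCall, SVCall]) -> Optional[str]:
    codes = {pair[0].breakends[0].junction_code,
             pair[1].breakends[0].junction_code}
    if codes == {"++"}:
        return "++"
    if codes == {"--"}:
        return "--"
    return None


def _inv_span_candidate(pair: tuple[SVCall, SVCall], kind: str
                        ) -> Optional[tuple[str, int, int]]:
    a, b = pair
    if a.chrom != b.chrom:
        return None
    lo, hi = sorted((a.start, b.start))
    if kind == "++":        # junction at (B-1, E) -> span (B, E)
        return a.chrom, lo + 1, hi
    return a.chrom, lo, hi - 1   # '--' junction at (B, E+1)


def pair_bnd_to_inversion(calls: Sequence[SVCall],
                          config: Optional[ReconcileConfig] = None
                          ) -> tuple[list[SVCall], list[SVCall]]:
    """Reconstruct inversions from BND quartets.

    Returns ``(inversions, leftover_bnds)``.  Two same-sample mate pairs on
    one chromosome whose junction codes are '++' and '--' and whose implied
    spans agree within ``bnd_pair_tolerance_bp`` at both ends are merged
    into a single INV call spanning the union of the two implied spans.
    Non-BND input records are ignored.
    """
    config = config or ReconcileConfig()
    tol = config.bnd_pair_tolerance_bp
    bnds = [c for c in calls if c.svtype is SVType.BND]
    pairs, leftovers = _resolve_mate_pairs(bnds, tol)

    candidates = []   # (kind, span, pair)
    other_pairs = []
    for pair in pairs:
        kind = _junction_kind(pair)
        span = _inv_span_candidate(pair, kind) if kind else None
        if kind and span:
            candidates.append((kind, span, pair))
        else:
            other_pairs.append(pair)

    candidates.sort(key=lambda t: (t[1][0], t[1][1], t[1][2]))
    used = [False] * len(candidates)
    inversions: list[SVCall] = []
    for i, (kind_i, span_i, pair_i) in enumerate(candidates):
        if used[i] or kind_i != "++":
            continue
        for j, (kind_j, span_j, pair_j) in enumerate(candidates):
            if used[j] or kind_j != "--":
                continue
            if span_i[0] != span_j[0]:
                continue
            if (abs(span_i[1] - span_j[1]) <= tol
                    and abs(span_i[2] - span_j[2]) <= tol):
                used[i] = used[j] = True
                members = [*pair_i, *pair_j]
                start = min(span_i[1], span_j[1])
                end = max(span_i[2], span_j[2])
                ids = tuple(sorted(m.call_id for m in members))
                status = "PASS" if all(m.is_pass for m in members) else next(
                    m.filter_status for m in members if not m.is_pass)
                lo_be = min(members, key=lambda m: m.start).breakends[0]
                hi_be = max(members, key=lambda m: m.start).breakends[0]
                inv = SVCall(
                    call_id="INV_" + "_".join(ids),
                    sample_id=members[0].sample_id,
                    svtype=SVType.INV,
                    chrom=span_i[0], start=start, end=end,
                    breakends=[
                        Breakend(span_i[0], start, lo_be.ci_lo, lo_be.ci_hi,
                                 orientation=Orientation.LEFT_ANCHORED),
                        Breakend(span_i[0], end, hi_be.ci_lo, hi_be.ci_hi,
                                 orientation=Orientation.RIGHT_ANCHORED),
                    ],
                    filter_status=status,
                    genotype=members[0].genotype,
                    source_ids=ids,
                )
                inversions.append(inv)
                break
    for (kind, span, pair), flag in zip(candidates, used):
        if not flag:
            leftovers.extend(pair)
    for pair in other_pairs:
        leftovers.extend(pair)
    leftovers.sort(key=lambda c: (c.chrom, c.start, c.call_id))
    return inversions, leftovers


# ---------------------------------------------------------------------------
# SV / read-depth CNV reconciliation
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Reciprocal overlap of two 1-based closed intervals (min of the two
    overlap fractions)."""
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0] + 1), ov / (b[1] - b[0] + 1))


def _near_breakend(seg: CNVSegment, sv: SVCall, window: int) -> bool:
    for be in sv.breakends:
        if be.chrom != seg.chrom:
            continue
        dist = max(0, seg.start - be.pos, be.pos - seg.end)
        if dist <= window:
            return True
    return False


def _overlaps_span(seg: CNVSegment, sv: SVCall) -> bool:
    return (seg.chrom == sv.chrom and seg.start <= sv.end
            and seg.end >= sv.start)


def categorize_event(sv: SVCall, cnv_segments: Iterable[CNVSegment],
                     config: Optional[ReconcileConfig] = None
                     ) -> tuple[Category, Optional[bool]]:
    """Classify one SV against same-sample read-depth segments.

    Returns ``(category, rd_support)``.  ``rd_support`` is meaningful for
    simple CNVs only: True when a same-state RD segment matches the call by
    reciprocal overlap, False when the call has no RD counterpart at all
    (the "missed by read depth" case, typical of sub-exon deletions);
    None otherwise.
    """
    config = config or ReconcileConfig()
    segs = [s for s in cnv_segments if s.sample_id == sv.sample_id]
    window = config.adjacency_window_bp

    if sv.svtype in (SVType.DEL, SVType.DUP):
        want = CNState.LOSS if sv.svtype is SVType.DEL else CNState.GAIN
        span = (sv.start, sv.end)
        for seg in segs:
            if (seg.chrom == sv.chrom and seg.state is want
                    and reciprocal_overlap(span, (seg.start, seg.end))
                    >= config.cnv_match_reciprocal_overlap):
                return Category.SIMPLE_CNV, True
        for seg in segs:
            if _overlaps_span(seg, sv) or _near_breakend(seg, sv, window):
                return Category.COMPLEX_SV, None
        # no RD signal anywhere near: a plausibly-missed small CNV
        return Category.SIMPLE_CNV, False

    if sv.svtype is SVType.INV:
        for seg in segs:
            if _overlaps_span(seg, sv) or _near_breakend(seg, sv, window):
                return Category.COMPLEX_SV, None
        return Category.CN_NEUTRAL, None

    if sv.svtype is SVType.BND:
        for seg in segs:
            if _near_breakend(seg, sv, window):
                return Category.COMPLEX_SV, None
        return Category.CN_NEUTRAL, None

    # INS: a point event; RD adjacency implies complexity, else unclassifiable
    for seg in segs:
        if _near_breakend(seg, sv, window):
            return Category.COMPLEX_SV, None
    return Category.UNCLASSIFIED, None


# ---------------------------------------------------------------------------
# clear-cut evidence flag
# ---------------------------------------------------------------------------

@dataclass
class FamilyGenotype:
    """Carrier status of one relative; ``carries=None`` means not assessed."""

    meta: SampleMeta
    carries: Optional[bool]


@dataclass
class Evidence:
    """Externally supplied evidence flags for the clear-cut criteria."""

    rd_support: bool
    phenotype_match: bool
    visual_ok: bool


def clear_cut_flag(candidate: CandidateRecord,
                   family: Iterable[FamilyGenotype],
                   evidence: Evidence) -> bool:
    """Conjunction of the four clear-cut evidence criteria.

    (1) multi-signal support (read depth or equivalent), (2) phenotype
    match, (3) segregation consistent across all available relatives --
    every affected member carries the variant and, for the dominant/XL
    tier, no unaffected member does -- and (4) clean visual inspection.
    A relative whose genotype is missing fails criterion (3).
    """
    if not evidence.rd_support or not evidence.phenotype_match \
            or not evidence.visual_ok:
        return False
    for member in family:
        if member.carries is None:
            logger.info("clear-cut: genotype missing for %s; "
                        "segregation unconfirmed", member.meta.sample_id)
            return False
        if member.meta.affected and not member.carries:
            return False
        if (not member.meta.affected and member.carries
                and candidate.tier is Tier.DOMINANT_XL):
            return False
    return True
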