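"""Breakend algebra, inversion round trips, CNV reconciliation categories
and the clear-cut evidence flag."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exomesv.model import (
    Breakend,
    CNState,
    CNVSegment,
    CandidateRecord,
    Category,
    GeneModel,
    Genotype,
    Group,
    InheritanceMode,
    Orientation,
    SVCall,
    SVType,
    SampleMeta,
    Tier,
)
from exomesv.reconcile import (
    Evidence,
    FamilyGenotype,
    ReconcileConfig,
    categorize_event,
    clear_cut_flag,
    pair_bnd_to_inversion,
    reciprocal_overlap,
)
from exomesv.simulate import plant_inversion_as_bnd


def _gene_spanning(chrom, start, end):
    return GeneModel("G", chrom, "+", [(start, min(start + 199, end))],
                     panels={Group.ITHACA},
                     inheritance_modes={InheritanceMode.AD})


# ---------------------------------------------------------------------------
# inversion quartet round trips
# ---------------------------------------------------------------------------

def test_quartet_reconstructs_large_inversion():
    # a ~9.8 Mb inversion on chromosome 9, hg19-scale coordinates
    span = (130_887_682, 140_727_115)
    gene = _gene_spanning("9", 130_900_000, 140_000_000)
    quartet = plant_inversion_as_bnd(gene, span, "P1")
    assert len(quartet) == 4
    inversions, leftover = pair_bnd_to_inversion(quartet)
    assert leftover == []
    [inv] = inversions
    assert (inv.start, inv.end) == span
    assert inv.length_bp == 9_839_434


def test_quartet_reconstructs_180kb_inversion():
    span = (31_950_000, 32_129_999)     # ~180 kb
    gene = _gene_spanning("X", 32_000_000, 32_100_000)
    inversions, leftover = pair_bnd_to_inversion(
        plant_inversion_as_bnd(gene, span, "P2"))
    assert leftover == []
    assert [(i.start, i.end) for i in inversions] == [span]


@given(start=st.integers(2, 10**6), length=st.integers(2, 10**6))
def test_inversion_round_trip_property(start, length):
    span = (start, start + length - 1)
    gene = _gene_spanning("7", start, span[1])
    inversions, leftover = pair_bnd_to_inversion(
        plant_inversion_as_bnd(gene, span, "S"))
    assert leftover == []
    assert [(i.start, i.end) for i in inversions] == [span]


def test_minimal_span_round_trip():
    gene = _gene_spanning("1", 100, 101)
    [inv], _ = pair_bnd_to_inversion(
        plant_inversion_as_bnd(gene, (100, 101), "S"))
    assert (inv.start, inv.end) == (100, 101)


def test_degenerate_span_rejected():
    gene = _gene_spanning("1", 100, 300)
    with pytest.raises(ValueError, match="degenerate"):
        plant_inversion_as_bnd(gene, (200, 200), "S")
    with pytest.raises(ValueError, match="overlap"):
        plant_inversion_as_bnd(gene, (5000, 6000), "S")


def test_single_bnd_is_leftover():
    be = Breakend("1", 500, mate_chrom="1", mate_pos=900,
                  orientation=Orientation.LEFT_ANCHORED, mate_inverted=True)
    bnd = SVCall("b", "S", SVType.BND, "1", 500, 500, [be])
    inversions, leftover = pair_bnd_to_inversion([bnd])
    assert inversions == [] and leftover == [bnd]


def test_missing_mateid_is_leftover():
    be = Breakend("1", 500, mate_chrom="1", mate_pos=900,
                  orientation=Orientation.LEFT_ANCHORED, mate_inverted=True)
    bnd = SVCall("b", "S", SVType.BND, "1", 500, 500, [be],
                 mate_id="GHOST")
    inversions, leftover = pair_bnd_to_inversion([bnd])
    assert inversions == [] and leftover == [bnd]


def test_jittered_quartet_merges_within_tolerance():
    gene = _gene_spanning("2", 50_000, 90_000)
    quartet = plant_inversion_as_bnd(gene, (50_000, 90_000), "S")
    # shift the tail-to-tail pair by 30 bp (< default 50 bp tolerance)
    for call in quartet[2:]:
        call.start += 30
        call.end += 30
        be = call.breakends[0]
        be.pos += 30
        be.mate_pos += 30
    inversions, leftover = pair_bnd_to_inversion(quartet)
    assert len(inversions) == 1 and leftover == []
    inv = inversions[0]
    assert abs(inv.start - 50_000) <= 30 and abs(inv.end - 90_030) <= 30


def test_half_quartet_stays_bnd():
    gene = _gene_spanning("2", 50_000, 90_000)
    quartet = plant_inversion_as_bnd(gene, (50_000, 90_000), "S")
    inversions, leftover = pair_bnd_to_inversion(quartet[:2])
    assert inversions == [] and len(leftover) == 2


# ---------------------------------------------------------------------------
# SV / CNV reconciliation
# ---------------------------------------------------------------------------

def _sv(svtype, start, end, sample="S"):
    return SVCall("c", sample, svtype, "1", start, end)


def test_reciprocal_overlap_values():
    assert reciprocal_overlap((1, 100), (1, 100)) == 1.0
    assert reciprocal_overlap((1, 100), (51, 150)) == 0.5
    assert reciprocal_overlap((1, 100), (200, 300)) == 0.0


def test_del_with_exact_rd_match_is_simple():
    sv = _sv(SVType.DEL, 1000, 2000)
    segs = [CNVSegment("S", "1", 1000, 2000, CNState.LOSS, "clincnv")]
    assert categorize_event(sv, segs) == (Category.SIMPLE_CNV, True)


def test_del_wrong_state_nearby_is_complex():
    sv = _sv(SVType.DUP, 1000, 2000)
    segs = [CNVSegment("S", "1", 2300, 9000, CNState.LOSS, "clincnv")]
    assert categorize_event(sv, segs) == (Category.COMPLEX_SV, None)


def test_del_without_rd_is_simple_unsupported():
    sv = _sv(SVType.DEL, 1000, 2000)
    assert categorize_event(sv, []) == (Category.SIMPLE_CNV, False)
    # segments of another sample never count
    other = [CNVSegment("T", "1", 1000, 2000, CNState.LOSS, "x")]
    assert categorize_event(sv, other) == (Category.SIMPLE_CNV, False)


def test_inversion_categories():
    inv = _sv(SVType.INV, 10_000, 60_000)
    assert categorize_event(inv, []) == (Category.CN_NEUTRAL, None)
    near = [CNVSegment("S", "1", 60_500, 70_000, CNState.GAIN, "x")]
    assert categorize_event(inv, near) == (Category.COMPLEX_SV, None)


def test_ins_unclassified_without_rd():
    ins = _sv(SVType.INS, 5000, 5000)
    assert categorize_event(ins, [])[0] is Category.UNCLASSIFIED


@given(svtype=st.sampled_from(list(SVType)),
       start=st.integers(1000, 50_000), length=st.integers(0, 20_000),
       segs=st.lists(
           st.tuples(st.integers(1, 80_000), st.integers(1, 30_000),
                     st.sampled_from(list(CNState))), max_size=4))
def test_categorize_total_function(svtype, start, length, segs):
    """Every input gets exactly one category from the enum."""
    end = start + length if svtype in (SVType.DEL, SVType.DUP,
                                       SVType.INV) else start
    if svtype is SVType.BND:
        be = Breakend("1", start, mate_chrom="2", mate_pos=10,
                      orientation=Orientation.LEFT_ANCHORED)
        sv = SVCall("c", "S", svtype, "1", start, start, [be])
    else:
        sv = SVCall("c", "S", svtype, "1", start, end)
    segments = [CNVSegment("S", "1", s, s + l, st_, "x")
                for s, l, st_ in segs]
    cat, rd = categorize_event(sv, segments)
    assert cat in Category
    if rd is not None:
        assert cat is Category.SIMPLE_CNV


# ---------------------------------------------------------------------------
# clear-cut flag
# ---------------------------------------------------------------------------

def _trio(carries_p, carries_f, carries_m):
    return [
        FamilyGenotype(SampleMeta("P", "F1", True, Group.RND), carries_p),
        FamilyGenotype(SampleMeta("F", "F1", False, Group.RND), carries_f),
        FamilyGenotype(SampleMeta("M", "F1", False, Group.RND), carries_m),
    ]


def _dominant_candidate():
    return CandidateRecord(sv=_sv(SVType.DEL, 1000, 2000, "P"),
                           cohort_count=1, cohort_fraction_pct=0.01,
                           genes_hit=["G"], tier=Tier.DOMINANT_XL)


def test_clear_cut_de_novo_trio():
    ev = Evidence(rd_support=True, phenotype_match=True, visual_ok=True)
    assert clear_cut_flag(_dominant_candidate(), _trio(True, False, False),
                          ev)


def test_clear_cut_fails_on_carrier_parent():
    ev = Evidence(rd_support=True, phenotype_match=True, visual_ok=True)
    assert not clear_cut_flag(_dominant_candidate(),
                              _trio(True, True, False), ev)


def test_clear_cut_fails_without_visual():
    ev = Evidence(rd_support=True, phenotype_match=True, visual_ok=False)
    assert not clear_cut_flag(_dominant_candidate(),
                              _trio(True, False, False), ev)


def test_clear_cut_fails_on_missing_genotype():
    ev = Evidence(rd_support=True, phenotype_match=True, visual_ok=True)
    assert not clear_cut_flag(_dominant_candidate(),
                              _trio(True, None, False), ev)


def test_recessive_candidate_tolerates_carrier_parent():
    ev = Evidence(rd_support=True, phenotype_match=True, visual_ok=True)
    rec = _dominant_candidate()
    rec.tier = Tier.RECESSIVE_BIALLELIC
    assert clear_cut_flag(rec, _trio(True, True, False), ev)


def test_reconcile_config_validation():
    with pytest.raises(ValueError):
        ReconcileConfig(cnv_match_reciprocal_overlap=0.0)
    with pytest.raises(ValueError):
        ReconcileConfig(bnd_pair_tolerance_bp=-1)
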