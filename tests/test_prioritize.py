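"""Filter cascade: boundary exactness, subset/commutation properties,
gene overlap, tiering and compound-het pairing."""
from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from exomesv.cohort_af import build_cohort_index
from exomesv.model import (
    Breakend,
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
    Tier,
    VariantCategory,
)
from exomesv.prioritize import (
    GeneIndex,
    PrioritizationConfig,
    annotate_gene_overlap,
    filter_gene_panel,
    filter_pass,
    filter_rare,
    find_compound_het,
    run_prioritization,
    sample_chromosome_qc,
    tier_dominant_xl,
)


def _del(sample, call_id, chrom, start, end, filt="PASS", gt=Genotype.HET):
    return SVCall(call_id, sample, SVType.DEL, chrom, start, end,
                  filter_status=filt, genotype=gt)


def _shared_index(n_sharing, pos=10_000, extra_samples=0):
    """An index where one breakpoint is shared by ``n_sharing`` datasets."""
    callsets = {f"S{i}": [_del(f"S{i}", "d", "1", pos, pos + 500)]
                for i in range(n_sharing)}
    for j in range(extra_samples):
        callsets[f"X{j}"] = [_del(f"X{j}", "d", "2", 99_000 + 50 * j,
                                  99_600 + 50 * j)]
    return callsets, build_cohort_index(callsets)


# ---------------------------------------------------------------------------
# PASS and rarity filters
# ---------------------------------------------------------------------------

def test_filter_pass_keeps_order():
    calls = [_del("S", "a", "1", 1, 2, "PASS"),
             _del("S", "b", "1", 3, 4, "MinGQ"),
             _del("S", "c", "1", 5, 6, "PASS")]
    assert [c.call_id for c in filter_pass(calls)] == ["a", "c"]
    assert filter_pass(calls[:1]) == calls[:1]


@given(st.lists(st.sampled_from(["PASS", "MinGQ", "Ploidy"]), max_size=12))
def test_filter_pass_subset_property(labels):
    calls = [_del("S", f"c{i}", "1", 10 * i + 1, 10 * i + 2, lab)
             for i, lab in enumerate(labels)]
    out = filter_pass(calls)
    assert set(c.call_id for c in out) <= set(c.call_id for c in calls)
    assert all(c.is_pass for c in out)


@pytest.mark.parametrize("n_sharing,kept", [(20, True), (21, False),
                                            (1, True)])
def test_rarity_threshold_boundary(n_sharing, kept):
    callsets, idx = _shared_index(n_sharing)
    focal = callsets["S0"]
    out = filter_rare(focal, idx)
    assert (len(out) == 1) == kept
    assert focal[0].cohort_count == n_sharing


def test_pass_and_rare_commute():
    callsets, idx = _shared_index(21)
    mixed = [_del("S0", "p1", "1", 10_000, 10_500),          # frequent
             _del("S0", "p2", "1", 50_000, 50_500),          # rare PASS
             _del("S0", "p3", "1", 60_000, 60_500, "MinGQ")]  # rare non-PASS
    a = filter_rare(filter_pass(mixed), idx)
    b = filter_pass(filter_rare(mixed, idx))
    assert [c.call_id for c in a] == [c.call_id for c in b] == ["p2"]


def test_record_filters_idempotent():
    callsets, idx = _shared_index(5)
    calls = [_del("S0", "a", "1", 10_000, 10_500),
             _del("S0", "b", "2", 1000, 1500, "MinGQ")]
    once = filter_rare(filter_pass(calls), idx)
    twice = filter_rare(filter_pass(once), idx)
    assert twice == once


# ---------------------------------------------------------------------------
# gene overlap and panel filtering
# ---------------------------------------------------------------------------

def test_exon_pad_boundary(toy_gene):
    # exon starts at 1000; a deletion ending 5 bp before it is a hit,
    # 6 bp before is not
    hit = _del("S", "h", "1", 900, 995)
    miss = _del("S", "m", "1", 900, 994)
    assert annotate_gene_overlap(hit, [toy_gene]) == ["TOY1"]
    assert annotate_gene_overlap(miss, [toy_gene]) == []


def test_intronic_span_no_hit(toy_gene):
    intronic = _del("S", "i", "1", 1300, 4900)
    assert annotate_gene_overlap(intronic, [toy_gene]) == []


def test_large_inversion_hits_via_span(toy_gene):
    # breakends deep in flanking/intronic sequence, span covers exons
    inv = SVCall("v", "S", SVType.INV, "1", 200, 9_500)
    assert annotate_gene_overlap(inv, [toy_gene]) == ["TOY1"]


def test_bnd_uses_ci_and_pad(toy_gene):
    # breakend at 960, CI reaching +35 -> padded window touches exon@1000
    be = Breakend("1", 960, -10, 35, mate_chrom="2", mate_pos=5,
                  orientation=Orientation.LEFT_ANCHORED)
    bnd = SVCall("b", "S", SVType.BND, "1", 960, 960, [be])
    assert annotate_gene_overlap(bnd, [toy_gene]) == ["TOY1"]
    be2 = Breakend("1", 960, -10, 30, mate_chrom="2", mate_pos=5)
    bnd2 = SVCall("b2", "S", SVType.BND, "1", 960, 960, [be2])
    assert annotate_gene_overlap(bnd2, [toy_gene]) == []


TOY_EXONS = [(1000, 1199), (5000, 5299), (9000, 9399)]


def _toy_gene_model():
    return GeneModel("TOY1", "1", "+", list(TOY_EXONS), {Group.NMD},
                     {InheritanceMode.AD})


@given(spans=st.lists(st.tuples(st.integers(1, 12_000),
                                st.integers(0, 2000)),
                      min_size=1, max_size=20),
       pad=st.integers(0, 10))
def test_gene_overlap_matches_brute_force(spans, pad):
    config = PrioritizationConfig(exon_pad_bp=pad)
    gi = GeneIndex([_toy_gene_model()])
    for i, (start, length) in enumerate(spans):
        sv = _del("S", f"c{i}", "1", start, start + length)
        expect = any(start <= e + pad and start + length >= s - pad
                     for s, e in TOY_EXONS)
        got = annotate_gene_overlap(sv, gi, config) == ["TOY1"]
        assert got == expect


def test_panel_filter(toy_gene):
    off_panel = GeneModel("OFF1", "1", "+", [(20_000, 20_199)],
                          panels={Group.RND},
                          inheritance_modes={InheritanceMode.AD})
    genes = [toy_gene, off_panel]
    in_panel = _del("S", "a", "1", 1000, 1100)
    off = _del("S", "b", "1", 20_000, 20_100)
    nowhere = _del("S", "c", "1", 400_000, 400_100)
    kept = filter_gene_panel([in_panel, off, nowhere], genes, Group.NMD)
    assert [c.call_id for c in kept] == ["a"]
    assert in_panel.genes_hit == ["TOY1"]
    with pytest.raises(ValueError):
        filter_gene_panel([], genes, Group.OTHER)


# ---------------------------------------------------------------------------
# sample chromosome QC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_chroms,dropped", [(5, False), (6, True)])
def test_chromosome_qc_boundary(n_chroms, dropped):
    calls = [_del("S", f"c{i}", f"chr{i}", 100, 200)
             for i in range(n_chroms)]
    kept, drop = sample_chromosome_qc({"S": calls})
    assert ("S" in drop) == dropped
    assert ("S" in kept) != dropped


def test_chromosome_qc_many_on_one_chrom():
    calls = [_del("S", f"c{i}", "1", 100 * i + 1, 100 * i + 50)
             for i in range(10)]
    kept, drop = sample_chromosome_qc({"S": calls})
    assert "S" in kept and not drop


# ---------------------------------------------------------------------------
# tiering and compound heterozygotes
# ---------------------------------------------------------------------------

def _candidate(sv, count, genes_hit):
    return CandidateRecord(sv=sv, cohort_count=count,
                           cohort_fraction_pct=0.1, genes_hit=genes_hit)


@pytest.mark.parametrize("count,expected", [(3, Tier.DOMINANT_XL),
                                            (4, Tier.OTHER)])
def test_dominant_tier_count_boundary(toy_gene, count, expected):
    rec = _candidate(_del("S", "a", "1", 1000, 1100), count, ["TOY1"])
    tier_dominant_xl([rec], [toy_gene])
    assert rec.tier is expected


def test_ar_only_gene_not_dominant():
    ar_gene = GeneModel("ARG1", "1", "+", [(1000, 1199)],
                        panels={Group.NMD},
                        inheritance_modes={InheritanceMode.AR})
    rec = _candidate(_del("S", "a", "1", 1000, 1100), 1, ["ARG1"])
    tier_dominant_xl([rec], [ar_gene])
    assert rec.tier is Tier.OTHER


def test_xlr_gene_in_dominant_tier():
    xlr = GeneModel("XG1", "X", "+", [(1000, 1199)], panels={Group.RND},
                    inheritance_modes={InheritanceMode.XLR})
    rec = _candidate(_del("S", "a", "X", 1000, 1100), 2, ["XG1"])
    tier_dominant_xl([rec], [xlr])
    assert rec.tier is Tier.DOMINANT_XL


def _ar_gene():
    return GeneModel("ARG1", "1", "+", [(1000, 1199), (5000, 5199)],
                     panels={Group.NMD},
                     inheritance_modes={InheritanceMode.AR})


def test_compound_het_pairing():
    gene = _ar_gene()
    rec = _candidate(_del("S1", "a", "1", 900, 1300), 1, ["ARG1"])
    short_same = ShortVariant("S1", "1", 5050, "ARG1",
                              VariantCategory.PATHOGENIC_MISSENSE,
                              Genotype.HET)
    short_other_sample = ShortVariant("S2", "1", 5050, "ARG1",
                                      VariantCategory.PATHOGENIC_MISSENSE,
                                      Genotype.HET)
    short_hom = ShortVariant("S1", "1", 5060, "ARG1",
                             VariantCategory.HIGH_IMPACT, Genotype.HOM)
    pairs = find_compound_het([rec], [short_other_sample, short_hom,
                                      short_same], [gene])
    assert len(pairs) == 1
    assert pairs[0][1] is short_same
    assert rec.tier is Tier.RECESSIVE_BIALLELIC


def test_compound_het_requires_het_sv():
    gene = _ar_gene()
    rec = _candidate(_del("S1", "a", "1", 900, 1300, gt=Genotype.HOM), 1,
                     ["ARG1"])
    short = ShortVariant("S1", "1", 5050, "ARG1",
                         VariantCategory.HIGH_IMPACT, Genotype.HET)
    assert find_compound_het([rec], [short], [gene]) == []


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def test_run_prioritization_sample_mismatch(toy_gene):
    samples = [SampleMeta("A", "F1", True, Group.NMD)]
    callsets = {"B": []}
    with pytest.raises(ValueError, match="disagree"):
        run_prioritization(callsets, samples, [toy_gene])


def test_run_prioritization_empty_cohort(toy_gene):
    result = run_prioritization({}, [], [toy_gene])
    assert all(not recs for recs in result.tables.values())
    assert (result.cascade_log["n_out"] == 0).all()


def test_causal_events_land_in_exactly_one_group_table(default_bundle,
                                                       default_result):
    truth_causal = [t for t in default_bundle.truth
                    if t.event_class == "causal"]
    group_of_sample = {s.sample_id: s.group
                       for s in default_bundle.samples}
    for t in truth_causal:
        hits = [g for g, recs in default_result.tables.items()
                if any(r.sv.sample_id in t.sample_ids
                       and r.sv.chrom == t.chrom
                       and t.gene in r.genes_hit for r in recs)]
        assert hits == [group_of_sample[t.sample_ids[0]]]


def test_cascade_is_monotone(default_result):
    log = default_result.cascade_log
    assert (log["n_out"] <= log["n_in"]).all()


def test_noisy_sample_dropped_by_qc(default_bundle):
    """Injecting a sample with panel candidates on many chromosomes drops
    it from the tables but records it in the drop log."""
    genes = default_bundle.genes
    samples = list(default_bundle.samples)
    callsets = {s: list(c) for s, c in default_bundle.callsets.items()}
    noisy = "NOISY_P"
    samples.append(SampleMeta(noisy, "FAMNOISY", True, Group.NMD))
    # one unique call per chromosome, on NMD-panel genes spread over 8
    # artificial chromosomes
    extra_genes = []
    calls = []
    for i in range(8):
        chrom = f"c{i}"
        g = GeneModel(f"NG{i}", chrom, "+", [(1000, 1199)],
                      panels={Group.NMD},
                      inheritance_modes={InheritanceMode.AD})
        extra_genes.append(g)
        calls.append(_del(noisy, f"n{i}", chrom, 1000, 1100))
    callsets[noisy] = calls
    result = run_prioritization(callsets, samples,
                                list(genes) + extra_genes)
    assert noisy in result.dropped_samples
    assert all(r.sv.sample_id != noisy
               for recs in result.tables.values() for r in recs)
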