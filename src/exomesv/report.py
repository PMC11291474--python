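"""Clinician-facing outputs: candidate report tables, IGV batch scripts
and per-group summary tables.

The candidate report carries, per SV and carrier: breakpoint coordinates,
cohort allele frequency, affected status, HPO terms and ORDO code of the
index case, genes potentially affected, and the other samples showing the
same SV -- plus the cohort count, review tier and reconciliation category.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .model import (
    PANEL_GROUPS,
    CandidateRecord,
    GeneModel,
    Group,
    SVType,
    SampleMeta,
)

PathLike = Union[str, Path]

REPORT_COLUMNS = [
    "group", "sample_id", "affected", "chrom", "start", "end", "svtype",
    "length_bp", "genes", "cohort_count", "cohort_af_pct", "tier",
    "category", "rd_support", "sharing_samples", "hpo_terms", "ordo",
]


def build_candidate_report(tables: Mapping[Group,
                                           Sequence[CandidateRecord]],
                           samples: Sequence[SampleMeta]) -> pd.DataFrame:
    """One deterministic row per (candidate, carrier), ordered by
    (group, sample, chrom, start)."""
    meta = {s.sample_id: s for s in samples}
    rows = []
    for group in PANEL_GROUPS:
        recs = sorted(tables.get(group, []),
                      key=lambda r: (r.sv.sample_id, r.sv.chrom, r.sv.start,
                                     r.sv.call_id))
        for rec in recs:
            s = meta.get(rec.sv.sample_id)
            rows.append({
                "group": group.value,
                "sample_id": rec.sv.sample_id,
                "affected": int(s.affected) if s else "",
                "chrom": rec.sv.chrom,
                "start": rec.sv.start,
                "end": rec.sv.end,
                "svtype": rec.sv.svtype.value,
                "length_bp": rec.sv.length_bp,
                "genes": ";".join(rec.genes_hit),
                "cohort_count": rec.cohort_count,
                "cohort_af_pct": f"{rec.cohort_fraction_pct:.2f}",
                "tier": rec.tier.value,
                "category": rec.category.value,
                "rd_support": "" if rec.rd_support is None
                              else int(rec.rd_support),
                "sharing_samples": ";".join(rec.sharing_samples),
                "hpo_terms": ";".join(s.hpo_terms) if s else "",
                "ordo": (s.ordo_code or "") if s else "",
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_candidate_report(report: pd.DataFrame, path: PathLike) -> Path:
    report.to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# IGV batch scripts
# ---------------------------------------------------------------------------

def igv_batch_script(candidate: CandidateRecord, bam_path: str,
                     out_dir: str, flank_bp: int = 500,
                     genome: str = "hg19") -> str:
    """IGV batch script snapshotting the left breakpoint, the right
    breakpoint, and the complete SV.

    The full-span view is padded on each side by 10% of the SV length, or
    by ``flank_bp`` if that is larger.  For a BND whose mate lies on
    another chromosome (or is unknown) only the resolvable views are
    emitted, with a comment noting the omission.
    """
    sv = candidate.sv
    gene = candidate.genes_hit[0] if candidate.genes_hit else "NA"
    base = f"{sv.sample_id}_{gene}_{sv.svtype.value}_{sv.chrom}_" \
           f"{sv.start}_{sv.end}"

    def view(chrom: str, lo: int, hi: int, tag: str) -> list[str]:
        return [f"goto {chrom}:{max(1, lo)}-{hi}",
                f"snapshot {base}_{tag}.png"]

    lines = ["new", f"genome {genome}", f"load {bam_path}",
             f"snapshotDirectory {out_dir}"]
    if sv.svtype is SVType.BND:
        be = sv.breakends[0]
        lines += view(sv.chrom, sv.start - flank_bp, sv.start + flank_bp,
                      "left")
        if be.mate_chrom is None or be.mate_pos is None:
            lines.append("# mate breakend unavailable; right and full "
                         "views omitted")
        elif be.mate_chrom != sv.chrom:
            lines += view(be.mate_chrom, be.mate_pos - flank_bp,
                          be.mate_pos + flank_bp, "right")
            lines.append("# inter-chromosomal junction; full view omitted")
        else:
            lo, hi = sorted((sv.start, be.mate_pos))
            lines += view(sv.chrom, be.mate_pos - flank_bp,
                          be.mate_pos + flank_bp, "right")
            pad = max(flank_bp, (hi - lo + 1) // 10)
            lines += view(sv.chrom, lo - pad, hi + pad, "full")
    else:
        lines += view(sv.chrom, sv.start - flank_bp, sv.start + flank_bp,
                      "left")
        lines += view(sv.chrom, sv.end - flank_bp, sv.end + flank_bp,
                      "right")
        pad = max(flank_bp, sv.length_bp // 10)
        lines += view(sv.chrom, sv.start - pad, sv.end + pad, "full")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# per-group summary (cohort-description arithmetic)
# ---------------------------------------------------------------------------

def pct_round_sig2(numerator: int, denominator: int) -> float:
    """Percentage rounded to two significant figures (0 if undefined)."""
    if denominator == 0 or numerator == 0:
        return 0.0
    pct = 100.0 * numerator / denominator
    digits = 1 - int(math.floor(math.log10(abs(pct))))
    return round(pct, digits)


def pct_trunc2(numerator: int, denominator: int) -> float:
    """Percentage truncated (not rounded) to two decimals, 0 if undefined."""
    if denominator == 0:
        return 0.0
    pct = 100.0 * numerator / denominator
    return math.floor(pct * 100 + 1e-9) / 100


SUMMARY_COLUMNS = [
    "group", "n_affected", "n_index", "n_panel_genes", "n_candidates",
    "n_samples_with_sv", "n_solved_index", "n_solved_affected",
    "pct_solved_index", "pct_causal_of_investigated",
]


def summarize_by_group(tables: Mapping[Group, Sequence[CandidateRecord]],
                       samples: Sequence[SampleMeta],
                       curation_labels: Mapping[tuple[str, str], str],
                       genes: Optional[Sequence[GeneModel]] = None
                       ) -> pd.DataFrame:
    """Per-group cohort summary with self-consistent percentage columns.

    ``curation_labels`` maps ``(sample_id, call_id)`` to ``"causal"`` or
    ``"not_causal"`` (expert review on real data, the truth table on
    synthetic runs).  Percentages are recomputed from the integer columns
    of the same row: the solved-index fraction to two significant figures,
    the causal-of-investigated fraction to two decimals.
    """
    rows = []
    for group in PANEL_GROUPS:
        members = [s for s in samples if s.group is group]
        affected = [s for s in members if s.affected]
        n_index = len({s.family_id for s in affected})
        recs = list(tables.get(group, []))
        causal = [r for r in recs
                  if curation_labels.get((r.sv.sample_id, r.sv.call_id))
                  == "causal"]
        meta = {s.sample_id: s for s in members}
        solved_samples = {r.sv.sample_id for r in causal}
        solved_families = {meta[sid].family_id for sid in solved_samples
                           if sid in meta}
        n_panel_genes = sum(1 for g in genes or []
                            if group in g.panels)
        row = {
            "group": group.value,
            "n_affected": len(affected),
            "n_index": n_index,
            "n_panel_genes": n_panel_genes,
            "n_candidates": len(recs),
            "n_samples_with_sv": len({r.sv.sample_id for r in recs}),
            "n_solved_index": len(solved_families),
            "n_solved_affected": len(solved_samples),
        }
        row["pct_solved_index"] = pct_round_sig2(row["n_solved_index"],
                                                 row["n_index"])
        row["pct_causal_of_investigated"] = pct_trunc2(
            row["n_solved_affected"], row["n_candidates"])
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
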