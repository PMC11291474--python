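"""Readers and writers for every external format the pipeline touches.

Formats
-------
* SV VCF (Manta-style dialect): symbolic ``<DEL>/<DUP>/<INS>/<INV>`` ALTs plus
  bracketed BND breakend notation, with ``SVTYPE``, ``END``, ``SVLEN``,
  ``CIPOS``, ``CIEND`` and ``MATEID`` INFO keys.  Parsed through :mod:`pysam`.
* Gene panel TSV with BED-style (0-based half-open) exon coordinates.
* Sample sheet TSV (family structure, affected status, ERN, HPO/ORDO).
* CNV segment and short-variant TSVs (1-based closed coordinates).

Internally everything is 1-based closed; BED half-open ``[a, b)`` maps to
``[a+1, b]`` at the boundary.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .model import (
    Breakend,
    CNState,
    CNVSegment,
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

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class SVParseError(ValueError):
    """A record-level error while parsing an SV VCF."""


# ---------------------------------------------------------------------------
# chromosome-name normalization
# ---------------------------------------------------------------------------

def normalize_chrom(name: str,
                    table: Optional[Mapping[str, str]] = None) -> str:
    """Normalize a chromosome name through an explicit mapping table.

    With ``table=None`` names are compared as exact strings (GRCh37 hs37d5
    style, un-prefixed).  Pass e.g. ``strip_chr_table()`` to fold ``chr1``
    onto ``1``.
    """
    if table is None:
        return name
    return table.get(name, name)


def strip_chr_table() -> dict[str, str]:
    """A normalization table mapping UCSC-style ``chrN`` names to plain ``N``."""
    names = [str(i) for i in range(1, 23)] + ["X", "Y", "MT"]
    table = {f"chr{n}": n for n in names}
    table["chrM"] = "MT"
    return table


# ---------------------------------------------------------------------------
# VCF breakend (BND) ALT algebra
# ---------------------------------------------------------------------------

_BND_ALT_RE = re.compile(
    r"^(?P<t1>[ACGTNacgtn.]*)"
    r"(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>[0-9]+)(?P<b2>[\[\]])"
    r"(?P<t2>[ACGTNacgtn.]*)$"
)


def parse_breakend_alt(alt: str) -> tuple[str, int, Orientation, bool]:
    """Decompose a bracketed breakend ALT into mate and junction geometry.

    Returns ``(mate_chrom, mate_pos, orientation, mate_inverted)``.  The four
    bracket forms map as:

    ========  =====================  ==============
    ALT form  orientation            mate_inverted
    ========  =====================  ==============
    ``t[p[``  left_anchored          False
    ``t]p]``  left_anchored          True
    ``]p]t``  right_anchored         False
    ``[p[t``  right_anchored         True
    ========  =====================  ==============
    """
    m = _BND_ALT_RE.match(alt)
    if m is None or m.group("b1") != m.group("b2"):
        raise SVParseError(f"malformed breakend ALT {alt!r}")
    t1, t2 = m.group("t1"), m.group("t2")
    if bool(t1) == bool(t2):
        raise SVParseError(
            f"malformed breakend ALT {alt!r}: expected bases on exactly one "
            "side of the brackets"
        )
    bracket = m.group("b1")
    if t1:
        orientation = Orientation.LEFT_ANCHORED
        mate_inverted = bracket == "]"
    else:
        orientation = Orientation.RIGHT_ANCHORED
        mate_inverted = bracket == "["
    return m.group("chrom"), int(m.group("pos")), orientation, mate_inverted


def format_breakend_alt(ref_base: str, mate_chrom: str, mate_pos: int,
                        orientation: Orientation,
                        mate_inverted: bool) -> str:
    """Inverse of :func:`parse_breakend_alt`."""
    p = f"{mate_chrom}:{mate_pos}"
    if orientation is Orientation.LEFT_ANCHORED:
        return f"{ref_base}]{p}]" if mate_inverted else f"{ref_base}[{p}["
    return f"[{p}[{ref_base}" if mate_inverted else f"]{p}]{ref_base}"


# ---------------------------------------------------------------------------
# SV VCF reading / writing
# ---------------------------------------------------------------------------

def _genotype_from_gt(gt: Optional[tuple]) -> Genotype:
    if not gt or any(a is None for a in gt):
        return Genotype.UNKNOWN
    alleles = set(gt)
    if alleles == {0, 1}:
        return Genotype.HET
    if alleles == {1}:
        return Genotype.HOM
    return Genotype.UNKNOWN


def _scalar(value):
    if isinstance(value, tuple):
        return value[0]
    return value


def read_sv_vcf(path: PathLike, sample_id: Optional[str] = None,
                chrom_table: Optional[Mapping[str, str]] = None
                ) -> list[SVCall]:
    """Read one sample's SV callset from a Manta-style VCF.

    ``sample_id`` overrides the VCF sample column name (useful when file
    naming, not header content, carries the dataset identity).  Records with
    an unknown SVTYPE are skipped with a logged warning count; a malformed
    breakend ALT raises :class:`SVParseError` naming the record.
    """
    path = Path(path)
    calls: list[SVCall] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        if sample_id is None:
            sample_id = header_samples[0] if header_samples else path.stem
        for idx, rec in enumerate(vcf, start=1):
            svtype_raw = _scalar(rec.info.get("SVTYPE"))
            try:
                svtype = SVType(svtype_raw)
            except ValueError:
                skipped += 1
                continue
            chrom = normalize_chrom(rec.chrom, chrom_table)
            filters = list(rec.filter.keys())
            filter_status = "PASS" if not filters else ";".join(filters)
            genotype = Genotype.UNKNOWN
            if header_samples:
                genotype = _genotype_from_gt(
                    rec.samples[header_samples[0]].get("GT"))
            cipos = tuple(rec.info.get("CIPOS", (0, 0)))
            ciend = tuple(rec.info.get("CIEND", (0, 0)))
            call_id = rec.id or f"{path.stem}_{idx}"
            if svtype is SVType.BND:
                alt = rec.alts[0] if rec.alts else ""
                try:
                    mate_chrom, mate_pos, orientation, inverted = \
                        parse_breakend_alt(alt)
                except SVParseError as exc:
                    raise SVParseError(
                        f"{path.name}: record {idx} at {rec.chrom}:{rec.pos}: "
                        f"{exc}"
                    ) from None
                be = Breakend(chrom, rec.pos, cipos[0], cipos[1],
                              orientation=orientation,
                              mate_chrom=normalize_chrom(mate_chrom,
                                                         chrom_table),
                              mate_pos=mate_pos,
                              mate_inverted=inverted)
                mate_id = rec.info.get("MATEID")
                calls.append(SVCall(call_id, sample_id, svtype, chrom,
                                    rec.pos, rec.pos, [be],
                                    filter_status=filter_status,
                                    genotype=genotype,
                                    mate_id=_scalar(mate_id)))
            else:
                end = rec.stop if svtype in (SVType.DEL, SVType.DUP,
                                             SVType.INV) else rec.pos
                breakends = [Breakend(chrom, rec.pos, cipos[0], cipos[1],
                                      orientation=Orientation.LEFT_ANCHORED)]
                if svtype in (SVType.DEL, SVType.DUP, SVType.INV):
                    breakends.append(
                        Breakend(chrom, end, ciend[0], ciend[1],
                                 orientation=Orientation.RIGHT_ANCHORED))
                length = None
                if svtype is SVType.INS:
                    svlen = _scalar(rec.info.get("SVLEN"))
                    length = abs(int(svlen)) if svlen is not None else 0
                calls.append(SVCall(call_id, sample_id, svtype, chrom,
                                    rec.pos, end, breakends,
                                    filter_status=filter_status,
                                    genotype=genotype,
                                    length_bp=length))
    if skipped:
        logger.warning("%s: skipped %d record(s) with unknown SVTYPE",
                       path.name, skipped)
    return calls


def _contig_sort_key(name: str) -> tuple:
    return (0, int(name)) if name.isdigit() else (1, name)


def _build_sv_header(calls: Sequence[SVCall], sample_id: str,
                     contigs: Optional[Mapping[str, int]]
                     ) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                    'Description="Type of structural variant">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,'
                    'Description="End position of the variant">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,'
                    'Description="Length of the variant">')
    header.add_line('##INFO=<ID=CIPOS,Number=2,Type=Integer,'
                    'Description="Confidence interval around POS">')
    header.add_line('##INFO=<ID=CIEND,Number=2,Type=Integer,'
                    'Description="Confidence interval around END">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,'
                    'Description="ID of mate breakend">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    if contigs is None:
        contigs = {}
        for call in calls:
            for be in call.breakends:
                contigs[be.chrom] = max(contigs.get(be.chrom, 0),
                                        be.pos + 1_000_000)
                if be.mate_chrom is not None:
                    contigs[be.mate_chrom] = max(
                        contigs.get(be.mate_chrom, 0),
                        be.mate_pos + 1_000_000)
            contigs[call.chrom] = max(contigs.get(call.chrom, 0),
                                      call.end + 1_000_000)
    for name in sorted(contigs, key=_contig_sort_key):
        header.contigs.add(name, length=contigs[name])
    for label in sorted({c.filter_status for c in calls
                         if c.filter_status != "PASS"}):
        for part in label.split(";"):
            if part not in header.filters:
                header.filters.add(part, None, None, "Non-PASS caller filter")
    header.add_sample(sample_id)
    return header


def write_sv_vcf(calls: Sequence[SVCall], path: PathLike,
                 sample_id: Optional[str] = None,
                 contigs: Optional[Mapping[str, int]] = None) -> Path:
    """Write one sample's callset as an uncompressed VCF.

    Round-trips with :func:`read_sv_vcf` on (svtype, chrom, start, end,
    confidence intervals, filter status, genotype).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = calls[0].sample_id if calls else "SAMPLE"
    header = _build_sv_header(calls, sample_id, contigs)
    order = {name: i for i, name in enumerate(header.contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (order.get(c.chrom, 1 << 30),
                                                 c.start, c.call_id)):
            if call.svtype is SVType.BND:
                be = call.breakends[0]
                alt = format_breakend_alt("N", be.mate_chrom, be.mate_pos,
                                          be.orientation, be.mate_inverted)
            else:
                alt = f"<{call.svtype.value}>"
            rec = out.new_record(contig=call.chrom, start=call.start - 1,
                                 stop=call.end, alleles=("N", alt),
                                 id=call.call_id)
            rec.info["SVTYPE"] = call.svtype.value
            # SVLEN is written for INS only: htslib >= 1.18 derives the
            # record span from SVLEN for symbolic alleles (VCF 4.4
            # semantics), which would fight the explicit END of spanned
            # types whose length differs from end - start.
            if call.svtype is SVType.INS and call.length_bp:
                rec.info["SVLEN"] = call.length_bp
            be0 = call.breakends[0]
            if (be0.ci_lo, be0.ci_hi) != (0, 0):
                rec.info["CIPOS"] = (be0.ci_lo, be0.ci_hi)
            if len(call.breakends) > 1:
                be1 = call.breakends[1]
                if (be1.ci_lo, be1.ci_hi) != (0, 0):
                    rec.info["CIEND"] = (be1.ci_lo, be1.ci_hi)
            if call.mate_id is not None:
                rec.info["MATEID"] = call.mate_id
            rec.stop = call.end
            if call.filter_status == "PASS":
                rec.filter.add("PASS")
            else:
                for part in call.filter_status.split(";"):
                    rec.filter.add(part)
            gt = {Genotype.HET: (0, 1), Genotype.HOM: (1, 1),
                  Genotype.UNKNOWN: (None, None)}[call.genotype]
            rec.samples[sample_id]["GT"] = gt
            out.write(rec)
    return path


# ---------------------------------------------------------------------------
# gene panel TSV
# ---------------------------------------------------------------------------

GENE_PANEL_COLUMNS = ["symbol", "chrom", "strand", "exon_starts", "exon_ends",
                      "panels", "inheritance"]


def read_gene_models(path: PathLike,
                     chrom_table: Optional[Mapping[str, str]] = None
                     ) -> list[GeneModel]:
    """Read a gene panel TSV.

    ``exon_starts``/``exon_ends`` are comma-separated BED-style 0-based
    half-open coordinates; they are converted to 1-based closed intervals.
    ``panels`` and ``inheritance`` are comma-separated label sets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene panel file missing columns: {missing}")
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in row.exon_starts.split(",") if x != ""]
        ends = [int(x) for x in row.exon_ends.split(",") if x != ""]
        if len(starts) != len(ends):
            raise ValueError(
                f"gene {row.symbol}: exon start/end count mismatch")
        exons = [(s + 1, e) for s, e in zip(starts, ends)]
        panels = {Group(p) for p in row.panels.split(",") if p}
        modes = {InheritanceMode(m) for m in row.inheritance.split(",") if m}
        genes.append(GeneModel(row.symbol,
                               normalize_chrom(row.chrom, chrom_table),
                               row.strand, exons, panels, modes))
    genes.sort(key=lambda g: (_contig_sort_key(g.chrom), g.start, g.symbol))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: PathLike) -> Path:
    rows = []
    for g in sorted(genes, key=lambda g: (_contig_sort_key(g.chrom), g.start,
                                          g.symbol)):
        rows.append({
            "symbol": g.symbol,
            "chrom": g.chrom,
            "strand": g.strand,
            "exon_starts": ",".join(str(s - 1) for s, _ in g.exons),
            "exon_ends": ",".join(str(e) for _, e in g.exons),
            "panels": ",".join(sorted(p.value for p in g.panels)),
            "inheritance": ",".join(
                sorted(m.value for m in g.inheritance_modes)),
        })
    pd.DataFrame(rows, columns=GENE_PANEL_COLUMNS).to_csv(
        path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# sample sheet TSV
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "family_id", "affected", "group",
                        "hpo", "ordo"]


def read_sample_sheet(path: PathLike) -> list[SampleMeta]:
    """Read the cohort sample sheet (one row per sequenced dataset)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sample_id(s) in sample sheet: {dupes}")
    samples: list[SampleMeta] = []
    allowed = [g.value for g in Group]
    for row in df.itertuples(index=False):
        if row.group not in allowed:
            raise ValueError(
                f"unknown group {row.group!r} for sample {row.sample_id}; "
                f"allowed: {allowed}")
        hpo = [t for t in row.hpo.split(";") if t]
        samples.append(SampleMeta(row.sample_id, row.family_id,
                                  affected=row.affected in ("1", "true",
                                                            "True"),
                                  group=Group(row.group),
                                  hpo_terms=hpo,
                                  ordo_code=row.ordo or None))
    return samples


def write_sample_sheet(samples: Sequence[SampleMeta], path: PathLike) -> Path:
    rows = [{
        "sample_id": s.sample_id,
        "family_id": s.family_id,
        "affected": int(s.affected),
        "group": s.group.value,
        "hpo": ";".join(s.hpo_terms),
        "ordo": s.ordo_code or "",
    } for s in samples]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(
        path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# CNV segments / short variants
# ---------------------------------------------------------------------------

CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "state", "caller"]
SHORT_VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "gene", "category",
                         "zygosity"]


def read_cnv_segments(path: PathLike,
                      chrom_table: Optional[Mapping[str, str]] = None
                      ) -> list[CNVSegment]:
    """Read read-depth CNV segments (1-based closed coordinates)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CNV segment file missing columns: {missing}")
    segments = []
    for row in df.itertuples(index=False):
        try:
            state = CNState(row.state)
        except ValueError:
            raise ValueError(
                f"CNV state must be one of "
                f"{[s.value for s in CNState]}, got {row.state!r}") from None
        segments.append(CNVSegment(row.sample_id,
                                   normalize_chrom(row.chrom, chrom_table),
                                   int(row.start), int(row.end), state,
                                   row.caller))
    return segments


def write_cnv_segments(segments: Sequence[CNVSegment],
                       path: PathLike) -> Path:
    rows = [{
        "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
        "end": s.end, "state": s.state.value, "caller": s.caller,
    } for s in segments]
    pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(path, sep="\t",
                                                   index=False)
    return Path(path)


def read_short_variants(path: PathLike,
                        chrom_table: Optional[Mapping[str, str]] = None
                        ) -> list[ShortVariant]:
    """Read HIGH-impact / known-pathogenic short-variant calls."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SHORT_VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"short-variant file missing columns: {missing}")
    variants = []
    for row in df.itertuples(index=False):
        variants.append(ShortVariant(
            row.sample_id, normalize_chrom(row.chrom, chrom_table),
            int(row.pos), row.gene, VariantCategory(row.category),
            Genotype(row.zygosity)))
    return variants


def write_short_variants(variants: Sequence[ShortVariant],
                         path: PathLike) -> Path:
    rows = [{
        "sample_id": v.sample_id, "chrom": v.chrom, "pos": v.pos,
        "gene": v.gene, "category": v.category.value,
        "zygosity": v.zygosity.value,
    } for v in variants]
    pd.DataFrame(rows, columns=SHORT_VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False)
    return Path(path)
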