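"""Cohort-wide breakpoint allele-frequency estimation.

Every breakend of every call in every dataset (affected and unaffected,
PASS and non-PASS) is inserted into a per-chromosome sorted index.  The
cohort count of a breakpoint is the number of *distinct datasets* carrying
at least one breakpoint within +/- ``window_bp`` (default 20 bp, matching
the typical caller confidence-interval width); the focal dataset always
counts itself.  An SV's count is, by default, the maximum over its
breakends.  Frequencies are expressed as a percentage of the number of
datasets, e.g. 20 of 9351 datasets ~ 0.21%.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .model import SVCall

PathLike = Union[str, Path]


@dataclass
class CohortIndex:
    """Per-chromosome sorted breakpoint positions with dataset codes."""

    window_bp: int
    n_datasets: int
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    dataset_codes: dict[str, np.ndarray] = field(default_factory=dict)
    dataset_ids: list[str] = field(default_factory=list)

    def n_breakpoints(self) -> int:
        """Total deduplicated (dataset, chrom, pos) entries in the index."""
        return sum(len(a) for a in self.positions.values())


def build_cohort_index(callsets: Mapping[str, Sequence[SVCall]],
                       window_bp: int = 20,
                       n_datasets: Optional[int] = None) -> CohortIndex:
    """Index every breakend of every call across all datasets.

    Within one dataset, multiple breakends at an identical (chrom, pos) are
    stored once; counting is dataset-denominated, so intra-sample duplicates
    can never inflate a frequency.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be >= 0, got {window_bp}")
    dataset_ids = sorted(callsets)
    code = {s: i for i, s in enumerate(dataset_ids)}
    if n_datasets is None:
        n_datasets = len(dataset_ids)
    elif n_datasets < len(dataset_ids):
        raise ValueError(
            f"n_datasets ({n_datasets}) smaller than number of distinct "
            f"datasets in the index ({len(dataset_ids)})")
    per_chrom: dict[str, set[tuple[int, int]]] = {}
    for sample in dataset_ids:
        c = code[sample]
        for call in callsets[sample]:
            for be in call.breakends:
                per_chrom.setdefault(be.chrom, set()).add((be.pos, c))
    positions: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for chrom, entries in per_chrom.items():
        arr = np.array(sorted(entries), dtype=np.int64)
        positions[chrom] = np.ascontiguousarray(arr[:, 0])
        codes[chrom] = np.ascontiguousarray(arr[:, 1])
    return CohortIndex(window_bp=window_bp, n_datasets=n_datasets,
                       positions=positions, dataset_codes=codes,
                       dataset_ids=dataset_ids)


def _window_slice(index: CohortIndex, chrom: str, pos: int
                  ) -> Optional[np.ndarray]:
    arr = index.positions.get(chrom)
    if arr is None:
        return None
    lo = np.searchsorted(arr, pos - index.window_bp, side="left")
    hi = np.searchsorted(arr, pos + index.window_bp, side="right")
    if hi <= lo:
        return None
    return index.dataset_codes[chrom][lo:hi]


def breakpoint_count(index: CohortIndex, chrom: str, pos: int) -> int:
    """Distinct datasets with >=1 breakpoint within +/- window of ``pos``.

    The window is closed: a neighbour at exactly ``window_bp`` counts.
    An unknown chromosome yields 0.
    """
    codes = _window_slice(index, chrom, pos)
    if codes is None:
        return 0
    return int(np.unique(codes).size)


def samples_near(index: CohortIndex, chrom: str, pos: int) -> list[str]:
    """Sorted dataset ids with a breakpoint within +/- window of ``pos``."""
    codes = _window_slice(index, chrom, pos)
    if codes is None:
        return []
    return [index.dataset_ids[c] for c in np.unique(codes)]


def sv_cohort_count(index: CohortIndex, sv: SVCall,
                    combine: str = "max") -> int:
    """Cohort count of an SV, combining its per-breakend counts.

    ``combine`` is one of ``max`` (default: an SV sharing *either*
    breakpoint with many datasets is frequent), ``min`` or ``mean``.
    """
    counts = [breakpoint_count(index, be.chrom, be.pos)
              for be in sv.breakends]
    if combine == "max":
        return max(counts)
    if combine == "min":
        return min(counts)
    if combine == "mean":
        return int(round(sum(counts) / len(counts)))
    raise ValueError(f"unknown combine rule {combine!r}")


def cohort_fraction_pct(count: int, n_datasets: int) -> float:
    """Breakpoint frequency as a percentage, reported to 2 decimals."""
    if n_datasets <= 0:
        raise ValueError("n_datasets must be positive")
    if count > n_datasets:
        raise ValueError(
            f"count ({count}) cannot exceed n_datasets ({n_datasets})")
    return round(100.0 * count / n_datasets, 2)


# ---------------------------------------------------------------------------
# TSV serialization (sorted; supports incremental cohort updates)
# ---------------------------------------------------------------------------

def write_index(index: CohortIndex, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#window_bp={index.window_bp}\n")
        fh.write(f"#n_datasets={index.n_datasets}\n")
        fh.write("chrom\tpos\tsample_id\n")
        for chrom in sorted(index.positions):
            pos = index.positions[chrom]
            codes = index.dataset_codes[chrom]
            for p, c in zip(pos, codes):
                fh.write(f"{chrom}\t{p}\t{index.dataset_ids[c]}\n")
    return path


def read_index(path: PathLike) -> CohortIndex:
    path = Path(path)
    window_bp = 20
    n_datasets = 0
    entries: dict[str, list[tuple[int, str]]] = {}
    samples: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#window_bp="):
                window_bp = int(line.split("=", 1)[1])
                continue
            if line.startswith("#n_datasets="):
                n_datasets = int(line.split("=", 1)[1])
                continue
            if line.startswith("chrom\t") or not line:
                continue
            chrom, pos, sample = line.split("\t")
            entries.setdefault(chrom, []).append((int(pos), sample))
            samples.add(sample)
    dataset_ids = sorted(samples)
    code = {s: i for i, s in enumerate(dataset_ids)}
    positions: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for chrom, rows in entries.items():
        rows = sorted((p, code[s]) for p, s in rows)
        arr = np.array(rows, dtype=np.int64).reshape(-1, 2)
        positions[chrom] = np.ascontiguousarray(arr[:, 0])
        codes[chrom] = np.ascontiguousarray(arr[:, 1])
    return CohortIndex(window_bp=window_bp,
                       n_datasets=n_datasets or len(dataset_ids),
                       positions=positions, dataset_codes=codes,
                       dataset_ids=dataset_ids)
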