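"""Genomic interval algebra: peak expansion and TSS intersection.

Peaks are expanded either symmetrically to a genomic distance λ around the
peak centre, or out to the boundaries of overlapping topologically associated
domains (TADs).  Expanded regions are then intersected with the TSS reference
to obtain the set of genes regulated (putatively) by each peak set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ParseError, PeakgeneError
from .reference import TssReference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open coordinate span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PeakSet:
    """A named collection of peak intervals (ChIP/ATAC peaks, SNPs, ...)."""

    name: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self):
        if not self.name:
            raise ValueError("peak set name must be non-empty")
        object.__setattr__(self, "intervals", tuple(self.intervals))

    def __len__(self):
        return len(self.intervals)


class TadSet:
    """Non-overlapping TAD intervals, sorted by (chrom, start).

    Overlapping input TADs are merged at construction with a warning;
    boundary-touching TADs (``[0,1000)`` and ``[1000,2000)``) stay distinct.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        merged: list[GenomicInterval] = []
        n_merged = 0
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
            cur_start, cur_end = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start < cur_end:  # strict overlap; touching stays separate
                    cur_end = max(cur_end, iv.end)
                    n_merged += 1
                else:
                    merged.append(GenomicInterval(chrom, cur_start, cur_end))
                    cur_start, cur_end = iv.start, iv.end
            merged.append(GenomicInterval(chrom, cur_start, cur_end))
        if n_merged:
            logger.warning("merged %d overlapping TAD intervals at load time", n_merged)
        self.intervals: tuple[GenomicInterval, ...] = tuple(merged)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted(by_chrom):
            chrom_ivs = [iv for iv in merged if iv.chrom == chrom]
            self._by_chrom[chrom] = (
                np.array([iv.start for iv in chrom_ivs], dtype=np.int64),
                np.array([iv.end for iv in chrom_ivs], dtype=np.int64),
            )

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def overlapping_span(self, peak: GenomicInterval) -> Optional[tuple[int, int]]:
        """Outermost boundaries of all TADs overlapping ``peak``, or None."""
        arrs = self._by_chrom.get(peak.chrom)
        if arrs is None:
            return None
        starts, ends = arrs
        # TADs are sorted and disjoint: those overlapping [start, end) form a
        # contiguous run with tad.start < peak.end and tad.end > peak.start.
        lo = int(np.searchsorted(ends, peak.start, side="right"))
        hi = int(np.searchsorted(starts, peak.end, side="left"))
        if lo >= hi:
            return None
        return int(starts[lo]), int(ends[hi - 1])


class ExpansionSpec:
    """One expansion rule: a symmetric distance λ in bp, or TAD mode.

    TAD mode replaces distance expansion: a run is a list of λ values plus an
    optional TAD entry, each producing its own block of result cells.
    """

    __slots__ = ("lambda_bp",)

    def __init__(self, lambda_bp: Optional[int]):
        if lambda_bp is not None and lambda_bp < 0:
            raise ValueError(f"expansion distance must be >= 0, got {lambda_bp}")
        self.lambda_bp = lambda_bp

    @classmethod
    def distance(cls, lambda_bp: int) -> "ExpansionSpec":
        return cls(int(lambda_bp))

    @classmethod
    def tads(cls) -> "ExpansionSpec":
        return cls(None)

    @property
    def is_tad(self) -> bool:
        return self.lambda_bp is None

    @property
    def label(self) -> str:
        return "TAD" if self.is_tad else str(self.lambda_bp)

    @property
    def display_label(self) -> str:
        """Human-readable axis label: 5000 -> '5 kb', 1500000 -> '1.5 Mb'."""
        if self.is_tad:
            return "TAD"
        bp = self.lambda_bp
        if bp >= 1_000_000 and bp % 100_000 == 0:
            v = bp / 1_000_000
            return f"{v:g} Mb"
        if bp >= 1_000 and bp % 100 == 0:
            v = bp / 1_000
            return f"{v:g} kb"
        return f"{bp} bp"

    def __eq__(self, other):
        return isinstance(other, ExpansionSpec) and self.lambda_bp == other.lambda_bp

    def __hash__(self):
        return hash(self.lambda_bp)

    def __repr__(self):
        return f"ExpansionSpec({self.label})"


def expand_peak(peak: GenomicInterval, lambda_bp: int) -> GenomicInterval:
    """Expand a peak to ``[centre - λ, centre + λ)``, clamped at 0 on the left.

    λ is measured from the peak centre ``floor((start + end) / 2)`` in both
    directions.  λ = 0 returns the peak unchanged, so raw peaks can be tested.
    """
    if lambda_bp < 0:
        raise ValueError(f"expansion distance must be >= 0, got {lambda_bp}")
    if lambda_bp == 0:
        return peak
    c = peak.centre
    return GenomicInterval(peak.chrom, max(0, c - lambda_bp), c + lambda_bp, peak.label)


def expand_peak_to_tads(peak: GenomicInterval, tads: TadSet) -> Optional[GenomicInterval]:
    """Expand a peak to the outermost boundaries of its overlapping TADs.

    Returns None when the peak overlaps no TAD: such a peak has no defined
    regulatory domain in TAD mode and contributes nothing.
    """
    span = tads.overlapping_span(peak)
    if span is None:
        return None
    return GenomicInterval(peak.chrom, span[0], span[1], peak.label)


def expand_peak_set(
    peaks: PeakSet,
    expansion: ExpansionSpec,
    tads: Optional[TadSet] = None,
) -> list[GenomicInterval]:
    """Expand every peak in a set under one expansion rule.

    In TAD mode peaks overlapping no TAD are dropped; the count of dropped
    peaks is logged.
    """
    if expansion.is_tad:
        if tads is None:
            raise PeakgeneError("TAD expansion requested but no TAD set provided")
        out = []
        n_orphan = 0
        for p in peaks.intervals:
            ex = expand_peak_to_tads(p, tads)
            if ex is None:
                n_orphan += 1
            else:
                out.append(ex)
        if n_orphan:
            logger.info(
                "peak set %r: %d/%d peaks overlap no TAD and were dropped in TAD mode",
                peaks.name, n_orphan, len(peaks),
            )
        return out
    return [expand_peak(p, expansion.lambda_bp) for p in peaks.intervals]


def overlapping_genes(
    regions: Sequence[GenomicInterval], ref: TssReference
) -> set[str]:
    """Unique gene symbols with a TSS inside at least one region.

    A TSS at ``pos`` is inside ``[start, end)`` iff ``start <= pos < end``.
    Implemented by per-chromosome binary search over the sorted TSS positions,
    O((R + T) log T) rather than the naive O(R·T) all-pairs scan.
    """
    if not regions:
        return set()
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {r.chrom for r in regions}:
        recs = [t for t in ref.records if t.chrom == chrom]
        if recs:
            by_chrom[chrom] = (
                np.array([t.pos for t in recs], dtype=np.int64),
                [t.gene for t in recs],
            )
    genes: set[str] = set()
    for region in regions:
        entry = by_chrom.get(region.chrom)
        if entry is None:
            continue
        pos, names = entry
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        genes.update(names[lo:hi])
    return genes


_BED_SKIP = ("#", "track", "browser")


def _read_bed_intervals(path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "need >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            if not (0 <= start < end):
                raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
            label = fields[3].strip() if len(fields) >= 4 and fields[3].strip() else None
            intervals.append(GenomicInterval(fields[0].strip(), start, end, label))
    if not intervals:
        raise PeakgeneError(f"empty BED file: {path}")
    return intervals


def load_peaks_bed(path, name: Optional[str] = None) -> PeakSet:
    """Load a peak set from BED; the set name defaults to the file basename."""
    from pathlib import Path

    if name is None:
        name = Path(path).name
        for suffix in (".gz", ".bed"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
    return PeakSet(name, tuple(_read_bed_intervals(path)))


def load_tads_bed(path) -> TadSet:
    """Load TAD intervals from BED (overlaps merged with a warning)."""
    return TadSet(_read_bed_intervals(path))


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as 3- or 4-column BED (label column when present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
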