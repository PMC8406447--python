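"""Deterministic synthetic genomes with planted peak-gene associations.

The generator produces everything the enrichment workflow consumes — a TSS
reference (and its refGene-style table), a peak BED, a tiling TAD BED and two
gene lists — at toy scale, with a planted signal whose strength is controlled
by the placement distance:

* genes are placed uniformly at random on each chromosome;
* a planted subset of genes each receives one peak whose centre sits at a
  signed uniform offset within ±``planted_distance`` bp of the gene's TSS,
  so expanding peaks by λ >= planted_distance recovers every planted gene;
* the remaining peaks are placed uniformly (background noise);
* a size-matched random gene set is drawn from the *non-planted* genes,
  independent of peak placement, and therefore behaves as a null draw;
* TADs tile each chromosome into contiguous non-overlapping blocks.

All randomness flows from a single ``numpy.random.default_rng(seed)``;
identical seeds give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enrichment import GeneSet, write_gene_set
from .errors import PeakgeneError
from .intervals import GenomicInterval, PeakSet, TadSet, write_bed
from .reference import TssRecord, TssReference, write_tss_bed


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a single 10 Mb chromosome carrying 500 genes and 100
    peaks, half of which are planted within 5 kb of a distinct gene TSS —
    a gene density (1 gene / 20 kb) and peak count typical of a focused
    ChIP-seq experiment, scaled down ~250x from a mammalian genome.
    """

    seed: int
    n_chroms: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 500
    n_peaks: int = 100
    planted_gene_fraction: float = 0.1
    planted_distance: int = 5_000
    peak_width: int = 200
    tad_size: int = 1_000_000

    def __post_init__(self):
        for label, v in (
            ("n_chroms", self.n_chroms),
            ("chrom_length", self.chrom_length),
            ("n_genes", self.n_genes),
            ("n_peaks", self.n_peaks),
            ("peak_width", self.peak_width),
            ("tad_size", self.tad_size),
        ):
            if v <= 0:
                raise ValueError(f"{label} must be positive, got {v}")
        if not (0.0 <= self.planted_gene_fraction <= 1.0):
            raise ValueError("planted_gene_fraction must be in [0, 1]")
        if self.planted_distance < 0:
            raise ValueError("planted_distance must be >= 0")
        if self.n_planted == 0:
            raise PeakgeneError(
                "planted gene set would be empty; raise planted_gene_fraction"
            )
        if self.n_planted > self.n_peaks:
            raise PeakgeneError(
                f"{self.n_planted} planted genes need one peak each but only "
                f"{self.n_peaks} peaks were requested"
            )
        if 2 * self.n_planted > self.n_genes:
            raise PeakgeneError(
                "need as many non-planted genes as planted ones to draw the "
                "size-matched random set"
            )

    @property
    def n_planted(self) -> int:
        return int(round(self.planted_gene_fraction * self.n_genes))


@dataclass(frozen=True)
class Fixture:
    """One generated dataset: reference, peaks, TADs and the two gene sets."""

    spec: FixtureSpec
    reference: TssReference
    peaks: PeakSet
    tads: TadSet
    planted: GeneSet
    random: GeneSet


def _centered_interval(chrom: str, centre: int, width: int, label=None) -> GenomicInterval:
    """Interval whose floor-centre is exactly ``centre``, clamped at 0."""
    half = width // 2
    if centre >= half:
        return GenomicInterval(chrom, centre - half, centre + (width - half), label)
    if centre == 0:
        return GenomicInterval(chrom, 0, 1, label)
    return GenomicInterval(chrom, 0, 2 * centre, label)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate one synthetic dataset from a spec (seeded, deterministic)."""
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]

    gene_chrom = rng.integers(0, spec.n_chroms, size=spec.n_genes)
    gene_pos = rng.integers(0, spec.chrom_length, size=spec.n_genes)
    gene_strand = rng.choice(np.array(["+", "-"]), size=spec.n_genes)
    width = max(len(str(spec.n_genes)), 4)
    records = [
        TssRecord(chroms[int(c)], int(p), f"G{i:0{width}d}", str(s))
        for i, (c, p, s) in enumerate(zip(gene_chrom, gene_pos, gene_strand))
    ]
    reference = TssReference(records)

    order = rng.permutation(spec.n_genes)
    planted_idx = order[: spec.n_planted]
    random_idx = order[spec.n_planted : 2 * spec.n_planted]
    planted = GeneSet("planted", [records[i].gene for i in planted_idx])
    random_set = GeneSet("random", [records[i].gene for i in random_idx])

    peaks: list[GenomicInterval] = []
    for k, i in enumerate(planted_idx):
        rec = records[i]
        offset = int(rng.integers(-spec.planted_distance, spec.planted_distance + 1))
        centre = min(max(rec.pos + offset, 0), spec.chrom_length - 1)
        peaks.append(_centered_interval(rec.chrom, centre, spec.peak_width, f"planted_{k}"))
    n_random_peaks = spec.n_peaks - spec.n_planted
    rp_chrom = rng.integers(0, spec.n_chroms, size=n_random_peaks)
    rp_start = rng.integers(
        0, max(1, spec.chrom_length - spec.peak_width), size=n_random_peaks
    )
    for k, (c, s) in enumerate(zip(rp_chrom, rp_start)):
        peaks.append(
            GenomicInterval(
                chroms[int(c)], int(s), int(s) + spec.peak_width, f"noise_{k}"
            )
        )
    peak_set = PeakSet("synthetic_peaks", tuple(peaks))

    tads: list[GenomicInterval] = []
    for chrom in chroms:
        for start in range(0, spec.chrom_length, spec.tad_size):
            end = min(start + spec.tad_size, spec.chrom_length)
            if end > start:
                tads.append(GenomicInterval(chrom, start, end))
    tad_set = TadSet(tads)

    return Fixture(spec, reference, peak_set, tad_set, planted, random_set)


def write_fixture(fixture: Fixture, outdir) -> dict[str, Path]:
    """Write a fixture to disk through the production writers.

    Emits ``tss.bed``, ``refgene.tsv`` (minimal 5-column dialect),
    ``peaks.bed``, ``tads.bed``, ``planted.txt`` and ``random.txt``; returns
    the path of each.  Tests and examples that load these files exercise the
    same I/O layer as real runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tss": outdir / "tss.bed",
        "refgene": outdir / "refgene.tsv",
        "peaks": outdir / "peaks.bed",
        "tads": outdir / "tads.bed",
        "planted": outdir / "planted.txt",
        "random": outdir / "random.txt",
    }
    write_tss_bed(fixture.reference, paths["tss"])
    with open(paths["refgene"], "w") as fh:
        for rec in fixture.reference:
            # Transcript span [pos, pos+1000) for "+", [pos-999, pos+1) for "-":
            # both give the TSS back under the strand rule.
            if rec.strand == "+":
                tx_start, tx_end = rec.pos, rec.pos + 1000
            else:
                tx_start, tx_end = max(0, rec.pos - 999), rec.pos + 1
            fh.write(f"{rec.gene}\t{rec.chrom}\t{rec.strand}\t{tx_start}\t{tx_end}\n")
    write_bed(fixture.peaks.intervals, paths["peaks"])
    write_bed(fixture.tads.intervals, paths["tads"])
    write_gene_set(fixture.planted, paths["planted"])
    write_gene_set(fixture.random, paths["random"])
    return paths
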