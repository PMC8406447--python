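"""Gene-TSS reference: the gene universe and TSS coordinates.

The reference defines both the coordinates against which expanded peaks are
intersected and the gene universe size ``M`` of the hypergeometric test
(the total number of unique gene symbols, not transcripts).

Coordinates are 0-based half-open throughout (BED convention); a TSS occupies
the single base ``[pos, pos + 1)``.  For a transcript span ``[txStart, txEnd)``
the TSS is ``txStart`` on the "+" strand and ``txEnd - 1`` on the "-" strand —
the last base inside the half-open span, since ``txEnd`` itself lies outside
the transcript.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError, PeakgeneError

logger = logging.getLogger(__name__)

_STRANDS = frozenset("+-")


@dataclass(frozen=True, order=True)
class TssRecord:
    """One transcription start site.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    pos : int
        0-based TSS coordinate in base pairs.
    gene : str
        Gene symbol; compared case-sensitively after whitespace stripping.
    strand : str
        "+" or "-".
    """

    chrom: str
    pos: int
    gene: str
    strand: str = "+"

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")


class TssReference:
    """An ordered, deduplicated collection of TSS records.

    Records are sorted by ``(chrom, pos)``; duplicate ``(chrom, pos, gene)``
    triples (e.g. identical transcripts from a refGene table) are collapsed.
    ``M`` counts unique gene symbols, not transcripts: a gene with several
    alternative TSSs contributes several records but one unit to ``M``.
    """

    def __init__(self, records: Iterable[TssRecord]):
        seen: dict[tuple[str, int, str], TssRecord] = {}
        for rec in records:
            key = (rec.chrom, rec.pos, rec.gene)
            if key not in seen:
                seen[key] = rec
        self.records: tuple[TssRecord, ...] = tuple(
            sorted(seen.values(), key=lambda r: (r.chrom, r.pos, r.gene))
        )
        self.universe: frozenset[str] = frozenset(r.gene for r in self.records)

    @property
    def M(self) -> int:
        """Number of unique gene symbols (the hypergeometric universe size)."""
        return len(self.universe)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TssRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TssReference):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:
        return f"TssReference({len(self.records)} TSSs, M={self.M})"


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_int(field: str, what: str, path, lineno: int) -> int:
    try:
        return int(field)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {field!r}") from None


def build_tss_reference(refgene_table) -> TssReference:
    """Build a TSS reference from a UCSC refGene-style tab-delimited table.

    Two dialects are accepted, selected by column count per line:

    * the full UCSC table (>= 13 columns: ``bin, name, chrom, strand, txStart,
      txEnd, ..., name2, ...``), gene symbol taken from ``name2``;
    * a minimal 5-column form ``symbol, chrom, strand, txStart, txEnd``.

    One record is produced per transcript row, with the TSS at ``txStart`` for
    "+"-strand and ``txEnd - 1`` for "-"-strand transcripts.  Gzip input is
    accepted.  Header lines starting with ``#`` are skipped.
    """
    records = []
    with _open_text(refgene_table) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 13:
                gene, chrom, strand = fields[12], fields[2], fields[3]
                tx_start = _parse_int(fields[4], "txStart", refgene_table, lineno)
                tx_end = _parse_int(fields[5], "txEnd", refgene_table, lineno)
            elif len(fields) == 5:
                gene, chrom, strand = fields[0], fields[1], fields[2]
                tx_start = _parse_int(fields[3], "txStart", refgene_table, lineno)
                tx_end = _parse_int(fields[4], "txEnd", refgene_table, lineno)
            else:
                raise ParseError(
                    refgene_table, lineno,
                    f"expected 5 or >=13 tab-delimited columns, got {len(fields)}",
                )
            gene = gene.strip()
            strand = strand.strip()
            if strand not in _STRANDS:
                raise ParseError(refgene_table, lineno, f"missing or invalid strand {strand!r}")
            if not gene:
                raise ParseError(refgene_table, lineno, "empty gene symbol")
            if tx_start >= tx_end:
                raise ParseError(
                    refgene_table, lineno, f"txStart {tx_start} >= txEnd {tx_end}"
                )
            pos = tx_start if strand == "+" else tx_end - 1
            records.append(TssRecord(chrom.strip(), pos, gene, strand))
    if not records:
        raise PeakgeneError(f"empty reference: no transcript rows in {refgene_table}")
    return TssReference(records)


def load_tss_bed(bed_file) -> TssReference:
    """Load a TSS reference from a 4-6 column BED file.

    Each line becomes one record with ``pos = start``; column 4 is the gene
    symbol and column 6, when present, the strand (default "+").  Lines whose
    interval is not the single base ``[start, start + 1)`` are accepted with a
    warning, using ``start``.
    """
    records = []
    with _open_text(bed_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(bed_file, lineno, "need >= 4 BED columns (chrom, start, end, gene)")
            chrom = fields[0].strip()
            if not chrom or any(c.isspace() for c in chrom):
                raise ParseError(bed_file, lineno, f"invalid chrom field {fields[0]!r}")
            start = _parse_int(fields[1], "start", bed_file, lineno)
            end = _parse_int(fields[2], "end", bed_file, lineno)
            if end != start + 1:
                logger.warning(
                    "%s:%d: interval [%d, %d) is not a single base; using start",
                    bed_file, lineno, start, end,
                )
            gene = fields[3].strip()
            if not gene:
                raise ParseError(bed_file, lineno, "empty gene symbol")
            strand = fields[5].strip() if len(fields) >= 6 else "+"
            if strand not in _STRANDS:
                raise ParseError(bed_file, lineno, f"invalid strand {strand!r}")
            records.append(TssRecord(chrom, start, gene, strand))
    if not records:
        raise PeakgeneError(f"empty reference: {bed_file}")
    return TssReference(records)


def write_tss_bed(ref: TssReference, path) -> None:
    """Write a reference as 6-column BED (chrom, start, end, gene, 0, strand)."""
    if len(ref) == 0:
        raise PeakgeneError("refusing to write an empty TSS reference")
    with open(path, "w") as fh:
        for rec in ref:
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\t{rec.gene}\t0\t{rec.strand}\n")


def load_reference(path) -> TssReference:
    """Load a reference from either a TSS BED file or a refGene-style table.

    The dialect is sniffed from the first data line: integer columns 2-3
    mean BED; a strand in column 3 with integer columns 4-5 means refGene.
    """
    with _open_text(path) as fh:
        first = None
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line.rstrip("\n").split("\t")
                break
    if first is None:
        raise PeakgeneError(f"empty reference: {path}")

    def _is_int(s):
        try:
            int(s)
            return True
        except ValueError:
            return False

    if len(first) >= 4 and _is_int(first[1]) and _is_int(first[2]):
        return load_tss_bed(path)
    return build_tss_reference(path)
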