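"""Hypergeometric enrichment of gene sets in peak-overlapping genes.

For a gene universe of size ``M`` (unique symbols in the TSS reference,
optionally restricted to a user background), an input gene set of effective
size ``Nc``, ``Np`` unique genes whose TSS falls inside the expanded peaks,
and an observed overlap ``n_pc``, the upper-tail hypergeometric p-value is

    p = sum_{x = n_pc}^{min(Np, Nc)}  C(Np, x) C(M - Np, Nc - x) / C(M, Nc)

i.e. the probability of drawing at least ``n_pc`` peak-associated genes when
``Nc`` genes are sampled from the universe without replacement.  The sum is
evaluated in log-space via log-gamma so it stays finite and accurate at
genome scale (M of order 10^4-10^5).

One p-value is produced per (gene set, peak set, expansion) triple; the grid
of results is an :class:`EnrichmentMatrix`, the source for both the tidy TSV
table and the heatmap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .errors import ConfigError, PeakgeneError
from .intervals import ExpansionSpec, PeakSet, TadSet, expand_peak_set, overlapping_genes
from .reference import TssReference

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene symbols."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Iterable[str]):
        genes = frozenset(g.strip() for g in genes if g.strip())
        if not name:
            raise ValueError("gene set name must be non-empty")
        if not genes:
            raise ValueError(f"gene set {name!r} is empty after deduplication")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", genes)

    def __len__(self):
        return len(self.genes)


def _check_counts(M: int, Nc: int, Np: int, n_pc: int) -> None:
    for label, v in (("M", M), ("Nc", Nc), ("Np", Np), ("n_pc", n_pc)):
        if v < 0:
            raise ValueError(f"{label} must be >= 0, got {v}")
    if Nc > M:
        raise ValueError(f"Nc ({Nc}) exceeds universe size M ({M})")
    if Np > M:
        raise ValueError(f"Np ({Np}) exceeds universe size M ({M})")
    if n_pc > min(Np, Nc):
        raise ValueError(f"n_pc ({n_pc}) exceeds min(Np, Nc) = {min(Np, Nc)}")


def hypergeom_log_tail(M: int, Nc: int, Np: int, n_pc: int) -> float:
    """Natural log of the upper-tail hypergeometric probability.

    Exact in log-space for any valid counts; returns 0.0 (p = 1) when
    ``n_pc = 0``.  Vectorised internally over the tail terms.
    """
    _check_counts(M, Nc, Np, n_pc)
    if n_pc == 0:
        return 0.0
    kmax = min(Np, Nc)
    # Terms with Nc - x > M - Np have a zero binomial; start above them.
    kmin = max(n_pc, Nc - (M - Np))
    if kmin > kmax:
        # Unreachable for valid counts (n_pc <= min and support is non-empty),
        # but guard against an empty sum.
        return -math.inf
    x = np.arange(kmin, kmax + 1, dtype=np.float64)
    log_terms = (
        gammaln(Np + 1) - gammaln(x + 1) - gammaln(Np - x + 1)
        + gammaln(M - Np + 1) - gammaln(Nc - x + 1) - gammaln(M - Np - Nc + x + 1)
        - (gammaln(M + 1) - gammaln(Nc + 1) - gammaln(M - Nc + 1))
    )
    return float(min(0.0, logsumexp(log_terms)))


def hypergeom_tail(M: int, Nc: int, Np: int, n_pc: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= n_pc), in (0, 1]."""
    return float(math.exp(hypergeom_log_tail(M, Nc, Np, n_pc)))


def hypergeom_log_tail_all(M: int, Nc: int, Np: int) -> np.ndarray:
    """Log tails for every possible overlap at once.

    Returns an array of length ``min(Np, Nc) + 1`` whose entry ``k`` is
    ``hypergeom_log_tail(M, Nc, Np, k)``, computed with one reverse
    cumulative log-sum-exp — much cheaper than ``kmax`` separate calls when
    scanning the whole overlap range.
    """
    _check_counts(M, Nc, Np, 0)
    kmax = min(Np, Nc)
    kmin = max(0, Nc - (M - Np))
    x = np.arange(kmin, kmax + 1, dtype=np.float64)
    log_terms = (
        gammaln(Np + 1) - gammaln(x + 1) - gammaln(Np - x + 1)
        + gammaln(M - Np + 1) - gammaln(Nc - x + 1) - gammaln(M - Np - Nc + x + 1)
        - (gammaln(M + 1) - gammaln(Nc + 1) - gammaln(M - Nc + 1))
    )
    rev_cum = np.logaddexp.accumulate(log_terms[::-1])[::-1]
    out = np.zeros(kmax + 1, dtype=np.float64)
    out[kmin:] = np.minimum(0.0, rev_cum)
    return out


def effective_counts(
    gene_set: GeneSet,
    overlap_genes: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> tuple[int, int, int]:
    """Counts (Nc, Np, n_pc) after restricting the gene set to the universe.

    Input symbols absent from the reference universe are dropped (with a
    logged count) rather than inflating ``Nc``: the test is only coherent
    when the cluster is a subset of the universe.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    in_universe = gene_set.genes & universe
    dropped = len(gene_set.genes) - len(in_universe)
    if dropped:
        logger.info(
            "gene set %r: %d/%d symbols absent from the reference universe were dropped",
            gene_set.name, dropped, len(gene_set.genes),
        )
    n_pc = len(in_universe & overlap_genes)
    return len(in_universe), len(overlap_genes), n_pc


@dataclass(frozen=True)
class EnrichmentCell:
    """All counts and the p-value for one (gene set, peak set, expansion)."""

    gene_set_name: str
    peak_set_name: str
    expansion: str
    M: int
    Nc: int
    Np: int
    n_pc: int
    p_value: float
    log_p: float  # natural log, exact in log-space (no underflow)

    @property
    def neg_log10_p(self) -> float:
        return 0.0 if self.log_p == 0.0 else -self.log_p / _LN10


@dataclass
class EnrichmentMatrix:
    """The full grid of enrichment cells plus axis label orders."""

    cells: list[EnrichmentCell]
    gene_set_order: list[str]
    peak_set_order: list[str]
    expansion_order: list[str]

    def __post_init__(self):
        expected = (
            len(self.gene_set_order) * len(self.peak_set_order) * len(self.expansion_order)
        )
        if len(self.cells) != expected:
            raise ValueError(
                f"expected {expected} cells "
                f"({len(self.gene_set_order)} gene sets x {len(self.peak_set_order)} "
                f"peak sets x {len(self.expansion_order)} expansions), got {len(self.cells)}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per cell, with supplementary BH q-values.

        The Benjamini-Hochberg column is informational only; the heatmap and
        the primary p_value column stay uncorrected raw p-values.
        """
        rows = [
            {
                "gene_set": c.gene_set_name,
                "peak_set": c.peak_set_name,
                "expansion": c.expansion,
                "M": c.M,
                "Nc": c.Nc,
                "Np": c.Np,
                "n_pc": c.n_pc,
                "p_value": c.p_value,
                "neg_log10_p": c.neg_log10_p,
            }
            for c in self.cells
        ]
        df = pd.DataFrame(rows)
        df["bh_q"] = false_discovery_control(df["p_value"].clip(upper=1.0), method="bh")
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    def cell(self, gene_set: str, peak_set: str, expansion: str) -> EnrichmentCell:
        for c in self.cells:
            if (
                c.gene_set_name == gene_set
                and c.peak_set_name == peak_set
                and c.expansion == expansion
            ):
                return c
        raise KeyError((gene_set, peak_set, expansion))


def load_gene_set(path, name: Optional[str] = None) -> GeneSet:
    """Load a gene set from plain text, one symbol per line.

    Blank lines and lines starting with ``#`` are ignored; the set name
    defaults to the file basename without extension.
    """
    from pathlib import Path

    if name is None:
        name = Path(path).stem
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    if not genes:
        raise PeakgeneError(f"empty gene set file: {path}")
    return GeneSet(name, genes)


def write_gene_set(gene_set: GeneSet, path) -> None:
    """Write one symbol per line, sorted for determinism."""
    with open(path, "w") as fh:
        for g in sorted(gene_set.genes):
            fh.write(g + "\n")


def load_background(path) -> frozenset[str]:
    """Load a background gene population (same format as a gene set file)."""
    return load_gene_set(path, name="background").genes


def run_enrichment(
    gene_sets: Sequence[GeneSet],
    peak_sets: Sequence[PeakSet],
    expansions: Sequence[ExpansionSpec],
    ref: TssReference,
    tads: Optional[TadSet] = None,
    background: Optional[Iterable[str]] = None,
) -> EnrichmentMatrix:
    """Compute the full (gene set x peak set x expansion) enrichment grid.

    For every peak set and expansion rule the peaks are expanded, intersected
    with the TSS reference, and each gene set is tested against the resulting
    overlap genes with the upper-tail hypergeometric statistic.  When a
    ``background`` is given, the universe is restricted to
    ``background ∩ reference universe`` and all gene and overlap sets are
    intersected with it, so ``M`` reflects the user's population.

    Cell order is deterministic: peak sets, then expansions, then gene sets,
    each in input order.
    """
    if not gene_sets or not peak_sets or not expansions:
        raise ConfigError("need at least one gene set, one peak set and one expansion")
    if any(e.is_tad for e in expansions) and tads is None:
        raise ConfigError("TAD expansion requested but no TAD set was provided")

    universe: frozenset[str] = ref.universe
    if background is not None:
        background = frozenset(g.strip() for g in background if g.strip())
        restricted = universe & background
        if not restricted:
            raise ConfigError("background shares no genes with the reference universe")
        dropped = len(universe) - len(restricted)
        if dropped:
            logger.info(
                "background restriction: universe reduced from %d to %d genes",
                len(universe), len(restricted),
            )
        universe = restricted
    M = len(universe)

    cells: list[EnrichmentCell] = []
    for peaks in peak_sets:
        for expansion in expansions:
            regions = expand_peak_set(peaks, expansion, tads)
            overlap = overlapping_genes(regions, ref) & universe
            for gs in gene_sets:
                restricted_genes = gs.genes & universe
                if not restricted_genes:
                    logger.warning(
                        "gene set %r is empty within the universe; "
                        "reporting degenerate cell with p = 1",
                        gs.name,
                    )
                    Nc, Np, n_pc, log_p = 0, len(overlap), 0, 0.0
                else:
                    eff = GeneSet(gs.name, restricted_genes)
                    Nc, Np, n_pc = effective_counts(eff, overlap, universe)
                    if Np == 0:
                        logger.warning(
                            "peak set %r at expansion %s overlaps no gene TSS; p = 1",
                            peaks.name, expansion.label,
                        )
                        log_p = 0.0
                    else:
                        log_p = hypergeom_log_tail(M, Nc, Np, n_pc)
                cells.append(
                    EnrichmentCell(
                        gene_set_name=gs.name,
                        peak_set_name=peaks.name,
                        expansion=expansion.label,
                        M=M,
                        Nc=Nc,
                        Np=Np,
                        n_pc=n_pc,
                        p_value=float(math.exp(log_p)),
                        log_p=log_p,
                    )
                )
    return EnrichmentMatrix(
        cells=cells,
        gene_set_order=[g.name for g in gene_sets],
        peak_set_order=[p.name for p in peak_sets],
        expansion_order=[e.label for e in expansions],
    )
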