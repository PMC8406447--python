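"""End-to-end workflows tying the modules together.

These functions are the package's operational surface — one per capability:

* :func:`run` — the full enrichment workflow: load a TSS reference, peak
  sets, gene sets and optional TADs/background, compute the enrichment grid
  and write the tidy TSV plus the combined heatmap;
* :func:`make_tss` — build a reusable TSS BED from a refGene-style table;
* :func:`make_fixture_files` — emit a synthetic dataset to disk;
* :func:`tissue_sets` — build tissue-specific gene lists from an expression
  matrix.

Outputs are written to a temporary name and moved into place on success, so
a failing run never leaves partial files behind.  Identical configuration
and inputs give byte-identical TSVs.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import tissue as tissue_mod
from .enrichment import (
    EnrichmentMatrix,
    GeneSet,
    load_background,
    load_gene_set,
    run_enrichment,
    write_gene_set,
)
from .errors import ConfigError
from .fixtures import Fixture, FixtureSpec, make_fixture, write_fixture
from .intervals import ExpansionSpec, load_peaks_bed, load_tads_bed
from .reference import build_tss_reference, load_reference, write_tss_bed
from .viz import HeatmapConfig, render_heatmap

logger = logging.getLogger(__name__)

_SUFFIX_SCALE = {"k": 1_000, "m": 1_000_000}


def parse_distance(text: Union[str, int]) -> ExpansionSpec:
    """Parse a distance spec: plain bp, k/M suffixed ('5k' = 5000), or 'tads'."""
    if isinstance(text, int):
        return ExpansionSpec.distance(text)
    t = text.strip()
    if t.lower() in ("tad", "tads"):
        return ExpansionSpec.tads()
    scale = 1
    if t and t[-1].lower() in _SUFFIX_SCALE:
        scale = _SUFFIX_SCALE[t[-1].lower()]
        t = t[:-1]
    try:
        value = float(t) if "." in t else int(t)
    except ValueError:
        raise ConfigError(f"cannot parse distance {text!r}") from None
    bp = int(round(value * scale))
    if bp < 0:
        raise ConfigError(f"distance must be >= 0, got {text!r}")
    return ExpansionSpec.distance(bp)


def _named_path(entry: Union[str, Path, tuple[str, Union[str, Path]]]):
    """Accept 'name=path' strings, (name, path) pairs, or bare paths."""
    if isinstance(entry, tuple):
        return entry[0], Path(entry[1])
    entry = str(entry)
    if "=" in entry:
        name, _, p = entry.partition("=")
        return name, Path(p)
    return None, Path(entry)


@dataclass
class RunConfig:
    """Configuration of one enrichment run.

    ``peaks`` and ``gene_sets`` entries may be bare paths (display name =
    file basename), ``name=path`` strings, or ``(name, path)`` pairs.
    ``distances`` entries are bp integers or suffixed strings ('5k', '1M');
    include ``'tads'`` (with ``tad_file``) for TAD-constrained expansion.
    """

    tss_reference: Union[str, Path]
    peaks: Sequence[Union[str, Path, tuple]]
    gene_sets: Sequence[Union[str, Path, tuple]]
    distances: Sequence[Union[str, int]]
    out_dir: Union[str, Path] = "."
    tad_file: Optional[Union[str, Path]] = None
    background_file: Optional[Union[str, Path]] = None
    heatmap: HeatmapConfig = field(default_factory=HeatmapConfig)


@dataclass(frozen=True)
class RunResult:
    matrix: EnrichmentMatrix
    tsv_path: Path
    heatmap_path: Path


def run(config: RunConfig) -> RunResult:
    """Execute the full enrichment workflow and write TSV + heatmap.

    Validates the configuration (files present, at least one of each input,
    TAD expansion only with a TAD file) before any computation; on error no
    output files are produced.
    """
    if not config.peaks or not config.gene_sets or not config.distances:
        raise ConfigError("need at least one peak file, one gene set and one distance")
    expansions = [parse_distance(d) for d in config.distances]
    if any(e.is_tad for e in expansions) and config.tad_file is None:
        raise ConfigError("'tads' expansion requested but no TAD file given")

    for entry in list(config.peaks) + list(config.gene_sets):
        _, p = _named_path(entry)
        if not p.exists():
            raise ConfigError(f"input file not found: {p}")
    for p in (config.tss_reference, config.tad_file, config.background_file):
        if p is not None and not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")

    ref = load_reference(config.tss_reference)
    peak_sets = [load_peaks_bed(p, name=n) for n, p in map(_named_path, config.peaks)]
    gene_sets = [load_gene_set(p, name=n) for n, p in map(_named_path, config.gene_sets)]
    tads = load_tads_bed(config.tad_file) if config.tad_file is not None else None
    background = (
        load_background(config.background_file)
        if config.background_file is not None
        else None
    )

    matrix = run_enrichment(gene_sets, peak_sets, expansions, ref, tads, background)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "enrichment.tsv"
    fig_path = out_dir / f"enrichment_heatmap.{config.heatmap.fmt}"
    with tempfile.TemporaryDirectory(dir=out_dir) as tmp:
        tmp_tsv = Path(tmp) / tsv_path.name
        matrix.write_tsv(tmp_tsv)
        tmp_fig = render_heatmap(matrix, config.heatmap, Path(tmp) / fig_path.name)
        os.replace(tmp_tsv, tsv_path)
        os.replace(tmp_fig, fig_path)
    logger.info("wrote %s and %s (%d cells)", tsv_path, fig_path, len(matrix.cells))
    return RunResult(matrix, tsv_path, fig_path)


def make_tss(refgene_table: Union[str, Path], out_bed: Union[str, Path]) -> Path:
    """Build a TSS reference BED from a refGene-style table (done once per genome)."""
    ref = build_tss_reference(refgene_table)
    out_bed = Path(out_bed)
    out_bed.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=out_bed.parent, suffix=".tmp")
    os.close(fd)
    try:
        write_tss_bed(ref, tmp)
        os.replace(tmp, out_bed)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return out_bed


def make_fixture_files(seed: int, out_dir: Union[str, Path], **spec_kwargs) -> Fixture:
    """Generate a synthetic dataset and write it to ``out_dir``.

    Extra keyword arguments override :class:`FixtureSpec` defaults.
    """
    fixture = make_fixture(FixtureSpec(seed=seed, **spec_kwargs))
    write_fixture(fixture, out_dir)
    return fixture


def tissue_sets(
    matrix_path: Union[str, Path],
    out_dir: Union[str, Path],
    fold: float = tissue_mod.DEFAULT_FOLD,
) -> dict[str, Path]:
    """Build one tissue-specific gene-list file per tissue.

    Each output file is named after its tissue (spaces replaced by
    underscores) and can be fed directly to :func:`run` as a gene set.
    """
    expr = tissue_mod.load_expression_matrix(matrix_path)
    sets = tissue_mod.all_tissue_sets(expr, fold=fold)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, gs in sets.items():
        p = out_dir / (name.replace(" ", "_") + ".txt")
        write_gene_set(gs, p)
        paths[name] = p
    return paths
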