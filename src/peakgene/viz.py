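"""Combined enrichment heatmaps: colour = -log10(p), annotation = n_pc.

One panel is drawn per peak set; rows are the expansions in input order with
the TAD row last, columns are the gene sets in input order.  The colour
scale is shared across panels of a figure so they are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .enrichment import EnrichmentMatrix
from .errors import PeakgeneError
from .intervals import ExpansionSpec

_FORMATS = frozenset({"png", "svg", "pdf"})


@dataclass(frozen=True)
class HeatmapConfig:
    """Display options for :func:`render_heatmap`.

    ``cap`` bounds the displayed -log10(p) (default 300, the double-precision
    underflow limit); the TSV keeps the exact log-space value.
    """

    colormap: str = "rocket_r"
    annotate: bool = True
    fmt: str = "png"
    cap: float = 300.0

    def __post_init__(self):
        if self.cap <= 0:
            raise ValueError(f"display cap must be > 0, got {self.cap}")
        if self.fmt not in _FORMATS:
            raise PeakgeneError(
                f"unknown output format {self.fmt!r}; choose from {sorted(_FORMATS)}"
            )


def _expansion_display(label: str) -> str:
    if label == "TAD":
        return "TAD"
    return ExpansionSpec.distance(int(label)).display_label


def _panel_frames(matrix: EnrichmentMatrix, cap: float):
    """Per-peak-set (scores, counts) frames; rows = expansions, TAD last."""
    df = matrix.to_frame()
    expansions = sorted(matrix.expansion_order, key=lambda e: e == "TAD")
    panels = []
    for peak_set in matrix.peak_set_order:
        sub = df[df["peak_set"] == peak_set]
        score = sub.pivot(index="expansion", columns="gene_set", values="neg_log10_p")
        count = sub.pivot(index="expansion", columns="gene_set", values="n_pc")
        score = score.reindex(index=expansions, columns=matrix.gene_set_order)
        count = count.reindex(index=expansions, columns=matrix.gene_set_order)
        score = score.clip(upper=cap)
        score.index = [_expansion_display(e) for e in score.index]
        count.index = score.index
        panels.append((peak_set, score, count))
    return panels


def build_heatmap_figure(matrix: EnrichmentMatrix, config: HeatmapConfig):
    """Build the heatmap figure without writing it (useful interactively).

    Rendering is a pure function of ``(matrix, config)``: identical inputs
    give identical figure layout and cell annotations.
    """
    if not matrix.cells:
        raise PeakgeneError("cannot render an empty enrichment matrix")
    panels = _panel_frames(matrix, config.cap)
    vmax = max(1e-9, max(float(np.nanmax(score.to_numpy())) for _, score, _ in panels))

    n_panels = len(panels)
    n_rows = len(matrix.expansion_order)
    n_cols = len(matrix.gene_set_order)
    fig_w = max(4.0, 1.1 * n_cols + 2.5)
    fig_h = max(2.5, (0.6 * n_rows + 1.2) * n_panels)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(fig_w, fig_h), squeeze=False, constrained_layout=True
    )
    for ax, (peak_set, score, count) in zip(axes[:, 0], panels):
        sns.heatmap(
            score,
            ax=ax,
            cmap=config.colormap,
            vmin=0.0,
            vmax=vmax,
            annot=count.to_numpy() if config.annotate else False,
            fmt="d" if config.annotate else "",
            cbar_kws={"label": r"$-\log_{10}(p)$"},
            linewidths=0.5,
            linecolor="white",
        )
        ax.set_title(peak_set)
        ax.set_xlabel("gene set")
        ax.set_ylabel("expansion")
        ax.tick_params(axis="x", rotation=45)
    return fig


def render_heatmap(matrix: EnrichmentMatrix, config: HeatmapConfig, path) -> Path:
    """Render the combined heatmap to ``path``; returns the written path."""
    fig = build_heatmap_figure(matrix, config)
    path = Path(path)
    if path.suffix.lstrip(".").lower() != config.fmt:
        path = path.with_suffix("." + config.fmt)
    fig.savefig(path, format=config.fmt, dpi=150)
    plt.close(fig)
    return path
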