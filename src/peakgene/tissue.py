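"""Tissue-specific gene lists from a gene x tissue expression matrix.

Emulates the GTEx-style workflow: given median TPM per gene per tissue, a
gene is called specific to a tissue when its expression there exceeds
``fold`` times the arithmetic mean of its medians over all other tissues
(strict inequality).  Genes expressed only in the target tissue (zero mean
elsewhere) are included — they are the most tissue-specific genes of all.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .enrichment import GeneSet
from .errors import PeakgeneError

DEFAULT_FOLD = 5.0


def load_expression_matrix(path) -> pd.DataFrame:
    """Load a tab-delimited gene x tissue matrix of median TPM values.

    First column: gene symbol (becomes the index); header row: tissue names.
    Gzip is accepted (pandas infers compression).  Duplicate gene or tissue
    labels and negative values are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise PeakgeneError(f"empty expression matrix: {path}")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise PeakgeneError(f"duplicate gene symbols in {path}: {dupes}")
    if df.columns.duplicated().any():
        raise PeakgeneError(f"duplicate tissue labels in {path}")
    if (df.to_numpy() < 0).any():
        raise PeakgeneError(f"negative expression values in {path}")
    df.index = df.index.astype(str).str.strip()
    return df


def tissue_specific_genes(
    expr: pd.DataFrame, tissue: str, fold: float = DEFAULT_FOLD
) -> GeneSet:
    """Genes with ``expr[g, tissue] > fold * mean(expr[g, other tissues])``.

    Parameters
    ----------
    expr : DataFrame
        Gene x tissue matrix (genes as index), median TPM.
    tissue : str
        Target tissue column.
    fold : float
        Fold-change threshold (default 5.0); strict inequality.
    """
    if expr.shape[1] < 2:
        raise PeakgeneError("need at least 2 tissues to define tissue specificity")
    if tissue not in expr.columns:
        raise PeakgeneError(f"unknown tissue {tissue!r}")
    if fold <= 0:
        raise ValueError(f"fold threshold must be > 0, got {fold}")
    target = expr[tissue]
    rest_mean = expr.drop(columns=[tissue]).mean(axis=1)
    # With a zero mean elsewhere the comparison reduces to target > 0,
    # which is exactly the inclusion rule for exclusively-expressed genes.
    mask = target > fold * rest_mean
    genes = expr.index[mask].tolist()
    if not genes:
        raise PeakgeneError(
            f"no genes pass the {fold}x specificity threshold for {tissue!r}"
        )
    return GeneSet(tissue, genes)


def all_tissue_sets(
    expr: pd.DataFrame, fold: float = DEFAULT_FOLD, skip_empty: bool = True
) -> dict[str, GeneSet]:
    """One gene set per tissue; tissues with no passing gene are skipped."""
    out: dict[str, GeneSet] = {}
    for tissue in expr.columns:
        try:
            out[tissue] = tissue_specific_genes(expr, tissue, fold)
        except PeakgeneError:
            if not skip_empty:
                raise
    return out
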