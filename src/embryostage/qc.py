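"""Cell- and sample-level quality control, normalization, and stage averaging.

The droplet filters follow the strict reading of their defining thresholds:
cells with *fewer than* `min_genes_per_cell` detected genes or *more than*
`max_mito_fraction` mitochondrial counts are removed, so cells sitting
exactly on either boundary are kept. A detected gene is any gene with
count > 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import (
    CellCountMatrix,
    ExpressionMatrix,
    LOG_SCALES,
    ScaleWarning,
    StageReference,
)

logger = logging.getLogger("embryostage")


@dataclass
class QcThresholds:
    """Quality-control thresholds for droplet cells and embryo profiles.

    Attributes
    ----------
    min_genes_per_cell : int
        Minimum detected genes (count > 0) for a droplet cell to be kept.
    max_mito_fraction : float
        Maximum tolerated fraction of counts on mitochondrial genes.
    scale_factor : float
        Per-cell library-size target for log-normalization.
    embryo_min_genes : int
        Minimum number of genes above `embryo_expr_cutoff` for an embryo
        profile to be kept.
    embryo_expr_cutoff : float
        log2 expression level defining an "expressed" gene for embryo QC.
    """

    min_genes_per_cell: int = 3000
    max_mito_fraction: float = 0.10
    scale_factor: float = 10_000.0
    embryo_min_genes: int = 6000
    embryo_expr_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def cell_qc_stats(counts: CellCountMatrix) -> pd.DataFrame:
    """Per-cell detected-gene counts and mitochondrial fractions."""
    csc = counts.counts
    n_genes = np.asarray((csc > 0).sum(axis=0)).ravel()
    totals = np.asarray(csc.sum(axis=0)).ravel().astype(float)
    mito_totals = np.asarray(csc[counts.mito_mask].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_totals / np.maximum(totals, 1e-300), 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes.astype(int), "mito_fraction": mito_frac},
        index=pd.Index(counts.barcodes, name="barcode"),
    )


def filter_cells(
    counts: CellCountMatrix, thresholds: QcThresholds | None = None
) -> tuple[CellCountMatrix, pd.DataFrame]:
    """Remove low-complexity and high-mitochondrial droplet cells.

    Returns the filtered matrix and a per-cell report with columns
    ``n_genes``, ``mito_fraction`` and ``passed`` covering every input cell.
    Removing all cells yields an empty matrix with a warning, not an error.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if counts.shape[1] == 0:
        raise ValueError("count matrix has no cells")
    report = cell_qc_stats(counts)
    passed = (report["n_genes"] >= thresholds.min_genes_per_cell) & (
        report["mito_fraction"] <= thresholds.max_mito_fraction
    )
    report = report.assign(passed=passed)
    if not passed.any():
        warnings.warn("all cells removed by QC thresholds", stacklevel=2)
    kept = counts.subset_cells(passed.to_numpy())
    logger.info("QC retained %d / %d cells", kept.shape[1], counts.shape[1])
    return kept, report


def normalize_lognorm(
    counts: CellCountMatrix, scale_factor: float = 10_000.0
) -> ExpressionMatrix:
    """Library-size normalize and natural-log transform droplet counts.

    value(g, c) = ln(1 + count(g, c) / total(c) * scale_factor). The sparsity
    pattern is preserved (zero counts map to zero values). A cell with zero
    total counts is an error naming its barcode.
    """
    csc = counts.counts.astype(float).copy()
    totals = np.asarray(csc.sum(axis=0)).ravel()
    if (totals <= 0).any():
        bad = counts.barcodes[int(np.argmax(totals <= 0))]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    # scale each column, then log1p the stored entries only
    inv = scale_factor / totals
    csc = csc.multiply(np.broadcast_to(inv, (1, len(inv)))).tocsc()
    csc.data = np.log1p(csc.data)
    dense = pd.DataFrame(
        csc.toarray(), index=counts.feature_ids, columns=counts.barcodes
    )
    return ExpressionMatrix(dense, "lognorm")


def _warn_if_not_log(m: ExpressionMatrix, op: str) -> None:
    if m.scale not in LOG_SCALES:
        warnings.warn(
            f"{op} expects log-scale values but matrix scale is {m.scale!r}",
            ScaleWarning,
            stacklevel=3,
        )


def filter_expressed_genes(
    m: ExpressionMatrix, cutoff: float = 0.0, min_samples: int = 1
) -> ExpressionMatrix:
    """Keep genes with expression strictly above `cutoff` in >= `min_samples` columns."""
    _warn_if_not_log(m, "filter_expressed_genes")
    n_above = (m.values.to_numpy() > cutoff).sum(axis=1)
    keep = n_above >= min_samples
    logger.info("expressed-gene filter retained %d / %d genes", int(keep.sum()), len(keep))
    return ExpressionMatrix(m.values.loc[keep].copy(), m.scale)


def filter_embryo_cells(
    m: ExpressionMatrix, thresholds: QcThresholds | None = None
) -> ExpressionMatrix:
    """Exclude embryo profiles expressing fewer than `embryo_min_genes` genes
    above `embryo_expr_cutoff` (log2 scale); the boundary count is kept."""
    if thresholds is None:
        thresholds = QcThresholds()
    _warn_if_not_log(m, "filter_embryo_cells")
    n_expr = (m.values.to_numpy() > thresholds.embryo_expr_cutoff).sum(axis=0)
    keep = n_expr >= thresholds.embryo_min_genes
    logger.info("embryo QC retained %d / %d profiles", int(keep.sum()), len(keep))
    return ExpressionMatrix(m.values.loc[:, keep].copy(), m.scale)


def average_by_group(
    m: ExpressionMatrix,
    groups: Mapping[str, str] | pd.Series,
    order: Sequence[str] | None = None,
) -> StageReference:
    """Average samples by group label on the stored scale.

    `groups` maps sample id -> label; `order` fixes the stage column order
    (labels absent from the data are dropped with a warning).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = set(m.sample_ids) - set(groups.index)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
    labels = groups.loc[m.sample_ids]
    present = pd.unique(labels)
    if order is None:
        order = list(present)
    used = []
    for lab in order:
        if lab in set(present):
            used.append(lab)
        else:
            warnings.warn(f"group {lab!r} has no member samples; dropped", stacklevel=2)
    cols = {lab: m.values.loc[:, labels[labels == lab].index].mean(axis=1) for lab in used}
    ref = pd.DataFrame(cols, index=m.values.index)[used]
    return StageReference(ref, m.scale)
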