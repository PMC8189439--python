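"""In-memory containers for expression data, gene sets, and stage references.

Gene and sample identifiers are opaque strings matched exactly and
case-sensitively everywhere in the package; no symbol/ID translation is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

#: Recognised value scales for expression matrices.
SCALES = ("counts", "fpkm", "log2fpkm", "lognorm")
#: Scales on which values are logarithms (may legitimately be negative).
LOG_SCALES = ("log2fpkm", "lognorm")


class ScaleWarning(UserWarning):
    """Raised as a warning when an operation receives data on an unexpected scale."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class ExpressionMatrix:
    """Dense gene x sample expression matrix with a value-scale tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows, samples in columns. Index/columns carry identifiers.
    scale : str
        One of :data:`SCALES`. Determines sign constraints (counts and fpkm
        must be non-negative) and how downstream operations de-log values.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.scale in ("counts", "fpkm") and (arr < 0).any():
            raise ValueError(f"negative values not allowed on scale {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return the sub-matrix for `genes` (order as given; all must exist)."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.scale)

    def delogged(self) -> np.ndarray:
        """Values on the linear scale (2**x for log2fpkm, expm1 for lognorm)."""
        arr = self.values.to_numpy()
        if self.scale == "log2fpkm":
            return np.exp2(arr)
        if self.scale == "lognorm":
            return np.expm1(arr)
        return arr


@dataclass
class StageReference:
    """Gene x stage matrix of stage-averaged profiles with an ordered stage axis.

    Column order is the developmental order used for tie-breaking in staging.
    """

    values: pd.DataFrame
    scale: str = "log2fpkm"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "stage")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("stage reference values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CellCountMatrix:
    """Sparse gene x cell integer count matrix with barcodes and feature IDs."""

    counts: sparse.spmatrix
    barcodes: list[str]
    feature_ids: list[str]
    mito_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sparse.csc_matrix(self.counts)
        n_genes, n_cells = self.counts.shape
        if len(self.feature_ids) != n_genes:
            raise ValueError(
                f"feature list length {len(self.feature_ids)} != matrix rows {n_genes}"
            )
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"barcode list length {len(self.barcodes)} != matrix columns {n_cells}"
            )
        _check_unique(self.barcodes, "barcode")
        if self.mito_mask is None:
            self.mito_mask = np.zeros(n_genes, dtype=bool)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if self.mito_mask.shape != (n_genes,):
            raise ValueError("mito_mask length must equal gene count")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_cells(self, keep: np.ndarray) -> "CellCountMatrix":
        """Return the matrix restricted to a boolean/index cell selection."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CellCountMatrix(
            self.counts[:, idx],
            [self.barcodes[i] for i in idx],
            list(self.feature_ids),
            self.mito_mask.copy(),
        )


@dataclass
class GeneSet:
    """Named gene list, optionally directional, with free-text provenance."""

    name: str
    genes: tuple[str, ...]
    direction: str = "unsigned"  # up | down | unsigned
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down", "unsigned"):
            raise ValueError(f"bad direction {self.direction!r}")
        # empty sets are tolerated here (a threshold can select nothing);
        # file readers reject empty sets at parse time
        self.genes = tuple(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, universe: Sequence[str]) -> "GeneSet":
        """Restrict to genes present in `universe`, preserving set order."""
        present = set(universe)
        kept = tuple(g for g in self.genes if g in present)
        if not kept:
            raise ValueError(f"gene set {self.name!r} has no genes in the matrix")
        return GeneSet(self.name, kept, self.direction, self.provenance)


def validate_metadata(meta: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Validate a sample-metadata table (columns: sample_id, condition, day, stage, replicate).

    Every sample of `matrix` (if given) must have exactly one row.
    """
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    _check_unique(meta["sample_id"], "sample")
    if matrix is not None:
        missing = set(matrix.sample_ids) - set(meta["sample_id"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    return meta
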