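"""Readers and writers for the delimited-text, sparse-triplet and gene-set
formats the pipeline consumes, plus YAML run configuration.

All tabular IO is delimited text (TSV/CSV autodetected by extension); droplet
counts use the coordinate sparse-matrix triplet dialect with companion
barcodes/features files, gzipped or plain.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .matrix import CellCountMatrix, ExpressionMatrix, GeneSet, StageReference

logger = logging.getLogger("embryostage")


class ParseError(ValueError):
    """A malformed cell or record in an input file."""


def setup_logging(level: str = "INFO") -> None:
    """Configure structured log lines to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("embryostage")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith((".csv", ".csv.gz")) else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "genes_in_rows",
    scale: str = "log2fpkm",
) -> ExpressionMatrix:
    """Read a delimited expression table into a genes x samples matrix.

    Parameters
    ----------
    orientation : {"genes_in_rows", "samples_in_rows"}
        Layout of the file; the returned matrix is always genes x samples.
    scale : str
        Value scale tag recorded on the matrix. Duplicate gene rows are
        collapsed by summation for counts and by mean otherwise, with a
        logged warning; duplicate sample identifiers are an error.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"bad orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples_in_rows":
        df = df.T
    # locate non-numeric cells before coercion so the error names them
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            bad = df.index[coerced.isna()][0]
            raise ParseError(
                f"non-numeric value at gene {bad!r}, sample {col!r} in {path.name}"
            )
        df[col] = coerced
    if df.isna().to_numpy().any():
        raise ParseError(f"missing values in {path.name}; imputation is not supported")
    if pd.Index(df.columns).has_duplicates:
        dupes = pd.Index(df.columns)
        raise ParseError(
            f"duplicate sample identifiers: {dupes[dupes.duplicated()].unique().tolist()[:5]}"
        )
    if pd.Index(df.index).has_duplicates:
        how = "sum" if scale == "counts" else "mean"
        n = int(pd.Index(df.index).duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by %s in %s", n, how, path.name)
        df = df.groupby(level=0, sort=False).agg(how)
    df = df.astype(float)
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df, scale)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def write_stage_reference(ref: StageReference, path: str | Path) -> None:
    path = Path(path)
    ref.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_stage_reference(path: str | Path, scale: str = "log2fpkm") -> StageReference:
    """Read a gene x stage table; column order is taken as the stage order."""
    m = read_expression_table(path, "genes_in_rows", scale)
    return StageReference(m.values, scale)


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_triplet_file(directory: Path, stems: Iterable[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {list(stems)} (optionally .gz) found in {directory}"
    )


def read_sparse_counts(directory: str | Path) -> CellCountMatrix:
    """Read a 10x-style triplet directory (matrix.mtx + barcodes + features).

    Duplicate (gene, cell) triplets are summed, the coordinate-format
    convention. The mitochondrial mask is set from a case-insensitive "MT-"
    prefix on the gene symbol (second features column, falling back to the
    first).
    """
    directory = Path(directory)
    mtx_path = _find_triplet_file(directory, ["matrix.mtx"])
    bc_path = _find_triplet_file(directory, ["barcodes.tsv"])
    ft_path = _find_triplet_file(directory, ["features.tsv", "genes.tsv"])

    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:  # re-raise as a format error naming the file
        raise ParseError(f"malformed sparse matrix file {mtx_path.name}: {exc}") from exc
    counts = sparse.csc_matrix(mat)  # duplicates summed on conversion

    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]
    with _open_maybe_gz(ft_path) as fh:
        feat_rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    feature_ids = [r[0] for r in feat_rows]
    symbols = [r[1] if len(r) > 1 else r[0] for r in feat_rows]

    if counts.shape[0] != len(feature_ids):
        raise ParseError(
            f"matrix has {counts.shape[0]} rows but features file lists {len(feature_ids)}"
        )
    if counts.shape[1] != len(barcodes):
        raise ParseError(
            f"matrix has {counts.shape[1]} columns but barcodes file lists {len(barcodes)}"
        )
    mito = np.array([s.upper().startswith("MT-") for s in symbols], dtype=bool)
    return CellCountMatrix(counts, barcodes, feature_ids, mito)


def write_sparse_counts(counts: CellCountMatrix, directory: str | Path,
                        symbols: Sequence[str] | None = None) -> None:
    """Write a triplet directory (plain text) readable by :func:`read_sparse_counts`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(directory / "matrix.mtx"), sparse.coo_matrix(counts.counts))
    (directory / "barcodes.tsv").write_text("\n".join(counts.barcodes) + "\n")
    if symbols is None:
        symbols = counts.feature_ids
    lines = [f"{fid}\t{sym}" for fid, sym in zip(counts.feature_ids, symbols)]
    (directory / "features.tsv").write_text("\n".join(lines) + "\n")


def _parse_direction(name: str) -> tuple[str, str]:
    for suffix, direction in ((":up", "up"), (":down", "down")):
        if name.endswith(suffix):
            return name[: -len(suffix)], direction
    return name, "unsigned"


def _dedup(name: str, genes: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in genes:
        if g in seen:
            logger.warning("gene %s listed twice in set %s; deduplicated", g, name)
        seen[g] = None
    return tuple(seen)


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (``name<TAB>desc<TAB>gene...``) or two-column TSV.

    Set order is preserved; an optional ``:up``/``:down`` suffix on the set
    name is parsed as the direction. Duplicate genes within a set are
    deduplicated with a warning; an empty set is an error naming the set.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    if path.suffix == ".gmt":
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                raw_name, desc = fields[0], fields[1] if len(fields) > 1 else ""
                genes = [g for g in fields[2:] if g]
                name, direction = _parse_direction(raw_name)
                if not genes:
                    raise ParseError(f"gene set {name!r} in {path.name} is empty")
                sets.append(GeneSet(name, _dedup(name, genes), direction, desc))
    else:
        df = pd.read_csv(path, sep=_sep_for(path), header=None, names=["set", "gene"])
        if df["gene"].isna().any():
            bad = df["set"][df["gene"].isna()].iloc[0]
            raise ParseError(f"gene set {bad!r} in {path.name} has an empty gene field")
        for raw_name in pd.unique(df["set"]):
            genes = df.loc[df["set"] == raw_name, "gene"].tolist()
            name, direction = _parse_direction(str(raw_name))
            sets.append(GeneSet(name, _dedup(name, genes), direction, f"from {path.name}"))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for s in sets:
            name = s.name if s.direction == "unsigned" else f"{s.name}:{s.direction}"
            fh.write("\t".join([name, s.provenance or "."] + list(s.genes)) + "\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read an externally produced DE table (gene_id, log2fc, padj, base_mean)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"DE table {path.name} missing columns: {sorted(missing)}")
    if "base_mean" not in df.columns:
        df["base_mean"] = np.nan
    if df["gene_id"].duplicated().any():
        raise ParseError(f"DE table {path.name} has duplicate gene rows")
    if ((df["padj"] <= 0) | (df["padj"] > 1)).any():
        raise ParseError(f"DE table {path.name}: padj must lie in (0, 1]")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML run-configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"configuration {path} must be a YAML mapping")
    return cfg
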