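"""Reading/writing the standard formats used across the pipeline.

Count matrices travel as Matrix Market ``.mtx`` files (genes as rows, cells
as columns, 1-based indices on disk) with ``genes.tsv`` / ``cells.tsv``
sidecars, one identifier per line, in matrix order.  Gene sets use the GMT
format.  Normalization is counts-per-``scale`` followed by ``log1p``, the
de-facto convention for droplet scRNA-seq counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._utils import FormatError, ValidationError, logger

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSetCollection",
    "TISSUES",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "normalize",
]

#: Recognized tissue labels: bone marrow, spleen, peripheral blood,
#: G-CSF-mobilized peripheral blood, hereditary-spherocytosis spleen.
TISSUES = ("BM", "SPL", "PB", "mPB", "HS-SPL")

#: Columns every cell table carries; stage and phase may be all-NA.
CELL_TABLE_COLUMNS = ("cell_id", "donor_id", "tissue", "cluster", "stage", "phase", "library_size")


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CountMatrix:
    """Sparse gene-by-cell raw count matrix with axis labels.

    ``counts`` is a CSC matrix of nonnegative integers with one row per
    entry of ``gene_ids`` and one column per entry of ``cell_ids``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise ValidationError("counts must be nonnegative")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(np.int64)


@dataclass
class NormalizedMatrix:
    """Log-transformed library-size-normalized expression, same axes as the
    CountMatrix it came from.  Zero counts map to exactly zero."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: sp.spmatrix

    def __post_init__(self) -> None:
        self.values = sp.csc_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("values shape does not match axis labels")
        if self.values.nnz and (
            not np.all(np.isfinite(self.values.data)) or self.values.data.min() < 0
        ):
            raise ValidationError("normalized values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class GeneSetCollection:
    """Named gene sets (as from a GMT file), order-preserving."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def _read_id_column(path: Path) -> list[str]:
    """First tab-separated field of each line; tolerates extra columns."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_counts(matrix_path, genes_path, cells_path) -> CountMatrix:
    """Read an MTX count matrix with gene/cell sidecar files.

    Order of the sidecars is preserved.  Raises :class:`FormatError` naming
    the offending file on a dimension mismatch, :class:`ValidationError` on
    duplicate identifiers.
    """
    matrix_path, genes_path, cells_path = map(Path, (matrix_path, genes_path, cells_path))
    for p in (matrix_path, genes_path, cells_path):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # invalid MTX header / body
        raise FormatError(f"{matrix_path}: not a valid Matrix Market file ({exc})") from exc
    mat = sp.csc_matrix(mat)
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{genes_path}: {len(genes)} rows but matrix declares {mat.shape[0]} genes"
        )
    if len(cells) != mat.shape[1]:
        raise FormatError(
            f"{cells_path}: {len(cells)} rows but matrix declares {mat.shape[1]} cells"
        )
    return CountMatrix(gene_ids=genes, cell_ids=cells, counts=mat)


def write_counts(matrix: CountMatrix, out_dir) -> dict[str, Path]:
    """Write ``matrix.mtx``, ``genes.tsv`` and ``cells.tsv`` under *out_dir*.

    Round-trips exactly through :func:`read_counts`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "cells": out_dir / "cells.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(matrix.counts), field="integer")
    paths["genes"].write_text("".join(g + "\n" for g in matrix.gene_ids))
    paths["cells"].write_text("".join(c + "\n" for c in matrix.cell_ids))
    return paths


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene [<tab> gene ...].

    Duplicate genes within a line are dropped (first occurrence kept) with a
    logged warning; a line with fewer than three fields raises
    :class:`FormatError` with its line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("GMT set %r (line %d): dropped %d duplicate genes",
                               name, lineno, len(genes) - len(deduped))
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    return path


def concat_counts(matrices: list[CountMatrix]) -> CountMatrix:
    """Concatenate count matrices cell-wise; all must share the same genes."""
    if not matrices:
        raise ValidationError("nothing to concatenate")
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise ValidationError("count matrices have different gene axes")
    return CountMatrix(
        gene_ids=list(genes),
        cell_ids=[c for m in matrices for c in m.cell_ids],
        counts=sp.hstack([m.counts for m in matrices], format="csc"),
    )


def validate_cell_table(cells: pd.DataFrame, matrix: CountMatrix | None = None) -> pd.DataFrame:
    """Check a per-cell annotation table against its invariants.

    Required columns: cell_id, donor_id, tissue, cluster; optional: stage,
    phase, library_size.  cell_id must be unique; when *matrix* is given,
    the ids must match its cells and library_size (if present) the column
    sums.  Returns the table with optional columns filled in.
    """
    cells = cells.copy()
    for col in ("cell_id", "donor_id", "tissue", "cluster"):
        if col not in cells.columns:
            raise ValidationError(f"cell table missing column {col!r}")
    if cells["cell_id"].duplicated().any():
        dups = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()[:10]
        raise ValidationError(f"duplicate cell ids: {dups}")
    bad = sorted(set(cells["tissue"]) - set(TISSUES))
    if bad:
        raise ValidationError(f"unknown tissue labels {bad}; expected one of {TISSUES}")
    for col in ("stage", "phase"):
        if col not in cells.columns:
            cells[col] = pd.NA
    if matrix is not None:
        if list(cells["cell_id"]) != list(matrix.cell_ids):
            raise ValidationError("cell table ids do not match count matrix cells")
        lib = matrix.library_sizes()
        if "library_size" in cells.columns and cells["library_size"].notna().all():
            if not np.array_equal(cells["library_size"].to_numpy(np.int64), lib):
                raise ValidationError("library_size does not equal count-matrix column sums")
        else:
            cells["library_size"] = lib
    return cells


def read_cell_table(path) -> pd.DataFrame:
    """Read a TSV cell table and validate its basic invariants."""
    return validate_cell_table(pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cluster": str}))


def write_cell_table(cells: pd.DataFrame, path) -> Path:
    path = Path(path)
    cells.to_csv(path, sep="\t", index=False)
    return path


def normalize(matrix: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Library-size normalize then log-transform.

    value(g, c) = log(1 + count(g, c) * scale / library_size(c)).  Cells with
    zero total counts are left as all-zero columns (warned about).  Sparsity
    is preserved: zero counts map to zero values.
    """
    if scale <= 0:
        raise ValidationError("scale must be > 0")
    lib = matrix.library_sizes().astype(float)
    n_zero = int((lib == 0).sum())
    if n_zero:
        logger.warning("normalize: %d cells with zero library size left all-zero", n_zero)
    inv = np.zeros_like(lib)
    nz = lib > 0
    inv[nz] = scale / lib[nz]
    out = sp.csc_matrix(matrix.counts, dtype=float, copy=True)
    # scale each column, then log1p the stored (nonzero) entries only
    out = out @ sp.diags(inv)
    out.data = np.log1p(out.data)
    return NormalizedMatrix(gene_ids=list(matrix.gene_ids), cell_ids=list(matrix.cell_ids), values=out)
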