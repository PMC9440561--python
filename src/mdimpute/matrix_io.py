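"""Expression-matrix container, standard-format I/O, and preprocessing.

The central object is :class:`ExpressionMatrix`, a dense genes × cells matrix
with string identifiers and a *layer* tag recording where the values live:

``counts``
    Raw (or UMI) counts, nonnegative.
``cpm``
    Counts-per-million library-size normalisation: every cell column is
    rescaled to sum to 10^6.
``log``
    ``log2(cpm + theta)`` with a positive pseudo-count ``theta`` (default 1)
    that keeps zeros finite and maps them to 0.

Supported on-disk formats are Matrix Market triplets with 10x-style
``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` sidecars (optionally
gzipped), and dense CSV/TSV with gene row labels and cell column labels.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix",
    "normalize_cpm",
    "log_transform",
    "inverse_transform",
    "filter_matrix",
]

LAYERS = ("counts", "cpm", "log")
CPM_TOTAL = 1.0e6


@dataclass
class ExpressionMatrix:
    """Dense genes × cells expression matrix with identifiers and a layer tag.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Nonnegative, finite expression values.
    gene_ids, cell_ids : sequence of str
        Unique row / column identifiers.
    layer : {"counts", "cpm", "log"}
        Which scale the values are on.
    theta : float
        Pseudo-count used by the log layer; must be positive.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    layer: str = "counts"
    theta: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × cells matrix")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        # counts/cpm are nonnegative; log values may dip below zero for
        # pseudo-counts theta < 1 (log2(x + theta) < 0 when x + theta < 1)
        if self.layer != "log" and self.values.size and self.values.min() < 0:
            i, j = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise ValueError(
                f"negative entry {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, cell {self.cell_ids[j]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy(),
                       gene_ids=list(self.gene_ids), cell_ids=list(self.cell_ids))

    def validate(self) -> None:
        """Check the layer-specific invariants (cpm column sums)."""
        if self.layer == "cpm":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, CPM_TOTAL, rtol=1e-9, atol=0):
                bad = int(np.argmax(np.abs(sums - CPM_TOTAL)))
                raise ValueError(
                    f"cpm column {self.cell_ids[bad]!r} sums to {sums[bad]!r}"
                )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, layer: str = "counts",
                       theta: float = 1.0) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), layer=layer, theta=theta)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id {x!r}")
        seen.add(x)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_GENE_SIDECARS = ("genes.tsv", "genes.tsv.gz", "features.tsv", "features.tsv.gz")
_BARCODE_SIDECARS = ("barcodes.tsv", "barcodes.tsv.gz")
_META_SIDECAR = "meta.tsv"


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def _read_id_column(path: Path) -> list:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _find_sidecar(directory: Path, names: Sequence[str], what: str) -> Path:
    for name in names:
        cand = directory / name
        if cand.exists():
            return cand
    raise FileNotFoundError(
        f"missing {what} sidecar in {directory} (looked for {', '.join(names)})"
    )


def read_matrix(path, format: str = None) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``format="mtx"`` expects a Matrix Market triplet file (or a directory
    containing ``matrix.mtx``) with gene and barcode sidecar files in the
    same directory. ``csv``/``tsv`` expect gene ids in the first column and
    cell ids in the header row; an optional leading ``# layer=... theta=...``
    comment restores the layer tag written by :func:`write_matrix`.
    """
    path = Path(path)
    if format is None:
        format = _guess_format(path)
    if format == "mtx":
        return _read_mtx(path)
    if format in ("csv", "tsv"):
        return _read_delimited(path, "," if format == "csv" else "\t")
    raise ValueError(f"unknown format {format!r}; expected mtx, csv or tsv")


def _guess_format(path: Path) -> str:
    if path.is_dir() or path.suffix == ".mtx":
        return "mtx"
    if path.suffix == ".tsv":
        return "tsv"
    return "csv"


def _read_mtx(path: Path) -> ExpressionMatrix:
    if path.is_dir():
        directory, mtx_path = path, path / "matrix.mtx"
        if not mtx_path.exists():
            raise FileNotFoundError(f"no matrix.mtx in {path}")
    else:
        directory, mtx_path = path.parent, path
    genes = _read_id_column(_find_sidecar(directory, _GENE_SIDECARS, "gene"))
    cells = _read_id_column(_find_sidecar(directory, _BARCODE_SIDECARS, "barcode"))
    mat = spio.mmread(str(mtx_path))
    values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    layer, theta = _read_meta(directory / _META_SIDECAR)
    return ExpressionMatrix(values, genes, cells, layer=layer, theta=theta)


def _read_meta(path: Path):
    layer, theta = "counts", 1.0
    if path.exists():
        with open(path) as fh:
            for line in fh:
                parts = line.strip().split("\t")
                if len(parts) == 2 and parts[0] == "layer":
                    layer = parts[1]
                elif len(parts) == 2 and parts[0] == "theta":
                    theta = float(parts[1])
    return layer, theta


def _read_delimited(path: Path, sep: str) -> ExpressionMatrix:
    layer, theta = "counts", 1.0
    with _open_text(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    if key == "layer":
                        layer = val
                    elif key == "theta":
                        theta = float(val)
            df = pd.read_csv(fh, sep=sep, index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep=sep, index_col=0)
    return ExpressionMatrix.from_dataframe(df, layer=layer, theta=theta)


def write_matrix(m: ExpressionMatrix, path, format: str = None) -> None:
    """Write ``m`` so that :func:`read_matrix` reproduces it.

    For mtx, ``path`` is a directory receiving ``matrix.mtx``, ``genes.tsv``,
    ``barcodes.tsv`` and a ``meta.tsv`` recording the layer tag. For csv/tsv
    a single file is written with the layer in a leading comment line.
    """
    path = Path(path)
    if format is None:
        format = _guess_format(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(m.values))
        (path / "genes.tsv").write_text(
            "".join(f"{g}\t{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
        (path / _META_SIDECAR).write_text(
            f"layer\t{m.layer}\ntheta\t{m.theta!r}\n")
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with open(path, "w") as fh:
            fh.write(f"# layer={m.layer} theta={m.theta!r}\n")
            m.to_dataframe().to_csv(fh, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}; expected mtx, csv or tsv")


# ----------------------------------------------------------------------
# Preprocessing
# ----------------------------------------------------------------------

def normalize_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalise every cell column to one million reads.

    ``x^N_ij = x^C_ij * 10^6 / sum_k x^C_kj``. All-zero columns are an
    error; remove them first with :func:`filter_matrix`.
    """
    sums = m.values.sum(axis=0)
    if np.any(sums == 0):
        bad = int(np.argmax(sums == 0))
        raise ValueError(
            f"cell {m.cell_ids[bad]!r} has zero total counts; "
            "filter all-zero cells before normalisation"
        )
    values = m.values * (CPM_TOTAL / sums)
    return replace(m, values=values, layer="cpm",
                   gene_ids=list(m.gene_ids), cell_ids=list(m.cell_ids))


def log_transform(m: ExpressionMatrix, theta: float = None) -> ExpressionMatrix:
    """``x = log2(x + theta)`` entrywise; zeros map to 0 when theta = 1."""
    theta = m.theta if theta is None else theta
    if theta <= 0:
        raise ValueError("theta must be positive")
    if m.layer == "log":
        raise ValueError("matrix is already on the log layer")
    values = np.log2(m.values + theta)
    return replace(m, values=values, layer="log", theta=theta,
                   gene_ids=list(m.gene_ids), cell_ids=list(m.cell_ids))


def inverse_transform(m: ExpressionMatrix, theta: float = None) -> ExpressionMatrix:
    """Undo the log transform: ``2^x - theta`` clipped at zero.

    The clip guards imputed values slightly below ``log2(theta)``.
    """
    theta = m.theta if theta is None else theta
    if m.layer != "log":
        raise ValueError("inverse_transform expects a log-layer matrix")
    values = np.clip(np.exp2(m.values) - theta, 0.0, None)
    return replace(m, values=values, layer="cpm", theta=theta,
                   gene_ids=list(m.gene_ids), cell_ids=list(m.cell_ids))


def filter_matrix(m: ExpressionMatrix, min_cells_per_gene: int = 0,
                  min_genes_per_cell: int = 0) -> ExpressionMatrix:
    """Drop genes expressed in too few cells, then cells expressing too few genes.

    A value counts as "expressed" when it is strictly positive. Survivor
    order is preserved. Removing everything is an error.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("thresholds must be nonnegative")
    expressed = m.values > 0
    gene_keep = expressed.sum(axis=1) >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError("gene filter removed all genes")
    cell_keep = expressed[gene_keep].sum(axis=0) >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError("cell filter removed all cells")
    values = m.values[np.ix_(gene_keep, cell_keep)]
    return replace(
        m, values=values,
        gene_ids=[g for g, k in zip(m.gene_ids, gene_keep) if k],
        cell_ids=[c for c, k in zip(m.cell_ids, cell_keep) if k],
    )
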