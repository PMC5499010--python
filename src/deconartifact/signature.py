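"""Signature matrices (LM22-dialect TSV) and collinearity diagnostics.

A signature matrix is a genes x cell-types table of non-negative,
linear-scale reference expression profiles; it is the design matrix of the
deconvolution regression.  Collinearity between its columns (e.g. naive vs
memory B cells) is one of the two drivers of the spurious negative
correlations this package studies, so this module also quantifies how
similar the column profiles are: pairwise Pearson correlation and the
condition number of the column-standardized matrix.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SignatureMatrix",
    "CollinearityReport",
    "SignatureError",
    "read_signature_matrix",
    "write_signature_matrix",
    "pairwise_profile_correlation",
    "collinearity_diagnostics",
]


class SignatureError(ValueError):
    """Raised for malformed or degenerate signature matrices."""


@dataclasses.dataclass(frozen=True)
class SignatureMatrix:
    """Genes x cell-types reference expression matrix.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene symbols, one per row.
    cell_types : list of str
        Unique cell-type names, one per column.
    values : ndarray, shape (n_genes, n_cell_types)
        Non-negative linear-scale expression.
    """

    gene_ids: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise SignatureError(f"duplicate gene symbol(s): {', '.join(dupes)}")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise SignatureError("duplicate cell-type names")
        if values.ndim != 2 or values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise SignatureError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_types)} cell types"
            )
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise SignatureError("need at least 2 genes and 2 cell types")
        if not np.all(np.isfinite(values)):
            raise SignatureError("non-finite expression values")
        if np.any(values < 0):
            g, c = map(int, np.argwhere(values < 0)[0])
            raise SignatureError(
                f"negative expression at gene {self.gene_ids[g]!r}, "
                f"cell type {self.cell_types[c]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def column(self, key: int | str) -> np.ndarray:
        """Expression profile of one cell type, by index or name."""
        if isinstance(key, str):
            key = self.cell_types.index(key)
        return self.values[:, key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_types)


@dataclasses.dataclass(frozen=True)
class CollinearityReport:
    """Similarity diagnostics for a set of reference profiles.

    ``pairwise_r`` is the cell-type x cell-type Pearson correlation matrix of
    the column profiles (NaN where a column has zero variance);
    ``condition_number`` is the ratio of the largest to smallest singular
    value of the column-z-scored matrix, so it reflects correlation
    structure, not scale.
    """

    cell_types: list[str]
    pairwise_r: np.ndarray
    condition_number: float
    max_offdiag_r: float


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read an LM22-dialect TSV: header of cell types, one gene per row.

    The first header cell labels the gene-id column; the remaining header
    cells are cell-type names.  Values must be numeric, finite and >= 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows
        raise SignatureError(f"malformed TSV {path}: {exc}") from exc
    gene_ids = [str(g) for g in frame.index]
    dupes = frame.index[frame.index.duplicated()].unique().tolist()
    if dupes:
        raise SignatureError(f"duplicate gene symbol(s): {', '.join(map(str, dupes))}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            try:
                # float() is correctly rounded, so repr-precision payloads
                # survive a write/read cycle bit-identically
                v = float(cell)
                if not np.isfinite(v):
                    raise ValueError
            except (TypeError, ValueError):
                raise SignatureError(
                    f"non-numeric or missing value at gene "
                    f"{gene_ids[i]!r}, column {col!r}") from None
            values[i, j] = v
    return SignatureMatrix(gene_ids, [str(c) for c in frame.columns], values)


def write_signature_matrix(sig: SignatureMatrix, path: str | Path,
                           gene_column: str = "Gene symbol") -> None:
    """Write the same TSV dialect ``read_signature_matrix`` accepts.

    Floats are written at full ``repr`` precision so a read-back is
    bit-identical.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([gene_column, *sig.cell_types]) + "\n")
        for gene, row in zip(sig.gene_ids, sig.values):
            fh.write("\t".join([gene, *(repr(float(v)) for v in row)]) + "\n")


def pairwise_profile_correlation(sig: SignatureMatrix,
                                 log_scale: bool = False) -> np.ndarray:
    """Pearson correlation, across genes, between every pair of columns.

    Zero-variance columns yield NaN (undefined) off-diagonal entries rather
    than being coerced to 0.  With ``log_scale`` the correlation is computed
    on log2(x + 1)-transformed values.

    Returns the symmetric cell-type x cell-type matrix with unit diagonal.
    """
    if sig.n_genes < 3:
        raise SignatureError("need at least 3 genes for profile correlations")
    x = np.log2(sig.values + 1.0) if log_scale else sig.values
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    degenerate = sd == 0
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0, out=r)
    return r


def collinearity_diagnostics(sig: SignatureMatrix,
                             subset: list[str] | None = None) -> CollinearityReport:
    """Condition number and max |r| for a subset of reference profiles.

    Columns are z-scored (mean 0, SD 1 across genes) before the SVD, so for
    two columns with correlation r the condition number is
    sqrt((1 + |r|) / (1 - |r|)); orthogonal standardized columns give 1.
    """
    if subset is None:
        subset = list(sig.cell_types)
    if not subset:
        raise SignatureError("subset must be non-empty")
    missing = [c for c in subset if c not in sig.cell_types]
    if missing:
        raise SignatureError(f"unknown cell type(s): {', '.join(missing)}")
    idx = [sig.cell_types.index(c) for c in subset]
    x = sig.values[:, idx].astype(float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = subset[int(np.argmax(sd == 0))]
        raise SignatureError(f"zero-variance column in subset: {bad!r}")
    z = (x - x.mean(axis=0)) / sd
    s = np.linalg.svd(z, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")
    r = pairwise_profile_correlation(sig)[np.ix_(idx, idx)]
    off = r[~np.eye(len(idx), dtype=bool)]
    max_off = float(np.nanmax(np.abs(off))) if off.size else 0.0
    return CollinearityReport(list(subset), r, cond, max_off)
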