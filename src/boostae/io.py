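"""Reading and writing expression matrices, encoder weights and run logs.

Matrices are held as a cells x genes array plus identifier lists; dense
CSV/TSV (cells as rows, first column = cell id), MatrixMarket MTX with
separate row/column identifier files, and AnnData ``.h5ad`` containers are
supported.  Encoder matrices are written as dense tabular files with gene
identifiers — after highly-variable-gene selection p is small enough that
sparse storage buys nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionMatrix",
    "read_matrix",
    "write_matrix_csv",
    "write_matrix_mtx",
    "write_encoder_matrix",
    "read_encoder_matrix",
    "write_history",
]


@dataclass
class ExpressionMatrix:
    """Dense n cells x p genes values with identifiers and optional per-cell
    categorical labels and time-point assignments."""

    values: np.ndarray
    gene_ids: list
    cell_ids: list
    labels: Optional[np.ndarray] = None
    timepoints: Optional[np.ndarray] = None

    def __post_init__(self):
        n, p = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicated {name} identifiers")

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def _read_ids(path) -> list:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_matrix(path, fmt: Optional[str] = None, *, sep: str = ",",
                gene_file=None, cell_file=None, transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix; genes end up as columns.

    ``fmt`` is inferred from the suffix when omitted ('csv', 'tsv', 'mtx',
    'h5ad').  MTX input needs ``cell_file``/``gene_file`` with one
    identifier per line for the rows/columns of the stored matrix.  Set
    ``transpose=True`` when the file stores genes as rows.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv",
               ".mtx": "mtx", ".h5ad": "h5ad"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, index_col=0, sep="\t" if fmt == "tsv" else sep,
                         float_precision="round_trip")
        if transpose:
            df = df.T
        return ExpressionMatrix(df.to_numpy(dtype=float),
                                list(df.columns.astype(str)), list(df.index.astype(str)))
    if fmt == "mtx":
        M = mmread(path)
        if hasattr(M, "toarray"):
            M = M.toarray()
        M = np.asarray(M, dtype=float)
        if cell_file is None or gene_file is None:
            raise ValueError("MTX input requires cell_file and gene_file identifier lists")
        cells, genes = _read_ids(cell_file), _read_ids(gene_file)
        if transpose:
            M = M.T
        if M.shape != (len(cells), len(genes)):
            raise ValueError(f"identifier files ({len(cells)} cells, {len(genes)} genes) "
                             f"do not match matrix shape {M.shape}")
        return ExpressionMatrix(M, genes, cells)
    if fmt == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        X = adata.X
        X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
        labels = adata.obs["label"].to_numpy() if "label" in adata.obs else None
        tps = adata.obs["timepoint"].to_numpy() if "timepoint" in adata.obs else None
        return ExpressionMatrix(X.astype(float), list(adata.var_names), list(adata.obs_names),
                                labels, tps)
    raise ValueError(f"unsupported format {fmt!r}")


def write_matrix_csv(path, em: ExpressionMatrix, sep: str = ",") -> None:
    df = em.to_frame()
    if em.labels is not None:
        meta = pd.DataFrame({"label": em.labels}, index=em.cell_ids)
        meta.to_csv(Path(path).with_suffix(".labels.csv"))
    df.to_csv(path, sep=sep, float_format="%.17g")  # bitwise round-trip


def write_matrix_mtx(path, em: ExpressionMatrix) -> None:
    from scipy.sparse import csr_matrix

    path = Path(path)
    mmwrite(str(path), csr_matrix(em.values))
    path.with_suffix(".cells.txt").write_text("\n".join(map(str, em.cell_ids)) + "\n")
    path.with_suffix(".genes.txt").write_text("\n".join(map(str, em.gene_ids)) + "\n")


def write_encoder_matrix(path, B: np.ndarray, gene_ids: Sequence,
                         dim_names: Optional[Sequence] = None) -> None:
    """Dense tabular encoder matrix: rows = genes, columns = latent dimensions."""
    B = np.asarray(B)
    if dim_names is None:
        dim_names = [f"dim_{l + 1}" for l in range(B.shape[1])]
    pd.DataFrame(B, index=list(gene_ids), columns=list(dim_names)).to_csv(
        path, float_format="%.17g")


def read_encoder_matrix(path):
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.index.astype(str))


def write_history(path, history: list) -> None:
    """Tabular training log: epoch, loss, dimension, selected gene, coefficient."""
    rows = []
    for h in history:
        if not h["selections"]:
            rows.append({"epoch": h["epoch"], "loss": h["loss"]})
        for r in h["selections"]:
            rows.append({"epoch": h["epoch"], "loss": h["loss"],
                         "dimension": r["dimension"], "gene": r["gene"],
                         "coefficient": r["coefficient"],
                         "skipped": r.get("skipped", "")})
    pd.DataFrame(rows).to_csv(path, index=False)
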