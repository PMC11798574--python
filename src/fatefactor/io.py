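"""Reading and writing expression matrices and fit artifacts.

The internal orientation is always cells x genes; file writers emit cells
as rows.  Dense matrices are CSV/TSV with a header row of gene names and a
first column of cell names; sparse input is MatrixMarket plus companion
row-name / column-name text files (one id per line).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["ExpressionMatrix", "read_expression", "write_fit", "FormatError"]


class FormatError(ValueError):
    """Raised when an input file is malformed (dimension/name mismatches,
    non-numeric entries)."""


@dataclass
class ExpressionMatrix:
    """A cells x genes log-normalized expression matrix with identifiers."""

    values: np.ndarray
    cell_ids: List[str]
    gene_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise FormatError("expression matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix contains non-finite entries")
        if len(self.cell_ids) != self.values.shape[0]:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {self.values.shape[0]} rows"
            )
        if len(self.gene_ids) != self.values.shape[1]:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[1]} columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)))


def _read_names(path: str) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(path: str, fmt: str = "csv",
                    orientation: str = "cells_by_genes") -> ExpressionMatrix:
    """Read an expression matrix from CSV, TSV or MatrixMarket.

    Parameters
    ----------
    path : str
        For ``csv``/``tsv``: the table itself (first column = row names,
        header = column names).  For ``mtx``: the ``.mtx`` file;
        ``<path>.rownames`` and ``<path>.colnames`` must sit next to it.
    orientation : {"cells_by_genes", "genes_by_cells"}
        Layout of the file; the result is always cells x genes.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric entries in {path}: {exc}") from exc
        row_ids = list(df.index.astype(str))
        col_ids = list(df.columns.astype(str))
    elif fmt == "mtx":
        rn, cn = path + ".rownames", path + ".colnames"
        for companion in (rn, cn):
            if not os.path.exists(companion):
                raise FileNotFoundError(companion)
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        row_ids, col_ids = _read_names(rn), _read_names(cn)
        if len(row_ids) != values.shape[0] or len(col_ids) != values.shape[1]:
            raise FormatError(
                f"name files ({len(row_ids)} x {len(col_ids)}) do not match "
                f"matrix shape {values.shape}")
    else:
        raise ValueError(f"unknown format {fmt!r}")

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids)


def write_expression(expr: ExpressionMatrix, path: str, fmt: str = "csv") -> None:
    sep = "," if fmt == "csv" else "\t"
    expr.to_frame().to_csv(path, sep=sep)


def write_fit(outdir: str, landmarks, point_estimate, factors, tree) -> List[str]:
    """Write the artifacts of a completed fit.

    Emits landmark/cell pseudotime tables, per-trajectory branch labels,
    the gene-weight matrix, highly-weighted-gene lists, and the consensus
    tree as Newick + JSON.  Every file round-trips through pandas/json.
    Returns the list of paths written.
    """
    from .consensus import export_newick, tree_to_dict
    from .downsample import map_landmarks_to_cells

    os.makedirs(outdir, exist_ok=True)
    written: List[str] = []

    def _path(name: str) -> str:
        p = os.path.join(outdir, name)
        written.append(p)
        return p

    M = landmarks.M
    lm_ids = [f"landmark_{m}" for m in range(1, M + 1)]
    T = np.asarray(point_estimate.T, dtype=float)
    labels = {f"branch_traj{l + 1}": st.labels
              for l, st in enumerate(point_estimate.trajectories)}

    lm_df = pd.DataFrame({"pseudotime": T}, index=pd.Index(lm_ids, name="landmark"))
    for k, v in labels.items():
        lm_df[k] = v
    lm_df.to_csv(_path("landmark_pseudotime.csv"))

    cell_T = map_landmarks_to_cells(landmarks, T)
    cell_df = pd.DataFrame(
        {"landmark": [lm_ids[i] for i in landmarks.assignment],
         "pseudotime": cell_T},
        index=pd.Index(landmarks.cell_ids, name="cell"))
    for k, v in labels.items():
        cell_df[k] = map_landmarks_to_cells(landmarks, np.asarray(v))
    cell_df.to_csv(_path("cell_pseudotime.csv"))

    uw = pd.DataFrame(factors.U, index=pd.Index(factors.gene_ids, name="gene"),
                      columns=[f"u_{l + 1}" for l in range(factors.U.shape[1])])
    uw.to_csv(_path("gene_weights.csv"))

    with open(_path("highly_weighted_genes.json"), "w") as fh:
        json.dump({f"trajectory_{l + 1}": [[g, w] for g, w in hw]
                   for l, hw in enumerate(factors.hwg)}, fh, indent=1)

    with open(_path("consensus_tree.nwk"), "w") as fh:
        fh.write(export_newick(tree) + "\n")
    with open(_path("consensus_tree.json"), "w") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1)

    return written
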