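"""Correspondence analysis of genes x codons matrices.

Standard CA on a non-negative table N: with P = N/n, row masses r and column
masses c, the matrix of standardized residuals S = D_r^{-1/2} (P - r c^T)
D_c^{-1/2} is decomposed by SVD; principal inertias are the squared singular
values and total inertia equals the table's chi-square statistic divided by
its grand total.  Gene-set centroids and supplementary rows (modal usages)
are projected onto the fitted space via the column standard coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneSetPartition

_RANK_TOL = 1e-12


@dataclass
class CAResult:
    row_coords: pd.DataFrame          # principal coordinates, genes x dims
    col_coords: pd.DataFrame          # principal coordinates, codons x dims
    col_standard: pd.DataFrame        # standard coordinates, codons x dims
    inertia: np.ndarray               # eigenvalues per dimension
    percent_variance: np.ndarray
    row_masses: pd.Series
    col_masses: pd.Series
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()
    input_kind: str = "RCC"

    @property
    def total_inertia(self) -> float:
        return float(self.inertia.sum())


def ca_fit(matrix: pd.DataFrame, input_kind: str = "RCC") -> CAResult:
    """Fit a correspondence analysis to a non-negative genes x codons table.

    All-zero rows and columns are dropped with a warning.  Dimension signs
    are fixed so that, per dimension, the column with the largest absolute
    standard coordinate has a positive one (CA signs are otherwise
    arbitrary); dimensions are ordered by decreasing inertia.
    """
    df = matrix.astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("CA input must be non-negative")
    zero_rows = df.index[df.sum(axis=1) == 0]
    zero_cols = df.columns[df.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(f"dropping {len(zero_rows)} all-zero rows and "
                      f"{len(zero_cols)} all-zero columns")
        df = df.drop(index=zero_rows, columns=zero_cols)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("no inertia: need at least 2 non-zero rows and columns")
    values = df.to_numpy()
    n = values.sum()
    p = values / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    keep = sv > max(sv[0] if len(sv) else 0.0, 1.0) * _RANK_TOL
    if not keep.any():
        # homogeneous table: zero total inertia, everything at the origin
        dims = ["dim1"]
        zero_rc = pd.DataFrame(0.0, index=df.index, columns=dims)
        zero_cc = pd.DataFrame(0.0, index=df.columns, columns=dims)
        return CAResult(zero_rc, zero_cc.copy(), zero_cc.copy(),
                        np.zeros(1), np.zeros(1),
                        pd.Series(r, index=df.index),
                        pd.Series(c, index=df.columns),
                        tuple(zero_rows), tuple(zero_cols), input_kind)
    u, sv, v = u[:, keep], sv[keep], vt[keep].T
    col_standard = v / np.sqrt(c)[:, None]
    # sign convention: largest-|loading| column positive, per dimension
    for d in range(col_standard.shape[1]):
        j = int(np.argmax(np.abs(col_standard[:, d])))
        if col_standard[j, d] < 0:
            col_standard[:, d] *= -1.0
            u[:, d] *= -1.0
    row_coords = (u * sv) / np.sqrt(r)[:, None]
    col_coords = col_standard * sv
    inertia = sv ** 2
    dims = [f"dim{i + 1}" for i in range(len(sv))]
    return CAResult(
        row_coords=pd.DataFrame(row_coords, index=df.index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=df.columns, columns=dims),
        col_standard=pd.DataFrame(col_standard, index=df.columns, columns=dims),
        inertia=inertia,
        percent_variance=inertia / inertia.sum() * 100.0,
        row_masses=pd.Series(r, index=df.index),
        col_masses=pd.Series(c, index=df.columns),
        dropped_rows=tuple(zero_rows),
        dropped_cols=tuple(zero_cols),
        input_kind=input_kind,
    )


def ca_project(fit: CAResult, rows: pd.DataFrame) -> pd.DataFrame:
    """Project supplementary non-negative rows into the fitted CA space.

    Supplementary principal coordinates are (row profile) . col_standard, so
    an exact copy of an active row lands on that row's coordinates.
    """
    missing = [c for c in fit.col_standard.index if c not in rows.columns]
    if missing:
        raise ValueError("supplementary rows lack fitted columns: "
                         + ", ".join(missing))
    sub = rows[list(fit.col_standard.index)].astype(float)
    if (sub.to_numpy() < 0).any():
        raise ValueError("supplementary rows must be non-negative")
    totals = sub.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"supplementary rows with zero total: {bad}")
    profiles = sub.div(totals, axis=0)
    coords = profiles.to_numpy() @ fit.col_standard.to_numpy()
    return pd.DataFrame(coords, index=sub.index,
                        columns=fit.col_standard.columns)


def set_centroids(fit: CAResult,
                  partition: GeneSetPartition | Mapping[str, Sequence[str]],
                  dims: Sequence[str] | None = None) -> pd.DataFrame:
    """Arithmetic mean of member-gene row coordinates per gene set.

    By default the first two dimensions are returned; sets without any active
    gene are skipped with a warning.
    """
    sets = partition.sets if isinstance(partition, GeneSetPartition) else dict(partition)
    if dims is None:
        dims = list(fit.row_coords.columns[:2])
    rows = {}
    for name, members in sets.items():
        present = [g for g in members if g in fit.row_coords.index]
        if not present:
            warnings.warn(f"gene set {name!r} has no active gene in the CA; skipped")
            continue
        rows[name] = fit.row_coords.loc[present, list(dims)].mean(axis=0)
    if not rows:
        raise ValueError("no gene set with active genes")
    return pd.DataFrame(rows).T
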