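"""Gene-gene coexpression with a reference gene across single cells.

For each gene of interest (GoI) the Pearson correlation coefficient

    r = E[(N_ref - mu_ref)(N_GoI - mu_GoI)] / (sigma_ref sigma_GoI)

is computed between raw per-cell read counts of the GoI and of a reference
gene (here synaptopodin), jointly over all cells.  Because the number of
cells n is very large, even tiny correlations are distinguishable from zero;
the significance threshold is the correlation magnitude whose Student t
statistic t = r sqrt((n-2)/(1-r^2)) reaches a chosen value, inverted in
closed form as

    r_min = t / sqrt(n - 2 + t^2).

Counts are used raw (no normalization or log transform), and the correlation
is accumulated from sufficient statistics on the sparse support, so the
matrix is never densified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ReferenceGeneError, ValidationError


@dataclass
class CellCountMatrix:
    """Gene-by-cell nonnegative counts (sparse-friendly)."""

    X: sparse.spmatrix | np.ndarray
    gene_ids: Sequence[str]
    cell_ids: Sequence[str]

    def __post_init__(self) -> None:
        if not sparse.issparse(self.X):
            self.X = sparse.csr_matrix(np.asarray(self.X))
        else:
            self.X = self.X.tocsr()
        if self.X.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("matrix shape must be (n_genes, n_cells)")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError as exc:
            raise ReferenceGeneError(f"gene {gene!r} not in matrix") from exc
        return np.asarray(self.X.getrow(i).todense()).ravel()


@dataclass
class ThresholdSpec:
    """t-to-r significance threshold parameters (df convention n - 2)."""

    n: int
    t: float = 0.99

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("n must be >= 3 for the n - 2 df convention")
        if self.t <= 0:
            raise ValidationError("t must be positive")

    @property
    def r_min(self) -> float:
        return significance_threshold(self)


def significance_threshold(spec: ThresholdSpec | None = None, *, t: float = 0.99, n: int | None = None) -> float:
    """r_min = t / sqrt(n - 2 + t^2), the smallest correlation with Student t >= t."""
    if spec is not None:
        t, n = spec.t, spec.n
    if n is None or n < 3:
        raise ValidationError("n must be >= 3")
    if t <= 0:
        raise ValidationError("t must be positive")
    return t / np.sqrt(n - 2 + t * t)


def pearson_vs_reference(m: CellCountMatrix, ref_gene: str) -> pd.DataFrame:
    """Pearson r of every gene against the reference, from sufficient statistics.

    Uses per-gene sums, sums of squares and the sparse cross-product with the
    reference row; zero-variance genes get ``r = NaN`` (undefined).  Raises
    :class:`ReferenceGeneError` if the reference gene is missing or constant.
    """
    X: sparse.csr_matrix = m.X  # type: ignore[assignment]
    n = m.n_cells
    if n < 3:
        raise ValidationError("need at least 3 cells")
    y = m.row(ref_gene).astype(np.float64)
    s_y = y.sum()
    s_yy = float(y @ y)
    var_y = n * s_yy - s_y * s_y
    if var_y <= 0:
        raise ReferenceGeneError(f"reference gene {ref_gene!r} has zero variance")

    Xf = X.astype(np.float64)
    s_x = np.asarray(Xf.sum(axis=1)).ravel()
    s_xx = np.asarray(Xf.multiply(Xf).sum(axis=1)).ravel()
    s_xy = np.asarray(Xf @ y).ravel()
    var_x = n * s_xx - s_x * s_x
    cov = n * s_xy - s_x * s_y
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(var_x * var_y)
    r[var_x <= 0] = np.nan
    r = np.clip(r, -1.0, 1.0, out=r)
    return pd.DataFrame({"gene": list(m.gene_ids), "r": r, "n_cells": n}).set_index("gene")


def rank_genes(
    results: pd.DataFrame, ref_gene: str, threshold: ThresholdSpec | None = None
) -> pd.DataFrame:
    """Rank genes by descending r (ties broken lexicographically by gene id).

    Genes with undefined r are excluded; the reference gene is reported with
    rank NA but excluded from the ranking itself.  If a threshold spec is
    given, an ``above_threshold`` column compares r against its ``r_min``.
    """
    frame = results.copy()
    if threshold is not None:
        frame["above_threshold"] = frame["r"] > threshold.r_min
    defined = frame["r"].notna() & (frame.index != ref_gene)
    ranked = frame[defined].copy()
    # stable two-key sort: lexicographic gene id first, then descending r
    ranked = ranked.sort_index(kind="mergesort")
    ranked = ranked.sort_values(by="r", ascending=False, kind="mergesort")
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    if ref_gene in frame.index:
        ref_row = frame.loc[[ref_gene]].copy()
        ref_row["rank"] = pd.NA
        ranked = pd.concat([ref_row, ranked])
    return ranked
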