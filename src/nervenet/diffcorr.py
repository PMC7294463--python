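"""Mock-bulk profiles and per-cell differential Pearson correlation.

A *mock bulk* (pseudobulk) is the per-gene mean expression over all
cells of a dataset.  Each single cell is Pearson-correlated against
several mock bulks, and the *differential correlation* -- the difference
of two correlation coefficients -- places the cell on an axis between
two reference states (e.g. uninjured-like vs injured-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellTypeAnnotation, ExpressionMatrix, GeneSet


@dataclass
class MockBulk:
    name: str
    profile: pd.Series  # per-gene mean (normalised) expression


def _normalised_dense(matrix: ExpressionMatrix, normalization: str) -> np.ndarray:
    """Genes x cells dense expression after optional library-size
    normalisation (scaled to the median library size) and log1p."""
    x = matrix.counts.toarray().astype(float)
    if normalization == "none":
        return x
    if normalization == "library-size":
        libs = x.sum(axis=0)
        libs[libs == 0] = 1.0
        return np.log1p(x / libs * np.median(libs[libs > 0]))
    raise ValueError(f"unknown normalization {normalization!r}")


def mock_bulk(matrix: ExpressionMatrix, annot: CellTypeAnnotation,
              dataset: str, normalization: str = "library-size") -> MockBulk:
    """Per-gene arithmetic mean over a dataset's cells."""
    cells = annot.cells_of(dataset=dataset)
    if not cells:
        raise ValueError(f"dataset {dataset!r} has no cells")
    sub = matrix.subset_cells(cells)
    dense = _normalised_dense(sub, normalization)
    return MockBulk(dataset, pd.Series(dense.mean(axis=1),
                                       index=matrix.genes_upper))


def correlate_cells(matrix: ExpressionMatrix, bulks: list[MockBulk],
                    gene_subset: GeneSet | None = None,
                    normalization: str = "library-size") -> pd.DataFrame:
    """Pearson r of every cell against every mock bulk.

    Cells with zero variance over the gene scope have undefined r; they
    are excluded and recorded in the result's ``attrs["excluded"]``.
    """
    genes = matrix.genes_upper
    keep = [i for i, g in enumerate(genes)
            if gene_subset is None or g in gene_subset.members]
    if len(keep) < 2:
        raise ValueError("need at least 2 genes in scope")
    dense = _normalised_dense(matrix, normalization)[keep, :]
    gene_names = [genes[i] for i in keep]
    bulk_mat = np.column_stack([
        b.profile.reindex(gene_names).to_numpy() for b in bulks])
    if np.isnan(bulk_mat).any():
        raise ValueError("mock bulk missing genes in scope")
    if (bulk_mat.std(axis=0) == 0).any():
        raise ValueError("constant mock-bulk profile: r undefined")

    cell_sd = dense.std(axis=0)
    ok = cell_sd > 0
    xc = dense - dense.mean(axis=0)
    bc = bulk_mat - bulk_mat.mean(axis=0)
    num = xc.T @ bc
    denom = np.outer(dense.std(axis=0) * np.sqrt(len(keep)),
                     bulk_mat.std(axis=0) * np.sqrt(len(keep)))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    out = pd.DataFrame(r[ok], index=[c for c, k in zip(matrix.cell_ids, ok) if k],
                       columns=[b.name for b in bulks])
    out.attrs["excluded"] = [c for c, k in zip(matrix.cell_ids, ok) if not k]
    return out


def differential_coordinates(r: pd.DataFrame, x_pair: tuple[str, str],
                             y_pair: tuple[str, str]) -> pd.DataFrame:
    """Two-dimensional coordinates per cell: x = r(cell, A) - r(cell, B)
    for the x-axis bulk pair, likewise y; positive values mean more
    similar to the pair's first (minuend) reference."""
    for name in (*x_pair, *y_pair):
        if name not in r.columns:
            raise KeyError(f"bulk {name!r} not in correlation matrix")
    out = pd.DataFrame({
        "x": r[x_pair[0]] - r[x_pair[1]],
        "y": r[y_pair[0]] - r[y_pair[1]],
    })
    out.attrs["x_pair"] = x_pair
    out.attrs["y_pair"] = y_pair
    return out
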