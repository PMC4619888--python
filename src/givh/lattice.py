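"""Spatial lattice, covariate fields, and design-matrix expansion.

All analyses live on a regular rectangular grid of square cells. Cells are
indexed 0-based in row-major order, and every per-cell vector in the package
follows that order. Cell-center coordinates are in ``cell_size`` units, so
distances between cells are Euclidean distances between cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Grid",
    "CovariateField",
    "DesignSpec",
    "DesignMatrix",
    "expand_design",
    "adjacency_matrix",
    "read_covariates_csv",
    "write_covariates_csv",
]


@dataclass(frozen=True)
class Grid:
    """A regular ``nrow`` x ``ncol`` lattice of square cells.

    Parameters
    ----------
    nrow, ncol : int
        Grid dimensions; both must be positive.
    cell_size : float
        Side length of a cell in abstract distance units (default 1).
    """

    nrow: int
    ncol: int
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        if self.nrow < 1 or self.ncol < 1:
            raise ValueError("grid dimensions must be positive")
        if not np.isfinite(self.cell_size) or self.cell_size <= 0:
            raise ValueError("cell_size must be a positive real")

    @property
    def n_cells(self) -> int:
        return self.nrow * self.ncol

    def cell_id(self, row: int, col: int) -> int:
        if not (0 <= row < self.nrow and 0 <= col < self.ncol):
            raise ValueError(f"(row={row}, col={col}) outside grid")
        return row * self.ncol + col

    def row_col(self, cell_ids) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(cell_ids)
        if np.any((ids < 0) | (ids >= self.n_cells)):
            raise ValueError("cell id outside grid")
        return ids // self.ncol, ids % self.ncol

    def centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center (x, y) coordinates."""
        rows, cols = self.row_col(np.arange(self.n_cells))
        return self.cell_size * np.column_stack([cols + 0.5, rows + 0.5])

    def distances_from(self, cell_id: int) -> np.ndarray:
        """Euclidean distance from ``cell_id``'s center to every cell center."""
        centers = self.centers()
        return np.linalg.norm(centers - centers[int(cell_id)], axis=1)

    @property
    def center_cell(self) -> int:
        """Cell id nearest the geometric middle of the grid."""
        return (self.nrow // 2) * self.ncol + self.ncol // 2


@dataclass(frozen=True)
class CovariateField:
    """One real-valued covariate observed in every grid cell."""

    grid: Grid
    name: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n_cells,):
            raise ValueError(
                f"covariate '{self.name}' has {values.size} values for a grid "
                f"of {self.grid.n_cells} cells"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"covariate '{self.name}' contains non-finite values")


@dataclass(frozen=True)
class DesignSpec:
    """Which fixed-effect terms to build from a set of covariates.

    ``covariates=None`` means "use every field passed in, in order".
    Interactions are pairwise products of the *linear* terms only.
    ``standardize_mean_one`` divides each covariate by its mean over the full
    grid so the standardized covariate has mean exactly 1 (the convention used
    for distance-type habitat covariates).
    """

    covariates: tuple[str, ...] | None = None
    include_quadratic: bool = True
    include_first_order_interactions: bool = True
    standardize_mean_one: bool = False
    smooth_basis_size: int | None = None


@dataclass(frozen=True)
class DesignMatrix:
    """A dense fixed-effect design with column labels and row cell ids."""

    matrix: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    cell_ids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        cell_ids = np.asarray(self.cell_ids, dtype=int)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "cell_ids", cell_ids)
        object.__setattr__(self, "labels", tuple(self.labels))
        if matrix.ndim != 2 or matrix.shape[1] != len(self.labels):
            raise ValueError("column count must match number of labels")
        if matrix.shape[0] != cell_ids.size:
            raise ValueError("row count must match number of cell ids")
        if matrix.shape[1] == 0 or not np.allclose(matrix[:, 0], 1.0):
            raise ValueError("first design column must be an intercept of ones")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def rows_for(self, cell_ids) -> np.ndarray:
        """Design rows for the given cell ids (which must all be present)."""
        order = {int(c): i for i, c in enumerate(self.cell_ids)}
        try:
            idx = [order[int(c)] for c in np.asarray(cell_ids).ravel()]
        except KeyError as err:
            raise ValueError(f"cell id {err.args[0]} not in design") from None
        return self.matrix[idx]


def expand_design(
    fields: Sequence[CovariateField],
    spec: DesignSpec = DesignSpec(),
    subset: Sequence[int] | None = None,
) -> DesignMatrix:
    """Expand covariate fields into a fixed-effect design matrix.

    Columns are ordered: intercept, linear terms, quadratic terms, then
    pairwise interaction terms of the linear covariates. Standardization
    (division by the full-grid mean) happens before polynomial expansion.

    Parameters
    ----------
    fields : sequence of CovariateField
        All on the same grid; names must be distinct.
    spec : DesignSpec
        Term selection.
    subset : sequence of cell ids, optional
        Restrict the rows to these cells (default: the whole grid).
    """
    names = [f.name for f in fields]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate covariate names: {sorted(names)}")
    if fields:
        grid = fields[0].grid
        if any(f.grid != grid for f in fields):
            raise ValueError("all covariate fields must share one grid")
        n = grid.n_cells
    elif subset is not None:
        raise ValueError("cannot subset an intercept-only design with no grid")
    else:
        n = 1  # intercept-only design with a single abstract row

    if spec.covariates is None:
        chosen = list(fields)
    else:
        by_name = {f.name: f for f in fields}
        missing = [c for c in spec.covariates if c not in by_name]
        if missing:
            raise ValueError(f"covariates not found: {missing}")
        chosen = [by_name[c] for c in spec.covariates]

    columns: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["intercept"]

    values = []
    for f in chosen:
        v = f.values
        if spec.standardize_mean_one:
            m = v.mean()
            if abs(m) < 1e-12:
                raise ValueError(
                    f"covariate '{f.name}' has mean ~0; mean-1 standardization undefined"
                )
            v = v / m
        values.append(v)
        columns.append(v)
        labels.append(f.name)
    if spec.include_quadratic:
        for f, v in zip(chosen, values):
            columns.append(v**2)
            labels.append(f"{f.name}^2")
    if spec.include_first_order_interactions:
        for (fi, vi), (fj, vj) in combinations(zip(chosen, values), 2):
            columns.append(vi * vj)
            labels.append(f"{fi.name}:{fj.name}")

    matrix = np.column_stack(columns)
    cell_ids = np.arange(n) if fields else np.zeros(1, dtype=int)
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        if np.any((subset < 0) | (subset >= n)):
            raise ValueError("subset contains invalid cell ids")
        matrix = matrix[subset]
        cell_ids = subset.copy()
    return DesignMatrix(matrix, labels, cell_ids)


def adjacency_matrix(grid: Grid, scheme: str = "rook") -> sp.csr_matrix:
    """Symmetric 0/1 neighbor matrix of the grid.

    ``rook`` links the 4 edge-sharing neighbors; ``queen`` adds diagonals.
    """
    if scheme not in ("rook", "queen"):
        raise ValueError(f"unknown adjacency scheme: {scheme!r}")
    nrow, ncol = grid.nrow, grid.ncol
    ids = np.arange(grid.n_cells).reshape(nrow, ncol)
    pairs = []
    # horizontal / vertical edges
    pairs.append((ids[:, :-1].ravel(), ids[:, 1:].ravel()))
    pairs.append((ids[:-1, :].ravel(), ids[1:, :].ravel()))
    if scheme == "queen":
        pairs.append((ids[:-1, :-1].ravel(), ids[1:, 1:].ravel()))
        pairs.append((ids[:-1, 1:].ravel(), ids[1:, :-1].ravel()))
    rows = np.concatenate([p[0] for p in pairs])
    cols = np.concatenate([p[1] for p in pairs])
    data = np.ones(rows.size, dtype=np.int8)
    upper = sp.coo_matrix((data, (rows, cols)), shape=(grid.n_cells, grid.n_cells))
    return (upper + upper.T).tocsr()


def write_covariates_csv(path: str | Path, fields: Sequence[CovariateField]) -> None:
    """Write covariate fields as ``cell_id,row,col,<name>...`` CSV."""
    if not fields:
        raise ValueError("no covariate fields to write")
    grid = fields[0].grid
    rows, cols = grid.row_col(np.arange(grid.n_cells))
    frame = pd.DataFrame({"cell_id": np.arange(grid.n_cells), "row": rows, "col": cols})
    for f in fields:
        frame[f.name] = f.values
    frame.to_csv(path, index=False)


def read_covariates_csv(
    path: str | Path, cell_size: float = 1.0
) -> tuple[Grid, list[CovariateField]]:
    """Read a ``cell_id,row,col,<covariate>...`` CSV back into fields."""
    frame = pd.read_csv(path)
    required = {"cell_id", "row", "col"}
    if not required.issubset(frame.columns):
        raise ValueError(f"covariates CSV must have columns {sorted(required)}")
    grid = Grid(int(frame["row"].max()) + 1, int(frame["col"].max()) + 1, cell_size)
    if len(frame) != grid.n_cells:
        raise ValueError("covariates CSV does not cover the full grid")
    frame = frame.sort_values("cell_id")
    if not np.array_equal(frame["cell_id"].to_numpy(), np.arange(grid.n_cells)):
        raise ValueError("cell_id must enumerate 0..n_cells-1")
    names = [c for c in frame.columns if c not in required]
    return grid, [CovariateField(grid, c, frame[c].to_numpy(float)) for c in names]
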