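"""Synthetic landscapes, abundance, survey designs, and quadrat counts.

This module generates every input the estimation workflow needs:

* spatially autocorrelated Gaussian covariate fields (exponential
  correlation between cell centers, exact covariance factorization);
* a log-linear Poisson abundance surface driven by those fields, with
  density homogeneous within each cell;
* two survey designs over the grid — a spatially balanced probability
  sample (randomized-quadrant ordering plus systematic selection, an
  accepted approximation to GRTS) and a convenience sample whose inclusion
  weights decay exponentially with distance from a base of operations;
* binomially thinned quadrat counts (a quadrat covers a fixed fraction of
  its cell, detection is a fixed probability);
* presumed-absence augmentation: unsampled cells whose habitat covariate
  falls below a threshold are added as certain zero counts.

Every generator takes an integer seed and is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance

from .lattice import CovariateField, Grid

__all__ = [
    "AbundanceSurface",
    "SurveyDesign",
    "CountData",
    "simulate_covariate_field",
    "simulate_abundance",
    "draw_spatially_balanced",
    "draw_convenience",
    "observe_counts",
    "augment_presumed_absences",
    "read_counts_csv",
    "write_counts_csv",
]


@dataclass(frozen=True)
class AbundanceSurface:
    """True expected and realized abundance per grid cell."""

    grid: Grid
    intensity: np.ndarray = field(repr=False)
    realized: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        realized = np.asarray(self.realized)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "realized", realized)
        n = self.grid.n_cells
        if intensity.shape != (n,) or realized.shape != (n,):
            raise ValueError("intensity/realized must have one value per cell")
        if not np.all(np.isfinite(intensity)) or np.any(intensity <= 0):
            raise ValueError("intensity must be finite and positive")
        if np.any(realized < 0) or not np.issubdtype(realized.dtype, np.integer):
            raise ValueError("realized abundance must be nonnegative integers")

    @property
    def total(self) -> int:
        return int(self.realized.sum())


@dataclass(frozen=True)
class SurveyDesign:
    """A set of distinct sampled cells plus the design that produced it."""

    cells: np.ndarray = field(repr=False)
    label: str = "balanced"
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        object.__setattr__(self, "cells", cells)
        if len(np.unique(cells)) != cells.size:
            raise ValueError("sampled cell ids must be distinct")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")

    @property
    def n(self) -> int:
        return self.cells.size


@dataclass(frozen=True)
class CountData:
    """Quadrat counts with area offsets.

    Per row: cell id, count ``Y``, proportion of the cell surveyed ``P``
    (in (0, 1]), proportion of the cell that is habitat ``A`` (in [0, 1]),
    and whether the row is a presumed absence (a certain zero inserted
    without surveying).
    """

    cells: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    prop_surveyed: np.ndarray = field(repr=False)
    prop_habitat: np.ndarray = field(repr=False)
    presumed_absence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        y = np.asarray(self.y, dtype=int)
        p = np.asarray(self.prop_surveyed, dtype=float)
        a = np.asarray(self.prop_habitat, dtype=float)
        pa = np.asarray(self.presumed_absence, dtype=bool)
        for name, arr in (("y", y), ("prop_surveyed", p), ("prop_habitat", a), ("presumed_absence", pa)):
            if arr.shape != cells.shape:
                raise ValueError(f"{name} length must match cells")
        if np.any(y < 0):
            raise ValueError("counts must be nonnegative")
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("prop_surveyed must be in (0, 1]")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("prop_habitat must be in [0, 1]")
        if np.any(y[pa] != 0):
            raise ValueError("presumed absences must have zero counts")
        for attr, arr in (("cells", cells), ("y", y), ("prop_surveyed", p),
                          ("prop_habitat", a), ("presumed_absence", pa)):
            object.__setattr__(self, attr, arr)

    @property
    def n(self) -> int:
        return self.cells.size

    @property
    def offset(self) -> np.ndarray:
        """log(P_i * A_i), the fitting offset on the log-intensity scale."""
        with np.errstate(divide="ignore"):
            return np.log(self.prop_surveyed) + np.log(self.prop_habitat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cells,
                "count": self.y,
                "prop_surveyed": self.prop_surveyed,
                "prop_habitat": self.prop_habitat,
                "presumed_absence": self.presumed_absence,
            }
        )


@lru_cache(maxsize=8)
def _exp_corr_factor(nrow: int, ncol: int, cell_size: float, corr_range: float) -> np.ndarray:
    """Lower Cholesky factor of the exponential correlation matrix.

    Cached because the simulation study reuses the same grid/range for many
    replicate fields; the factorization dominates the cost otherwise.
    """
    grid = Grid(nrow, ncol, cell_size)
    centers = grid.centers()
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(centers))
    corr = np.exp(-d / corr_range)
    # tiny jitter guards the factorization against roundoff at long ranges
    corr[np.diag_indices_from(corr)] += 1e-9
    return np.linalg.cholesky(corr)


def simulate_covariate_field(
    grid: Grid, correlation_range: float, seed: int, name: str = "z"
) -> CovariateField:
    """Zero-mean, unit-variance Gaussian field with exponential correlation.

    Correlation between two cells at center distance ``d`` is
    ``exp(-d / correlation_range)``; ``correlation_range = 0`` gives
    independent standard normal values.
    """
    if correlation_range < 0:
        raise ValueError("correlation_range must be nonnegative")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(grid.n_cells)
    if correlation_range == 0:
        values = z
    else:
        L = _exp_corr_factor(grid.nrow, grid.ncol, grid.cell_size, float(correlation_range))
        values = L @ z
    return CovariateField(grid, name, values)


def simulate_abundance(
    fields: Sequence[CovariateField], coefficients: Sequence[float], seed: int
) -> AbundanceSurface:
    """Poisson abundance with log-linear intensity in the covariates.

    ``intensity_i = exp(b0 + sum_k b_k z_ki)``; each cell's realized
    abundance is one Poisson draw from its intensity (density homogeneous
    within a cell).
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size != len(fields) + 1:
        raise ValueError("need one intercept plus one coefficient per field")
    if not fields:
        raise ValueError("at least one covariate field is required")
    grid = fields[0].grid
    log_mu = np.full(grid.n_cells, coefficients[0])
    for b, f in zip(coefficients[1:], fields):
        log_mu += b * f.values
    intensity = np.exp(log_mu)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("non-finite intensity; check coefficients/covariates")
    rng = np.random.default_rng(seed)
    realized = rng.poisson(intensity)
    return AbundanceSurface(grid, intensity, realized)


def _balanced_order(grid: Grid, rng: np.random.Generator) -> np.ndarray:
    """Randomized recursive-quadrant ordering of all cells.

    The grid is split into quadrants, the quadrant visiting order is
    shuffled independently at every node, and the recursion continues until
    single cells remain. Cells adjacent in the resulting order tend to be
    spatially close, so a systematic draw along the order is spatially
    spread.
    """
    out: list[int] = []

    def visit(r0: int, r1: int, c0: int, c1: int) -> None:
        if r1 - r0 == 1 and c1 - c0 == 1:
            out.append(r0 * grid.ncol + c0)
            return
        rm = (r0 + r1) // 2 if r1 - r0 > 1 else r1
        cm = (c0 + c1) // 2 if c1 - c0 > 1 else c1
        blocks = [
            (r0, rm, c0, cm),
            (r0, rm, cm, c1),
            (rm, r1, c0, cm),
            (rm, r1, cm, c1),
        ]
        blocks = [b for b in blocks if b[1] > b[0] and b[3] > b[2]]
        for i in rng.permutation(len(blocks)):
            visit(*blocks[i])

    visit(0, grid.nrow, 0, grid.ncol)
    return np.asarray(out, dtype=int)


def draw_spatially_balanced(grid: Grid, n: int, seed: int) -> SurveyDesign:
    """Spatially balanced probability sample of ``n`` distinct cells.

    Cells are ordered by a randomized recursive-quadrant address and then
    selected systematically with a random fractional start, which makes the
    marginal inclusion probability exactly ``n / n_cells`` for every cell
    while spreading the realized sample across the grid.
    """
    if not 1 <= n <= grid.n_cells:
        raise ValueError(f"n must be in [1, {grid.n_cells}]")
    rng = np.random.default_rng(seed)
    order = _balanced_order(grid, rng)
    step = grid.n_cells / n
    start = rng.uniform(0, step)
    idx = np.floor(start + step * np.arange(n)).astype(int)
    return SurveyDesign(order[idx], "balanced", n / grid.n_cells)


def draw_convenience(
    grid: Grid, n: int, base_cell: int, decay: float, seed: int
) -> SurveyDesign:
    """Convenience sample clustered around a base of operations.

    ``n`` distinct cells are drawn without replacement with selection
    weights proportional to ``exp(-d_i / decay)`` where ``d_i`` is the
    distance from ``base_cell``; ``decay = inf`` reduces to simple random
    sampling.
    """
    if not 1 <= n <= grid.n_cells:
        raise ValueError(f"n must be in [1, {grid.n_cells}]")
    if not 0 <= base_cell < grid.n_cells:
        raise ValueError("base_cell outside grid")
    if not decay > 0:
        raise ValueError("decay must be positive")
    d = grid.distances_from(base_cell)
    w = np.exp(-d / decay) if np.isfinite(decay) else np.ones_like(d)
    rng = np.random.default_rng(seed)
    cells = rng.choice(grid.n_cells, size=n, replace=False, p=w / w.sum())
    return SurveyDesign(np.sort(cells), "convenience", n / grid.n_cells)


def observe_counts(
    surface: AbundanceSurface,
    design: SurveyDesign,
    coverage: float,
    detection: float = 1.0,
    habitat_fraction: np.ndarray | None = None,
    seed: int = 0,
) -> CountData:
    """Quadrat counts by binomial thinning of realized abundance.

    Each sampled cell contributes ``Y_i ~ Binomial(N_i, coverage*detection)``
    — the quadrat covers ``coverage`` of the cell, and each animal inside it
    is detected independently with probability ``detection``. The surveyed
    fraction recorded for fitting is ``P_i = coverage`` (detection is part of
    the thinning, not the offset, mirroring a perfect-detection analysis).
    """
    if not 0 < coverage * detection <= 1 or not 0 < coverage <= 1:
        raise ValueError("coverage and coverage*detection must be in (0, 1]")
    cells = design.cells
    if habitat_fraction is None:
        a = np.ones(cells.size)
    else:
        habitat_fraction = np.asarray(habitat_fraction, dtype=float)
        a = habitat_fraction[cells] if habitat_fraction.size == surface.grid.n_cells else habitat_fraction
        if a.shape != cells.shape:
            raise ValueError("habitat_fraction must cover the grid or the sample")
    rng = np.random.default_rng(seed)
    y = rng.binomial(surface.realized[cells], coverage * detection)
    return CountData(
        cells=cells,
        y=y,
        prop_surveyed=np.full(cells.size, coverage),
        prop_habitat=a,
        presumed_absence=np.zeros(cells.size, dtype=bool),
    )


def augment_presumed_absences(
    counts: CountData, covariate: CovariateField, threshold: float
) -> CountData:
    """Append certain zero counts where habitat makes presence impossible.

    Every cell *not* already in ``counts`` whose covariate value (e.g. ice
    concentration) is below ``threshold`` is appended as a zero count with
    ``presumed_absence=True`` and ``P = 1``. Original rows are unchanged.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    sampled = set(counts.cells.tolist())
    below = np.flatnonzero(covariate.values < threshold)
    new = np.array([c for c in below if c not in sampled], dtype=int)
    if new.size == 0:
        return counts
    return CountData(
        cells=np.concatenate([counts.cells, new]),
        y=np.concatenate([counts.y, np.zeros(new.size, dtype=int)]),
        prop_surveyed=np.concatenate([counts.prop_surveyed, np.ones(new.size)]),
        prop_habitat=np.concatenate([counts.prop_habitat, np.ones(new.size)]),
        presumed_absence=np.concatenate(
            [counts.presumed_absence, np.ones(new.size, dtype=bool)]
        ),
    )


def write_counts_csv(
    path: str | Path, counts: CountData, meta: dict | None = None
) -> None:
    """Write counts CSV plus a JSON sidecar recording generation parameters."""
    path = Path(path)
    counts.to_frame().to_csv(path, index=False)
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_counts_csv(path: str | Path) -> CountData:
    frame = pd.read_csv(path)
    required = ["cell_id", "count", "prop_surveyed", "prop_habitat", "presumed_absence"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"counts CSV missing columns: {missing}")
    return CountData(
        cells=frame["cell_id"].to_numpy(int),
        y=frame["count"].to_numpy(int),
        prop_surveyed=frame["prop_surveyed"].to_numpy(float),
        prop_habitat=frame["prop_habitat"].to_numpy(float),
        presumed_absence=frame["presumed_absence"].to_numpy(bool),
    )

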