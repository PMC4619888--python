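"""The simulation experiment: generate, survey, fit, flag, summarize.

Each replicate generates three autocorrelated covariate fields on a grid,
a Poisson abundance surface that is log-linear in all three, and quadrat
counts under one or both survey designs (spatially balanced and
convenience). Estimation models are deliberately misspecified: they
receive only the first two covariates. For each design x model the
replicate records the posterior-median total abundance over (a) the whole
grid and (b) the cells inside the gIVH, together with the matching true
totals, and the proportional error of each. Summaries across replicates
mirror the boxplot convention of the experiment: mean/median/quartiles of
proportional error and the count of outliers exceeding 2.0.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lattice import DesignSpec, Grid, adjacency_matrix, expand_design
from .models import (
    MCMCConfig,
    fit_gam,
    fit_glm_bayes,
    fit_strm_rsr,
    posterior_total_abundance,
    prediction_set,
)
from .simulate import (
    draw_convenience,
    draw_spatially_balanced,
    observe_counts,
    simulate_abundance,
    simulate_covariate_field,
)

__all__ = [
    "StudyConfig",
    "ReplicateResult",
    "proportional_error",
    "run_replicate",
    "summarize_bias",
    "run_study",
]

logger = logging.getLogger("givh.study")

OUTLIER_CUTOFF = 2.0  # proportional errors beyond this are counted separately


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the simulation experiment.

    Defaults are the experiment's stated conditions: 100 replicates on a
    30x30 grid, 45 sampled cells, quadrats covering 10% of a cell, perfect
    detection, abundance log-linear in three autocorrelated covariates of
    which the estimation models see only the first two, and a desk-scale
    chain of 5,000 iterations with 1,000 burn-in.
    """

    replicates: int = 100
    nrow: int = 30
    ncol: int = 30
    n_sample: int = 45
    designs: tuple[str, ...] = ("balanced", "convenience")
    models: tuple[str, ...] = ("glm", "gam", "strm")
    coverage: float = 0.1
    detection: float = 1.0
    correlation_range: float = 10.0
    abundance_coef: tuple[float, ...] = (math.log(20.0), 0.75, -0.75, 0.5)
    n_covariates_fit: int = 2
    convenience_decay: float | None = None  # default: grid side / 6
    eigen_threshold: float = 0.5
    gam_basis_size: int = 5
    gam_bootstrap_draws: int = 1000
    mcmc_iterations: int = 5000
    mcmc_burn_in: int = 1000
    mcmc_thin: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        unknown = set(self.designs) - {"balanced", "convenience"}
        if unknown:
            raise ValueError(f"unknown designs: {sorted(unknown)}")
        unknown = set(self.models) - {"glm", "gam", "strm"}
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if not 1 <= self.n_sample <= self.nrow * self.ncol:
            raise ValueError("n_sample out of range for the grid")
        if len(self.abundance_coef) < 2:
            raise ValueError("abundance_coef needs an intercept and >=1 slope")
        if not 1 <= self.n_covariates_fit <= len(self.abundance_coef) - 1:
            raise ValueError("n_covariates_fit out of range")
        if self.mcmc_burn_in >= self.mcmc_iterations:
            raise ValueError("burn_in must be smaller than iterations")

    @property
    def grid(self) -> Grid:
        return Grid(self.nrow, self.ncol)

    @property
    def n_covariates(self) -> int:
        return len(self.abundance_coef) - 1

    @property
    def decay(self) -> float:
        return (
            self.convenience_decay
            if self.convenience_decay is not None
            else max(self.nrow, self.ncol) / 6.0
        )


@dataclass(frozen=True)
class ReplicateResult:
    """Per-replicate outcomes, one record per design x model x restriction."""

    replicate: int
    true_total: int
    records: tuple[dict, ...] = field(repr=False)

    def __post_init__(self) -> None:
        for rec in self.records:
            if not rec.get("failed") and rec["restriction"] == "givh":
                if rec["true_total"] > self.true_total:
                    raise ValueError("restricted true total exceeds whole-grid total")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(list(self.records))
        frame.insert(0, "replicate", self.replicate)
        return frame


def proportional_error(estimated_total: float, true_total: float) -> float:
    """(estimate - truth) / truth, the experiment's bias metric."""
    if not true_total > 0:
        raise ValueError("true_total must be positive")
    return (estimated_total - true_total) / true_total


def _replicate_seed(master_seed: int, replicate: int, stream: int) -> int:
    """Counter-based child seed: reproducible for any replicate in isolation."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(replicate), int(stream)))
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicate(config: StudyConfig, replicate: int) -> ReplicateResult:
    """Run one replicate: simulate, survey, fit each model, flag, record."""
    grid = config.grid
    seed = lambda stream: _replicate_seed(config.master_seed, replicate, stream)

    fields = [
        simulate_covariate_field(grid, config.correlation_range, seed(10 + k), name=f"z{k + 1}")
        for k in range(config.n_covariates)
    ]
    surface = simulate_abundance(fields, config.abundance_coef, seed(20))
    true_totals = surface.realized

    fit_fields = fields[: config.n_covariates_fit]
    design = expand_design(
        fit_fields,
        DesignSpec(include_quadratic=True, include_first_order_interactions=True),
    )
    adjacency = adjacency_matrix(grid, "rook")
    mcmc = lambda stream: MCMCConfig(
        iterations=config.mcmc_iterations,
        burn_in=config.mcmc_burn_in,
        thin=config.mcmc_thin,
        seed=seed(stream),
    )

    records: list[dict] = []
    for d_idx, design_label in enumerate(config.designs):
        if design_label == "balanced":
            survey = draw_spatially_balanced(grid, config.n_sample, seed(30 + d_idx))
        else:
            survey = draw_convenience(
                grid, config.n_sample, grid.center_cell, config.decay, seed(30 + d_idx)
            )
        counts = observe_counts(
            surface, survey, config.coverage, config.detection, seed=seed(40 + d_idx)
        )
        for m_idx, model_label in enumerate(config.models):
            stream = 50 + 10 * d_idx + m_idx
            try:
                if model_label == "glm":
                    model = fit_glm_bayes(counts, design, mcmc(stream))
                elif model_label == "strm":
                    model = fit_strm_rsr(
                        counts, design, adjacency, config.eigen_threshold, mcmc(stream)
                    )
                else:
                    model = fit_gam(counts, fit_fields, config.gam_basis_size)
                preds = prediction_set(model, seed=seed(stream + 100))
                in_hull = np.asarray(preds.in_givh, bool)
                for restriction, subset in (
                    ("none", None),
                    ("givh", np.flatnonzero(in_hull)),
                ):
                    _, quantiles = posterior_total_abundance(
                        model,
                        subset=subset,
                        seed=seed(stream + 200),
                        n_boot=config.gam_bootstrap_draws,
                    )
                    true_sub = int(
                        true_totals.sum() if subset is None else true_totals[subset].sum()
                    )
                    est = quantiles["q50"]
                    records.append(
                        {
                            "design": design_label,
                            "model": model_label,
                            "restriction": restriction,
                            "n_cells": int(grid.n_cells if subset is None else subset.size),
                            "true_total": true_sub,
                            "estimated_total": est,
                            "prop_error": proportional_error(est, true_sub),
                            "failed": False,
                        }
                    )
            except Exception as err:  # a failed fit must not abort the replicate
                logger.warning(
                    "replicate %d %s/%s failed: %s", replicate, design_label, model_label, err
                )
                for restriction in ("none", "givh"):
                    records.append(
                        {
                            "design": design_label,
                            "model": model_label,
                            "restriction": restriction,
                            "n_cells": np.nan,
                            "true_total": np.nan,
                            "estimated_total": np.nan,
                            "prop_error": np.nan,
                            "failed": True,
                        }
                    )
    return ReplicateResult(replicate, surface.total, tuple(records))


def summarize_bias(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """Distributional summaries of proportional error across replicates.

    One row per design x model x restriction: mean, median, quartiles,
    the number of outliers with proportional error above 2.0, and the
    effective (non-failed) replicate count.
    """
    if len(results) == 0:
        raise ValueError("no replicate results to summarize")
    frame = pd.concat([r.to_frame() for r in results], ignore_index=True)
    rows = []
    for (design, model, restriction), group in frame.groupby(
        ["design", "model", "restriction"], sort=True
    ):
        err = group.loc[~group["failed"], "prop_error"].to_numpy(float)
        rows.append(
            {
                "design": design,
                "model": model,
                "restriction": restriction,
                "n_replicates": err.size,
                "mean": err.mean() if err.size else np.nan,
                "median": np.median(err) if err.size else np.nan,
                "q25": np.quantile(err, 0.25) if err.size else np.nan,
                "q75": np.quantile(err, 0.75) if err.size else np.nan,
                "mean_abs": np.abs(err).mean() if err.size else np.nan,
                "n_outliers": int((err > OUTLIER_CUTOFF).sum()),
            }
        )
    return pd.DataFrame(rows)


def run_study(
    config: StudyConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all replicates sequentially and summarize.

    Returns ``(summary, per_replicate)`` tables; when ``out_dir`` is given
    they are written as ``summary.csv`` and ``replicates.csv`` along with
    the configuration used.
    """
    results = []
    for r in range(config.replicates):
        t0 = time.perf_counter()
        results.append(run_replicate(config, r))
        logger.info(
            "replicate %d/%d done in %.1fs",
            r + 1,
            config.replicates,
            time.perf_counter() - t0,
        )
    summary = summarize_bias(results)
    per_rep = pd.concat([r.to_frame() for r in results], ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "summary.csv", index=False)
        per_rep.to_csv(out_dir / "replicates.csv", index=False)
        pd.Series(asdict(config)).to_json(out_dir / "config.json", indent=2)
    return summary, per_rep
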