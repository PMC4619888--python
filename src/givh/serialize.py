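"""Save and reload fitted models as a directory of JSON metadata + CSV arrays.

The dump deliberately stores only what cannot be rebuilt from the
covariates CSV: coefficient draws (or mean and covariance), the spatial
basis for the STRM, the spline specification for the GAM, the sampled
cells, and the design specification used. Reloading requires the same
covariate fields so the prediction-domain design can be reconstructed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .lattice import CovariateField, DesignSpec, expand_design
from .models import BayesPoissonGLM, BayesSTRM, QuasiPoissonGAM

__all__ = ["save_model", "load_model"]


def _spec_dict(spec: DesignSpec) -> dict:
    return {
        "covariates": list(spec.covariates) if spec.covariates else None,
        "include_quadratic": spec.include_quadratic,
        "include_first_order_interactions": spec.include_first_order_interactions,
        "standardize_mean_one": spec.standardize_mean_one,
    }


def save_model(model, path: str | Path, design_spec: DesignSpec | None = None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "kind": model.kind,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in model.get_params().items()},
        "cells": np.asarray(model.cells_).tolist(),
    }
    if design_spec is not None:
        meta["design_spec"] = _spec_dict(design_spec)
    if isinstance(model, QuasiPoissonGAM):
        meta["field_names"] = model.field_names_
        meta["coef"] = model.coef_.tolist()
        meta["dispersion"] = model.dispersion_
        meta["edf"] = model.edf_
        meta["lambda"] = model.lambda_
        meta["domain"] = model.domain_.tolist()
        meta["n_features"] = model.n_features_in_
        meta["smooths"] = [
            None
            if spec is None
            else {
                "knots": np.asarray(spec["knots"]).tolist(),
                "degree": int(spec["degree"]),
                "Q": np.asarray(spec["Q"]).tolist(),
                "penalty": np.asarray(spec["penalty"]).tolist(),
            }
            for spec in model.smooths_
        ]
        meta["degenerate_smooths"] = model.degenerate_smooths_
        np.savetxt(path / "coef_cov.csv", model.coef_cov_, delimiter=",")
    else:
        np.savetxt(path / "coef_draws.csv", model.coef_draws_, delimiter=",")
        np.savetxt(path / "sigma2_draws.csv", model.sigma2_draws_, delimiter=",")
        if isinstance(model, BayesSTRM):
            np.savetxt(path / "basis.csv", model.basis_, delimiter=",")
            np.savetxt(path / "spatial_penalty.csv", model.spatial_penalty_, delimiter=",")
            meta["n_fixed"] = model.n_fixed_
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path, fields: Sequence[CovariateField]):
    """Reload a dumped model, rebuilding its prediction domain from fields."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    kind = meta["kind"]
    cells = np.asarray(meta["cells"], dtype=int)
    params = {
        k: (tuple(v) if isinstance(v, list) else v) for k, v in meta["params"].items()
    }
    if kind == "gam":
        model = QuasiPoissonGAM(
            **{k: params[k] for k in ("basis_size", "max_iter", "tol", "ridge")}
        )
        model.field_names_ = meta["field_names"]
        by_name = {f.name: f for f in fields}
        model.covariates_grid_ = np.column_stack(
            [by_name[n].values for n in model.field_names_]
        )
        model.coef_ = np.asarray(meta["coef"])
        model.coef_cov_ = np.loadtxt(path / "coef_cov.csv", delimiter=",", ndmin=2)
        model.dispersion_ = meta["dispersion"]
        model.edf_ = meta["edf"]
        model.lambda_ = meta["lambda"]
        model.domain_ = np.asarray(meta["domain"])
        model.n_features_in_ = meta["n_features"]
        model.smooths_ = [
            None
            if spec is None
            else {
                "knots": np.asarray(spec["knots"]),
                "degree": spec["degree"],
                "Q": np.asarray(spec["Q"]),
                "penalty": np.asarray(spec["penalty"]),
            }
            for spec in meta["smooths"]
        ]
        model.degenerate_smooths_ = meta["degenerate_smooths"]
        model.cells_ = cells
        return model

    spec_d = meta.get("design_spec") or {}
    spec = DesignSpec(
        covariates=tuple(spec_d["covariates"]) if spec_d.get("covariates") else None,
        include_quadratic=spec_d.get("include_quadratic", True),
        include_first_order_interactions=spec_d.get(
            "include_first_order_interactions", True
        ),
        standardize_mean_one=spec_d.get("standardize_mean_one", False),
    )
    design = expand_design(list(fields), spec)
    cls = BayesSTRM if kind == "strm" else BayesPoissonGLM
    model = cls(**params)
    model.coef_draws_ = np.loadtxt(path / "coef_draws.csv", delimiter=",", ndmin=2)
    model.sigma2_draws_ = np.loadtxt(path / "sigma2_draws.csv", delimiter=",")
    model.coef_ = model.coef_draws_.mean(axis=0)
    model.coef_cov_ = np.cov(model.coef_draws_, rowvar=False).reshape(
        model.coef_.size, model.coef_.size
    )
    model.design_grid_ = design
    model.cells_ = cells
    model.n_features_in_ = model.coef_.size
    if kind == "strm":
        model.basis_ = np.loadtxt(path / "basis.csv", delimiter=",", ndmin=2)
        model.spatial_penalty_ = np.loadtxt(
            path / "spatial_penalty.csv", delimiter=",", ndmin=2
        )
        model.n_fixed_ = meta["n_fixed"]
        model.n_spatial_ = model.basis_.shape[1]
    return model
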