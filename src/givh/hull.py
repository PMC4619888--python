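"""The (generalized) independent variable hull.

For a full-rank linear regression, the independent variable hull (IVH) is
the smallest convex set containing all design points; a new design point
``x0`` lies inside it exactly when its scaled prediction variance
``x0' (X'X)^-1 x0`` does not exceed the maximum leverage of the observed
design. Because leverage is proportional to prediction variance, the idea
extends to any model for which a prediction variance exists: the
*generalized* IVH (gIVH) is the set of prediction locations whose
response-scale prediction variance does not exceed the maximum over the
sampled locations. Predictions inside the hull are interpolations;
predictions outside are extrapolations deserving skepticism.

Three routes from coefficient uncertainty to response-scale variance are
provided: the delta method (first-order Taylor through the inverse link),
posterior-predictive variance (sample variance across posterior draws of
the mean response), and a parametric bootstrap of the coefficients. The
hull itself only ever needs per-location variance diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .lattice import DesignMatrix

__all__ = [
    "LinkFunction",
    "LOG",
    "IDENTITY",
    "LOGIT",
    "link_by_name",
    "PredictionSet",
    "ivh_linear",
    "prediction_variance_linear",
    "delta_response_variance",
    "posterior_predictive_variance",
    "bootstrap_response_variance",
    "givh_flags",
    "IndependentVariableHull",
]

#: relative tolerance under which a variance tied with the sampled maximum
#: (or a leverage tied with the max observed leverage) still counts as inside
BOUNDARY_RTOL = 1e-10


@dataclass(frozen=True)
class LinkFunction:
    """A link with its inverse map and the inverse's derivative.

    The response-scale mean is ``inverse(mu)`` for linear predictor ``mu``;
    ``dinverse`` is d inverse(mu) / d mu, the diagonal of the Jacobian used
    by the delta method.
    """

    name: str
    inverse: Callable[[np.ndarray], np.ndarray]
    dinverse: Callable[[np.ndarray], np.ndarray]

    def check_consistency(self, mu: np.ndarray, h: float = 1e-6, rtol: float = 1e-4) -> None:
        """Finite-difference check that ``dinverse`` differentiates ``inverse``."""
        mu = np.asarray(mu, dtype=float)
        fd = (self.inverse(mu + h) - self.inverse(mu - h)) / (2 * h)
        if not np.allclose(fd, self.dinverse(mu), rtol=rtol, atol=1e-8):
            raise ValueError(f"link '{self.name}': inverse/derivative inconsistent")


LOG = LinkFunction("log", np.exp, np.exp)
IDENTITY = LinkFunction("identity", lambda m: np.asarray(m, float), lambda m: np.ones_like(np.asarray(m, float)))
LOGIT = LinkFunction("logit", expit, lambda m: expit(m) * (1.0 - expit(m)))

_LINKS = {l.name: l for l in (LOG, IDENTITY, LOGIT)}


def link_by_name(name: str) -> LinkFunction:
    try:
        return _LINKS[name]
    except KeyError:
        raise ValueError(f"unknown link: {name!r}") from None


@dataclass(frozen=True)
class PredictionSet:
    """Per-location predictions, variances, and hull membership."""

    cell_ids: np.ndarray = field(repr=False)
    lambda_mean: np.ndarray = field(repr=False)
    var_mu: np.ndarray = field(repr=False)
    var_lambda: np.ndarray = field(repr=False)
    in_givh: np.ndarray = field(repr=False)
    sampled: np.ndarray = field(repr=False)
    variance_method: str = "delta"

    def __post_init__(self) -> None:
        n = np.asarray(self.cell_ids).size
        for name in ("lambda_mean", "var_mu", "var_lambda", "in_givh", "sampled"):
            arr = np.asarray(getattr(self, name))
            if arr.size != n:
                raise ValueError(f"{name} must have one entry per cell")
            object.__setattr__(self, name, arr)
        if np.any(self.var_lambda < 0) or np.any(self.var_mu < 0):
            raise ValueError("variances must be nonnegative")
        if not np.all(self.in_givh[self.sampled]):
            raise ValueError("sampled locations cannot fall outside the gIVH")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.asarray(self.cell_ids, int),
                "lambda_mean": self.lambda_mean,
                "var_mu": self.var_mu,
                "var_lambda": self.var_lambda,
                "in_givh": np.asarray(self.in_givh, bool),
                "sampled": np.asarray(self.sampled, bool),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, DesignMatrix):
        return x.matrix
    return np.atleast_2d(np.asarray(x, dtype=float))


def ivh_linear(X_obs, X_pred, rtol: float = BOUNDARY_RTOL) -> np.ndarray:
    """Cook's IVH membership for rows of ``X_pred``.

    A prediction row ``x0`` is inside the hull iff ``x0'(X'X)^-1 x0`` is no
    larger than the maximum diagonal of the observed hat matrix; ties within
    relative tolerance count as inside. ``X_obs`` must have full column
    rank; otherwise the (near-)collinear columns are reported.
    """
    Xo = _as_matrix(X_obs)
    Xp = _as_matrix(X_pred)
    if Xo.shape[1] != Xp.shape[1]:
        raise ValueError("observed and prediction designs must share columns")
    u, s, vt = np.linalg.svd(Xo, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        bad = np.flatnonzero(np.abs(vt[-1]) > 1e-8)
        labels = (
            [X_obs.labels[i] for i in bad]
            if isinstance(X_obs, DesignMatrix)
            else bad.tolist()
        )
        raise ValueError(f"design is rank deficient; collinear columns: {labels}")
    # leverage of a row x is ||V S^-1 x'||^2 via the SVD
    half = vt.T / s  # p x p, (X'X)^-1 = half @ half.T
    lev_obs = np.einsum("ij,ij->i", Xo @ half, Xo @ half)
    lev_pred = np.einsum("ij,ij->i", Xp @ half, Xp @ half)
    vmax = lev_obs.max()
    return lev_pred <= vmax * (1.0 + rtol)


def prediction_variance_linear(X_pred, coef_cov: np.ndarray) -> np.ndarray:
    """Diagonal of ``X V X'`` — linear-predictor prediction variance per row."""
    Xp = _as_matrix(X_pred)
    V = np.asarray(coef_cov, dtype=float)
    if V.shape != (Xp.shape[1], Xp.shape[1]):
        raise ValueError(
            f"coefficient covariance {V.shape} does not conform with design "
            f"of {Xp.shape[1]} columns"
        )
    var = np.einsum("ij,jk,ik->i", Xp, V, Xp)
    return np.maximum(var, 0.0)


def delta_response_variance(mu_hat, var_mu, link: LinkFunction = LOG) -> np.ndarray:
    """Delta-method variance on the response scale.

    First-order propagation through the inverse link: with diagonal Jacobian
    ``D = dinverse(mu_hat)``, the response variance is ``D^2 * var_mu`` for a
    per-location variance vector, or ``diag(D C D)`` when ``var_mu`` is a
    full linear-scale covariance matrix ``C``.
    """
    mu_hat = np.asarray(mu_hat, dtype=float)
    d = link.dinverse(mu_hat)
    if not np.all(np.isfinite(d)):
        raise ValueError(f"link '{link.name}' derivative non-finite at mu_hat")
    var_mu = np.asarray(var_mu, dtype=float)
    if var_mu.ndim == 2:
        return np.maximum(d * np.diag(var_mu) * d, 0.0)
    return np.maximum(d * var_mu * d, 0.0)


def posterior_predictive_variance(lambda_draws: np.ndarray) -> np.ndarray:
    """Per-location sample variance of the mean response across draws.

    ``lambda_draws`` has one row per posterior draw and one column per
    location; iid observation noise is deliberately excluded — the hull
    measures uncertainty in the *mean* prediction.
    """
    draws = np.asarray(lambda_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need a draws-by-locations matrix with at least 2 draws")
    return draws.var(axis=0, ddof=1)


def bootstrap_response_variance(
    model, X_pred, B: int = 1000, link: LinkFunction = LOG, seed: int = 0,
    offset=None,
) -> np.ndarray:
    """Parametric-bootstrap response-scale variance.

    Draws ``B`` coefficient vectors from ``Normal(coef, coef_cov)`` taken
    from the fitted model, maps each through the design and inverse link,
    and returns the per-location variance of the resulting mean responses.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap draws")
    mean = np.asarray(getattr(model, "coef_"), dtype=float)
    cov = np.asarray(getattr(model, "coef_cov_"), dtype=float)
    Xp = _as_matrix(X_pred)
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("coefficient covariance is not positive semidefinite")
    L = V * np.sqrt(np.clip(w, 0.0, None))  # PSD factor, exact for zero cov
    rng = np.random.default_rng(seed)
    betas = mean + rng.standard_normal((B, mean.size)) @ L.T
    mu = betas @ Xp.T
    if offset is not None:
        mu = mu + np.asarray(offset, dtype=float)
    return link.inverse(mu).var(axis=0, ddof=1)


def givh_flags(
    var_lambda_pred: np.ndarray,
    var_lambda_sampled: np.ndarray,
    rtol: float = BOUNDARY_RTOL,
) -> np.ndarray:
    """gIVH membership: variance no larger than the sampled maximum.

    A prediction location is inside the hull iff its response-scale
    prediction variance is at most the maximum over sampled locations;
    equality (within relative tolerance) counts as inside, so every sampled
    location is inside its own hull.
    """
    var_sampled = np.asarray(var_lambda_sampled, dtype=float)
    if var_sampled.size == 0:
        raise ValueError("sampled variance set is empty")
    vmax = var_sampled.max()
    return np.asarray(var_lambda_pred, dtype=float) <= vmax * (1.0 + rtol) + np.finfo(float).tiny


class IndependentVariableHull(BaseEstimator):
    """Cook's IVH as a fit/predict estimator for linear designs.

    ``fit`` records the observed design; ``predict`` returns a boolean
    interpolation flag per prediction row. Thin object wrapper over
    :func:`ivh_linear` so the diagnostic composes with sklearn pipelines.
    """

    def __init__(self, rtol: float = BOUNDARY_RTOL):
        self.rtol = rtol

    def fit(self, X, y=None):
        Xo = _as_matrix(X)
        # validates rank eagerly so misuse fails at fit time
        ivh_linear(Xo, Xo[:1], rtol=self.rtol)
        self.X_ = Xo
        self.n_features_in_ = Xo.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "X_"):
            raise ValueError("IndependentVariableHull is not fitted")
        return ivh_linear(self.X_, X, rtol=self.rtol)
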