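"""Phylogenetic generalized least squares with ML Pagel's λ.

The residual covariance is ``σ² · V(λ)`` where ``V(λ)`` is the tree's
shared-path-length matrix with off-diagonals multiplied by λ (λ = 0 is an
independent-tips star; λ = 1 pure Brownian motion). β and σ² have closed
forms given λ; λ itself is profiled on a 0.01 grid over [0, 1] and refined
by bounded scalar search around the best grid point.

The model sets mirror the comparative analysis this package reimplements:
each leaf trait (log-transformed by default) against altitude, habitat,
both, and their interaction (interaction models keep the main effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .modelselect import aicc as _aicc
from .trees import Phylogeny, TreeSample

__all__ = ["lambda_transform", "GlsFit", "gls_fit", "MODEL_TERMS",
           "build_design", "fit_pgls_models", "fit_model_set"]

MODEL_TERMS = ("altitude", "habitat", "altitude+habitat", "altitude*habitat")


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of a phylogenetic covariance matrix by λ."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(V, np.diag(C))
    return V


@dataclass
class GlsFit:
    """A GLS fit with ML residual rate σ², Pagel's λ, and AICc score."""

    beta: np.ndarray
    se: np.ndarray
    names: list
    sigma2: float
    lam: float
    loglik: float
    k: int
    n: int
    aicc: float
    r2_adj: float
    degenerate: bool = False

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])


def _profile(X, y, C, lam):
    """Profile log-likelihood pieces at a fixed λ; None if V is singular."""
    V = lambda_transform(C, lam)
    n = len(y)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    try:
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    except np.linalg.LinAlgError:
        raise ValueError("singular design matrix X") from None
    e = y - X @ beta
    Vi_e = cho_solve(cf, e)
    sse = float(e @ Vi_e)
    sigma2 = sse / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return None, beta, 0.0, logdet, cf, XtViX
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, logdet, cf, XtViX


def _ll_at(X, y, C, lam) -> float:
    out = _profile(X, y, C, lam)
    return -np.inf if out is None or out[0] is None else out[0]


def gls_fit(X: np.ndarray, y: np.ndarray, C: np.ndarray,
            lambda_mode: str = "ml", lambda_value: float | None = None,
            names: list | None = None) -> GlsFit:
    """Fit y = Xβ + ε, ε ~ N(0, σ²·V(λ)), by maximum likelihood.

    ``lambda_mode`` "ml" profiles λ on [0, 1]; "fixed" uses
    ``lambda_value``. k counts every column of X plus σ² and λ. The
    adjusted R² is the GLS analogue computed against an intercept-only fit
    under the same V.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"b{i}" for i in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is rank deficient")
    if np.allclose(y, y[0]):
        return GlsFit(beta=np.full(p, np.nan), se=np.full(p, np.nan),
                      names=list(names), sigma2=0.0, lam=0.0,
                      loglik=np.nan, k=p + 2, n=n, aicc=np.nan,
                      r2_adj=np.nan, degenerate=True)

    if lambda_mode == "fixed":
        if lambda_value is None:
            raise ValueError("lambda_value required with lambda_mode='fixed'")
        lam = float(lambda_value)
    elif lambda_mode == "ml":
        grid = np.linspace(0.0, 1.0, 101)
        lls = np.array([_ll_at(X, y, C, g) for g in grid])
        if not np.isfinite(lls).any():
            out = _profile(X, y, C, 0.0)
            if out is not None and out[0] is None:
                # perfect fit: residual variance exactly zero
                return GlsFit(beta=out[1], se=np.zeros(p), names=list(names),
                              sigma2=0.0, lam=0.0, loglik=np.nan, k=p + 2,
                              n=n, aicc=np.nan, r2_adj=np.nan, degenerate=True)
            raise ValueError("profile likelihood undefined on the whole "
                             "lambda grid (singular V)")
        i = int(np.nanargmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = minimize_scalar(lambda g: -_ll_at(X, y, C, g),
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-6})
            lam = float(res.x) if -res.fun >= lls[i] else float(grid[i])
        else:
            lam = float(grid[i])
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    out = _profile(X, y, C, lam)
    if out is None:
        raise ValueError(f"singular V at lambda={lam}")
    ll, beta, sigma2, logdet, cf, XtViX = out
    if ll is None:
        return GlsFit(beta=beta, se=np.full(p, np.nan), names=list(names),
                      sigma2=0.0, lam=lam, loglik=np.nan, k=p + 2, n=n,
                      aicc=np.nan, r2_adj=np.nan, degenerate=True)
    # standard errors with the unbiased residual variance
    s2_unb = sigma2 * n / max(n - p, 1)
    se = np.sqrt(np.diag(np.linalg.inv(XtViX)) * s2_unb)

    # GLS R^2 against the intercept-only model under the same V
    ones = np.ones((n, 1))
    out0 = _profile(ones, y, C, lam)
    b0 = out0[1] if out0 is not None else np.array([y.mean()])
    e0 = y - ones @ b0
    sst = float(e0 @ cho_solve(cf, e0))
    e = y - X @ beta
    sse = float(e @ cho_solve(cf, e))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    p_terms = p - 1  # assumes an intercept column
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_terms - 1) if n - p_terms - 1 > 0 else np.nan

    k = p + 2
    return GlsFit(beta=beta, se=se, names=list(names), sigma2=float(sigma2),
                  lam=lam, loglik=float(ll), k=k, n=n,
                  aicc=_aicc(ll, k, n) if n > k + 1 else np.nan,
                  r2_adj=float(r2_adj))


# ---------------------------------------------------------------------
# the habitat/altitude model set

def build_design(df: pd.DataFrame, terms: str,
                 habitat_col: str = "paramo") -> tuple[np.ndarray, list]:
    """Design matrix for one model of the set.

    Habitat enters as a 0/1 dummy (reference level = 0, i.e. non-páramo or
    sheltered); altitude stays in metres. ``terms`` is one of
    ``MODEL_TERMS``; the interaction model contains both main effects.
    """
    if terms not in MODEL_TERMS:
        raise ValueError(f"unknown model terms {terms!r}")
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    alt = df["altitude"].to_numpy(dtype=float)
    hab = df[habitat_col].to_numpy(dtype=float)
    if "altitude" in terms:
        cols.append(alt)
        names.append("altitude")
    if "habitat" in terms:
        cols.append(hab)
        names.append("habitat")
    if "*" in terms:
        cols.append(alt * hab)
        names.append("altitude:habitat")
    return np.column_stack(cols), names


def fit_pgls_models(tree: Phylogeny, table: pd.DataFrame, response: str,
                    log_transform: bool = True, habitat_col: str = "paramo",
                    lambda_mode: str = "ml") -> dict:
    """Fit the four-model habitat/altitude set for one response on one tree.

    Table rows are matched to tips by ``specimen_id``; tips with missing
    response, altitude or habitat are dropped (tree pruned accordingly,
    count reported via a warning). Models with fewer than 3 residual
    degrees of freedom are skipped. Returns {terms: GlsFit or None}.
    """
    df = table.set_index("specimen_id")
    df = df.loc[[t for t in tree.tip_labels if t in df.index]]
    needed = df[[response, "altitude", habitat_col]].apply(
        pd.to_numeric, errors="coerce")
    good = needed.dropna().index.tolist()
    dropped = len(tree.tip_labels) - len(good)
    if dropped:
        warnings.warn(f"dropped {dropped} tips with missing {response}/"
                      f"altitude/{habitat_col}")
    if len(good) < 3:
        raise ValueError("fewer than 3 usable tips")
    sub = tree.retain_tips(good) if dropped or len(good) < tree.n_tips else tree
    df = df.loc[sub.tip_labels]
    C = sub.vcv()
    y = df[response].to_numpy(dtype=float)
    if log_transform:
        y = np.log(y)
    fits = {}
    for terms in MODEL_TERMS:
        X, names = build_design(df, terms, habitat_col)
        if len(y) - X.shape[1] < 3:
            warnings.warn(f"model {terms!r} skipped: <3 residual df")
            fits[terms] = None
            continue
        try:
            fits[terms] = gls_fit(X, y, C, lambda_mode=lambda_mode, names=names)
        except ValueError as exc:
            warnings.warn(f"model {terms!r} skipped: {exc}")
            fits[terms] = None
    return fits


def fit_model_set(tree_sample: TreeSample, table: pd.DataFrame, response: str,
                  log_transform: bool = True, habitat_col: str = "paramo") -> list:
    """Apply :func:`fit_pgls_models` to every tree of a posterior sample."""
    return [fit_pgls_models(t, table, response, log_transform=log_transform,
                            habitat_col=habitat_col) for t in tree_sample]
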