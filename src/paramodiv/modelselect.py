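"""AICc scoring, Akaike weights, and cross-tree aggregation.

Model support is averaged the way comparative studies on posterior tree
samples do it: AICc, ΔAICc and Akaike weights are computed *per tree* and
their arithmetic means taken across trees (averaging weights preserves the
simplex; the weights of averaged ΔAICc would not). Parameter estimates are
summarised as the median with 5th/95th percentiles across trees, using the
linear-interpolation quantile rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["aicc", "akaike_weights", "score_models", "aggregate",
           "CrossTreeSummary"]


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    ``-2 logL + 2k + 2k(k+1)/(n-k-1)``; undefined for ``n <= k+1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Normalized relative likelihoods exp(-ΔAICc/2) of a model set."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 1 or not np.isfinite(a).any():
        raise ValueError("need at least one finite AICc value")
    delta = a - np.nanmin(a[np.isfinite(a)])
    rel = np.where(np.isfinite(delta), np.exp(-delta / 2.0), 0.0)
    return rel / rel.sum()


def score_models(fits: pd.DataFrame) -> pd.DataFrame:
    """Attach ΔAICc and Akaike weights to a one-tree model table.

    ``fits`` needs columns ``model`` and ``aicc``; rows are one comparison
    set. Returns a copy with ``delta_aicc`` and ``weight`` columns.
    """
    out = fits.copy()
    a = out["aicc"].to_numpy(dtype=float)
    out["delta_aicc"] = a - np.nanmin(a)
    out["weight"] = akaike_weights(a)
    return out


@dataclass
class CrossTreeSummary:
    """Per-model score averages and per-parameter percentiles over trees."""

    scores: pd.DataFrame      # model, mean_aicc, mean_delta_aicc, mean_weight, n_trees
    params: pd.DataFrame      # model, parameter, median, q05, q95
    n_trees: int
    n_failed: int = 0

    @property
    def best_model(self) -> str:
        """Lowest mean AICc (the conventional 'overall best model')."""
        return str(self.scores.loc[self.scores["mean_aicc"].idxmin(), "model"])


def aggregate(per_tree_scores: list[pd.DataFrame],
              per_tree_params: list[pd.DataFrame] | None = None) -> CrossTreeSummary:
    """Average model scores, and summarise parameters, across a tree sample.

    Each element of ``per_tree_scores`` is one tree's scored model table
    (``model``, ``logLik``, ``k``, ``aicc`` at minimum; ΔAICc/weights are
    recomputed here per tree before averaging). Failed fits are passed as
    NaN logLik rows or absent rows; a model missing from more than half the
    trees is an error. ``per_tree_params`` rows carry
    ``model``, ``parameter``, ``value``.
    """
    if not per_tree_scores:
        raise ValueError("no per-tree scores to aggregate")
    scored = []
    for i, df in enumerate(per_tree_scores):
        ok = df[np.isfinite(df["aicc"].astype(float))]
        if len(ok) == 0:
            continue
        s = score_models(ok)
        s = s.assign(tree=i)
        scored.append(s)
    if not scored:
        raise ValueError("all trees failed")
    big = pd.concat(scored, ignore_index=True)
    models = list(dict.fromkeys(pd.concat(per_tree_scores)["model"]))
    n_trees = len(per_tree_scores)
    counts = big.groupby("model")["tree"].nunique()
    for m in models:
        if counts.get(m, 0) <= n_trees / 2.0:
            raise ValueError(
                f"model {m!r} fitted successfully in only {counts.get(m, 0)}"
                f"/{n_trees} trees")
    agg = (big.groupby("model", sort=False)
              .agg(mean_aicc=("aicc", "mean"),
                   mean_delta_aicc=("delta_aicc", "mean"),
                   mean_weight=("weight", "mean"),
                   n_trees=("tree", "nunique"))
              .reindex(models).reset_index())
    n_failed = int(sum(n_trees - counts.get(m, 0) for m in models))

    if per_tree_params:
        pp = pd.concat(per_tree_params, ignore_index=True)
        rows = []
        for (m, p), grp in pp.groupby(["model", "parameter"], sort=False):
            v = grp["value"].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            rows.append({"model": m, "parameter": p,
                         "median": np.quantile(v, 0.5),
                         "q05": np.quantile(v, 0.05),
                         "q95": np.quantile(v, 0.95)})
        params = pd.DataFrame(rows, columns=["model", "parameter",
                                             "median", "q05", "q95"])
    else:
        params = pd.DataFrame(columns=["model", "parameter", "median", "q05", "q95"])
    return CrossTreeSummary(scores=agg, params=params,
                            n_trees=n_trees, n_failed=n_failed)
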