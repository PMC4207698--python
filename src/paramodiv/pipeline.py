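"""End-to-end orchestration over a posterior tree sample.

Two entry points mirror the study design:

* :func:`run_diversification` — per tree: draw one exemplar tip per
  species, fit the four BiSSE parameter-sharing schemes, score by AICc;
  aggregate across trees and export the speciation-rate densities
  (páramo, non-páramo, and their difference) of the best model.
* :func:`run_morphology` — per tree: the four-model PGLS habitat/altitude
  set per leaf trait on the full (locality-tip) trees, and the four
  state-dependent BM models per trait on exemplar trees painted from BiSSE
  marginal ancestral states (or from observed microhabitat).

All outputs are plain CSV plus a JSON run manifest recording config and
seed; runs are deterministic given both.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bisse as _bisse
from . import modelselect as ms
from . import pgls as _pgls
from . import traitrate as tr
from .simulate import stream_rng
from .trees import Phylogeny, SamplingFractions, TreeSample

log = logging.getLogger("paramodiv")

__all__ = ["RunConfig", "run_diversification", "run_morphology", "write_outputs"]

RESPONSES = ("pinnae_length", "leaves_per_frond")


@dataclass
class RunConfig:
    """Run-wide options; defaults mirror the study design."""

    n_trees: int | None = None          # None = all trees in the sample
    seed: int = 0
    f0: float = 4.0 / 12.0
    f1: float = 22.0 / 43.0
    bisse_models: tuple = ("full6", "eq_rates4", "sdd_speciation4", "null3")
    pgls_models: tuple = _pgls.MODEL_TERMS
    trait_models: tuple = tr.TRAIT_MODELS
    painting: str = "bisse"             # or "microhabitat"
    painting_model: str = "sdd_speciation4"
    root_mode: str = "obs"
    condition_on_survival: bool = False
    log_transform: bool = True
    n_restarts: int = 3
    max_failed_fraction: float = 0.2

    def manifest(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _species_states(table: pd.DataFrame, column: str = "paramo") -> pd.Series:
    """Specimen-level binary states (1 = páramo-present / exposed)."""
    if column == "microhabitat":
        col = table["microhabitat"]
        if col.isna().all() or (col == "unknown").all():
            raise ValueError("microhabitat column is empty/unknown; cannot "
                             "use painting='microhabitat'")
        m = col.map({"exposed": 1, "sheltered": 0})
        return pd.Series(m.values, index=table["specimen_id"].values).dropna().astype(int)
    return pd.Series(table[column].values,
                     index=table["specimen_id"].values).astype(int)


def _exemplar(tree: Phylogeny, table: pd.DataFrame, seed: int, i: int) -> Phylogeny:
    rng = np.random.Generator(np.random.Philox(
        np.random.SeedSequence([seed, 71, i])))
    from .trees import sample_exemplars
    return sample_exemplars(tree.resolve_polytomies(), table, rng)


def run_diversification(sample: TreeSample, table: pd.DataFrame,
                        config: RunConfig | None = None) -> dict:
    """Fit and score the BiSSE model set on every tree of the sample.

    Returns a dict with keys ``per_tree`` (one row per tree × model),
    ``summary`` (a :class:`~paramodiv.modelselect.CrossTreeSummary`), and
    ``densities`` (per-tree λ̂0, λ̂1 and their difference,
    páramo − non-páramo, from the best model overall).
    """
    config = config or RunConfig()
    f = SamplingFractions(config.f0, config.f1)
    states_all = _species_states(table)
    n_use = min(config.n_trees or len(sample), len(sample))
    rows, score_frames, param_frames = [], [], []
    n_failed_trees = 0
    for i in range(n_use):
        t0 = time.perf_counter()
        try:
            ex = _exemplar(sample[i], table, config.seed, i)
            st = states_all[ex.tip_labels]
        except ValueError as exc:
            log.warning("tree %d skipped: %s", i, exc)
            n_failed_trees += 1
            continue
        tree_rows = []
        for mname in config.bisse_models:
            fit = _bisse.fit_bisse(ex, st, f, spec=mname,
                                   n_restarts=config.n_restarts,
                                   seed=config.seed * 1009 + i,
                                   root_mode=config.root_mode,
                                   condition_on_survival=config.condition_on_survival)
            if not fit.converged:
                log.warning("tree %d model %s did not converge; excluded",
                            i, mname)
            row = {"tree": i, "model": mname, "logLik": fit.loglik,
                   "k": fit.k, "n": fit.n,
                   "aicc": fit.aicc if fit.converged else np.nan,
                   "converged": fit.converged}
            row.update({f"p_{nm}": v for nm, v in
                        zip(("lambda0", "lambda1", "mu0", "mu1", "q01", "q10"),
                            fit.params.as_array())})
            tree_rows.append(row)
        rows.extend(tree_rows)
        df = pd.DataFrame(tree_rows)
        score_frames.append(df[["model", "logLik", "k", "aicc"]])
        pf = df.melt(id_vars=["model"],
                     value_vars=[c for c in df.columns if c.startswith("p_")],
                     var_name="parameter", value_name="value")
        pf["parameter"] = pf["parameter"].str.removeprefix("p_")
        param_frames.append(pf)
        log.info("tree %d: %d models in %.2fs", i, len(tree_rows),
                 time.perf_counter() - t0)
    if n_failed_trees > config.max_failed_fraction * n_use:
        raise RuntimeError(f"{n_failed_trees}/{n_use} trees failed")
    summary = ms.aggregate(score_frames, param_frames)
    per_tree = pd.DataFrame(rows)
    best = summary.best_model
    bb = per_tree[(per_tree["model"] == best) & per_tree["converged"]]
    densities = pd.DataFrame({
        "tree": bb["tree"].values,
        "lambda0": bb["p_lambda0"].values,
        "lambda1": bb["p_lambda1"].values,
        # páramo speciation rate − non-páramo speciation rate
        "lambda_diff": bb["p_lambda1"].values - bb["p_lambda0"].values,
    })
    return {"per_tree": per_tree, "summary": summary, "densities": densities}


def _paint_tree(ex: Phylogeny, st: pd.Series, config: RunConfig,
                f: SamplingFractions, seed: int) -> tr.PaintedTree:
    fit = _bisse.fit_bisse(ex, st, f, spec=config.painting_model,
                           n_restarts=config.n_restarts, seed=seed,
                           root_mode=config.root_mode,
                           condition_on_survival=config.condition_on_survival)
    marg = _bisse.marginal_asr(ex, st, fit.params, f,
                               root_mode=config.root_mode,
                               condition_on_survival=config.condition_on_survival)
    return _bisse.paint_branches(ex, marg, st)


def run_morphology(sample: TreeSample, table: pd.DataFrame,
                   config: RunConfig | None = None,
                   responses=RESPONSES) -> dict:
    """PGLS model sets and painted-BM trait-rate models over the sample.

    Returns ``{"pgls": {response: {...}}, "traitrate": {response: {...}}}``
    with per-tree tables and cross-tree summaries in each leaf dict.
    """
    config = config or RunConfig()
    f = SamplingFractions(config.f0, config.f1)
    n_use = min(config.n_trees or len(sample), len(sample))
    paint_col = "microhabitat" if config.painting == "microhabitat" else "paramo"
    states_all = _species_states(table, paint_col)

    pgls_scores = {r: [] for r in responses}
    pgls_rows = {r: [] for r in responses}
    pgls_params = {r: [] for r in responses}
    tr_scores = {r: [] for r in responses}
    tr_rows = {r: [] for r in responses}
    tr_params = {r: [] for r in responses}

    spec_traits = table.set_index("specimen_id")
    for i in range(n_use):
        tree = sample[i].resolve_polytomies()
        # PGLS on the full (locality-tip) tree
        for r in responses:
            fits = _pgls.fit_pgls_models(tree, table, r,
                                         log_transform=config.log_transform)
            rws = []
            for terms, fit in fits.items():
                if fit is None or fit.degenerate:
                    rws.append({"tree": i, "model": terms, "logLik": np.nan,
                                "k": np.nan, "aicc": np.nan, "lambda": np.nan,
                                "r2_adj": np.nan})
                    continue
                row = {"tree": i, "model": terms, "logLik": fit.loglik,
                       "k": fit.k, "aicc": fit.aicc, "lambda": fit.lam,
                       "r2_adj": fit.r2_adj}
                row.update({f"b_{nm}": b for nm, b in zip(fit.names, fit.beta)})
                rws.append(row)
            pgls_rows[r].extend(rws)
            df = pd.DataFrame(rws)
            pgls_scores[r].append(df[["model", "logLik", "k", "aicc"]])
            pf = df.melt(id_vars=["model"],
                         value_vars=[c for c in df.columns
                                     if c.startswith("b_") or c in ("lambda", "r2_adj")],
                         var_name="parameter", value_name="value")
            pgls_params[r].append(pf)

        # trait-rate models on the exemplar tree, painted
        ex = _exemplar(sample[i], table, config.seed, i)
        tips_known = [t for t in ex.tip_labels if t in states_all.index]
        if len(tips_known) < ex.n_tips:
            if len(tips_known) < 4:
                raise ValueError(f"too few tips with known {paint_col}")
            ex = ex.retain_tips(tips_known)
        st = states_all[ex.tip_labels]
        painted = _paint_tree(ex, st, config, f, seed=config.seed * 2003 + i)
        for r in responses:
            yv = spec_traits.loc[ex.tip_labels, r].to_numpy(dtype=float)
            if config.log_transform:
                yv = np.log(yv)
            rws = []
            for m in config.trait_models:
                fit = tr.fit_trait_model(painted, yv, m)
                rws.append({"tree": i, "model": m, "logLik": fit.loglik,
                            "k": fit.k, "aicc": fit.aicc,
                            "mean0": fit.mean0, "mean1": fit.mean1,
                            "sigma2": fit.sigma2,
                            "rate_ratio": fit.rate_ratio, "lambda": fit.lam})
            tr_rows[r].extend(rws)
            df = pd.DataFrame(rws)
            tr_scores[r].append(df[["model", "logLik", "k", "aicc"]])
            pf = df.melt(id_vars=["model"],
                         value_vars=["mean0", "mean1", "rate_ratio",
                                     "sigma2", "lambda"],
                         var_name="parameter", value_name="value")
            tr_params[r].append(pf)

    out = {"pgls": {}, "traitrate": {}}
    for r in responses:
        out["pgls"][r] = {
            "per_tree": pd.DataFrame(pgls_rows[r]),
            "summary": ms.aggregate(pgls_scores[r], pgls_params[r]),
        }
        out["traitrate"][r] = {
            "per_tree": pd.DataFrame(tr_rows[r]),
            "summary": ms.aggregate(tr_scores[r], tr_params[r]),
        }
    return out


def write_outputs(out_dir, config: RunConfig, diversification=None,
                  morphology=None) -> None:
    """Write the standard CSV tables and the JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.manifest()}
    if diversification is not None:
        diversification["per_tree"].to_csv(out / "bisse_per_tree.csv", index=False)
        diversification["summary"].scores.to_csv(out / "bisse_summary.csv", index=False)
        diversification["summary"].params.to_csv(out / "bisse_params.csv", index=False)
        diversification["densities"].to_csv(out / "speciation_densities.csv",
                                            index=False)
        manifest["bisse_best_model"] = diversification["summary"].best_model
    if morphology is not None:
        for kind in ("pgls", "traitrate"):
            for r, res in morphology[kind].items():
                stem = f"{kind}_{r}"
                res["per_tree"].to_csv(out / f"{stem}_per_tree.csv", index=False)
                res["summary"].scores.to_csv(out / f"{stem}_summary.csv", index=False)
                res["summary"].params.to_csv(out / f"{stem}_params.csv", index=False)
                manifest[f"{stem}_best_model"] = res["summary"].best_model
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
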