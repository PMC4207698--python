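"""Synthetic-data generation with known truth.

Everything the analysis pipeline consumes can be generated here: binary-
state birth–death trees (exact Gillespie simulation), state-biased
incomplete sampling, Brownian traits with state-specific means/rates plus
λ noise on painted trees, and habitat×altitude regression structure on leaf
traits.

Randomness uses the counter-based Philox generator throughout, with named
per-operation streams derived from a single seed, so each operation is
independently reproducible.

Default parameter values state the world the package's tests assume: a
páramo-like radiation with ~1 speciation event per lineage per Ma in the
derived habitat, twice the background rate; sampling fractions 22/43
(páramo) and 4/12 (non-páramo); páramo altitudes 2800–5000 m against
600–3000 m below; leaf traits analysed on a natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pgls import lambda_transform
from .traitrate import PaintedTree, painted_covariance
from .trees import Phylogeny, TreeSample, _N

__all__ = [
    "stream_rng", "TraitTruth", "RegressionTruth", "SimConfig",
    "simulate_bisse_tree", "subsample_tips", "simulate_painted_bm",
    "simulate_regression_data", "simulate_tree_sample", "simulate_study",
]

_STREAMS = {"tree": 11, "subsample": 23, "traits": 37, "regression": 53,
            "exemplar": 71, "posterior": 89, "pipeline": 101}


def stream_rng(seed: int, stream: str = "tree") -> np.random.Generator:
    """A Philox generator on a named, independently reproducible stream."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown stream {stream!r}; one of {sorted(_STREAMS)}")
    ss = np.random.SeedSequence([int(seed), _STREAMS[stream]])
    return np.random.Generator(np.random.Philox(ss))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(int(rng))))


@dataclass
class TraitTruth:
    """True painted-BM trait parameters (means keyed by edge state)."""

    mean0: float = 4.0
    mean1: float = 2.5
    sigma2: float = 1.0       # state-0 BM rate per Ma
    rate_ratio: float = 1.0   # state-1 rate relative to state 0
    lam: float = 1.0

    def __post_init__(self):
        if self.sigma2 < 0 or self.rate_ratio <= 0:
            raise ValueError("sigma2 must be >= 0 and rate_ratio > 0")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


@dataclass
class RegressionTruth:
    """True linear structure of a (log) leaf trait on altitude and habitat.

    ``response = b0 + b1·altitude + b2·habitat + b3·altitude·habitat + ε``
    with ε a Brownian residual on the tree (λ-transformed), scaled so that
    ``resid_sigma2`` is the residual variance at the tips.
    """

    beta0: float = 4.0
    beta1: float = -6e-4      # per metre
    beta2: float = -0.8       # páramo (habitat=1) effect
    beta3: float = 3e-4       # interaction: shallower decline in páramo
    alt_range0: tuple = (600.0, 3000.0)   # non-páramo, metres
    alt_range1: tuple = (2800.0, 5000.0)  # páramo
    resid_sigma2: float = 0.09
    resid_lambda: float = 0.8

    def __post_init__(self):
        if self.resid_sigma2 < 0:
            raise ValueError("resid_sigma2 must be >= 0")


@dataclass
class SimConfig:
    """The full stated world of one synthetic study."""

    lambda0: float = 0.5
    lambda1: float = 1.0
    mu0: float = 0.1
    mu1: float = 0.1
    q01: float = 0.05
    q10: float = 0.05
    stop_taxa: int | None = 55
    stop_time: float | None = None
    f0: float = 4.0 / 12.0
    f1: float = 22.0 / 43.0
    n_trees: int = 20
    trait_truth: TraitTruth = field(default_factory=TraitTruth)
    pinnae_truth: RegressionTruth = field(default_factory=RegressionTruth)
    leaves_truth: RegressionTruth = field(default_factory=lambda: RegressionTruth(
        beta0=2.2, beta1=3e-4, beta2=0.9, beta3=0.0,
        resid_sigma2=0.0625, resid_lambda=0.0))
    seed: int = 0

    def params_array(self) -> np.ndarray:
        return np.array([self.lambda0, self.lambda1, self.mu0, self.mu1,
                         self.q01, self.q10])


# ---------------------------------------------------------------------
# state-dependent birth–death simulation

def _sim_once(p, stop_taxa, stop_time, root_state, crown, rng, history):
    la = (p[0], p[1])
    mu = (p[2], p[3])
    q = (p[4], p[5])  # q[0]=q01 (out of 0), q[1]=q10 (out of 1)
    tot = (la[0] + mu[0] + q[0], la[1] + mu[1] + q[1])
    root = _N(0.0)
    active: list[list] = []  # [node, state, birth_time]
    n_start = 2 if crown else 1
    for _ in range(n_start):
        c = _N(0.0)
        root.children.append(c)
        active.append([c, root_state, 0.0])
    crown_ids = [id(l[0]) for l in active]
    t = 0.0
    while True:
        if stop_taxa is not None and len(active) >= stop_taxa:
            # observe at a uniform time between the Nth birth and the next
            # event, so pendant edges are strictly positive
            R = sum(tot[l[1]] for l in active)
            if R > 0.0:
                t += rng.exponential(1.0 / R) * rng.random()
            break
        R = sum(tot[l[1]] for l in active)
        if R <= 0.0:
            if stop_time is None:
                return None, None
            break
        dt = rng.exponential(1.0 / R)
        if stop_time is not None and t + dt >= stop_time:
            break
        t += dt
        u = rng.random() * R
        acc = 0.0
        li = len(active) - 1
        for i, l in enumerate(active):
            acc += tot[l[1]]
            if u < acc:
                li = i
                break
        node, s, t0 = active[li]
        v = rng.random() * tot[s]
        if v < la[s]:  # speciation
            node.length = t - t0
            k1, k2 = _N(0.0), _N(0.0)
            node.children = [k1, k2]
            active[li] = [k1, s, t]
            active.append([k2, s, t])
            history["births"] += 1
        elif v < la[s] + mu[s]:  # extinction
            node.length = t - t0
            history["deaths"] += 1
            node.label = f"x{history['deaths']}"
            active.pop(li)
            if not active:
                return None, None
        else:  # anagenetic state change
            active[li][1] = 1 - s
            history["transitions"] += 1
    t_end = t if stop_taxa is not None or stop_time is None else stop_time
    states = {}
    for i, (node, s, t0) in enumerate(active):
        node.length = t_end - t0
        node.label = f"t{i + 1}"
        states[node.label] = s
    if len(active) < 2:
        return None, None
    if crown:
        # crown root kept only when both original subtrees survive
        def has_extant(n):
            if not n.children:
                return n.label in states
            return any(has_extant(c) for c in n.children)
        if not all(has_extant(c) for c in root.children):
            return None, None
    return root, states


def simulate_bisse_tree(params, stop_taxa: int | None = None,
                        stop_time: float | None = None,
                        root_state: int | None = None, crown: bool = True,
                        rng=0, max_retries: int = 1000,
                        return_history: bool = False):
    """Exact stochastic simulation of a binary-state birth–death tree.

    Each lineage in state i waits Exp(λ_i+μ_i+q_ij); the event is chosen by
    relative rates. Extinct lineages are pruned from the returned tree.
    With ``crown=True`` (default) the simulation starts from two root
    lineages and realizations where either crown subtree dies out are
    rejected and redrawn. The root state defaults to a draw from the
    q-stationary distribution.

    Returns ``(Phylogeny, tip_states Series)`` (+ a history dict of event
    counts when ``return_history``).
    """
    p = np.asarray(getattr(params, "as_array", lambda: params)(), dtype=float)
    if p.shape != (6,) or np.any(p < 0):
        raise ValueError("params must be six nonnegative rates")
    if (stop_taxa is None) == (stop_time is None):
        raise ValueError("exactly one of stop_taxa/stop_time is required")
    if stop_taxa is not None and stop_taxa < 2:
        raise ValueError("stop_taxa must be >= 2")
    rng = _as_rng(rng)
    for attempt in range(max_retries):
        if root_state is None:
            qs = p[4] + p[5]
            pi1 = p[4] / qs if qs > 0 else 0.5
            rs = int(rng.random() < pi1)
        else:
            rs = int(root_state)
        history = {"births": 0, "deaths": 0, "transitions": 0}
        root, states = _sim_once(p, stop_taxa, stop_time, rs, crown, rng, history)
        if root is None:
            continue
        full = Phylogeny._from_build(root)
        surviving = [lab for lab in full.tip_labels if lab in states]
        tree = full.retain_tips(surviving) if len(surviving) < full.n_tips else full
        tip_states = pd.Series({lab: states[lab] for lab in tree.tip_labels},
                               dtype=int)
        history["extant"] = len(surviving)
        history["n_start"] = 2 if crown else 1
        if return_history:
            return tree, tip_states, history
        return tree, tip_states
    raise RuntimeError(f"whole-clade extinction in all {max_retries} attempts")


def subsample_tips(tree: Phylogeny, tip_states, f0: float, f1: float, rng=0):
    """Retain each tip independently with its state's sampling fraction.

    Emulates state-biased incomplete taxon sampling. Returns
    ``(pruned tree, retained tip_states)``; errors if fewer than 2 tips
    survive.
    """
    if not (0 < f0 <= 1 and 0 < f1 <= 1):
        raise ValueError("sampling fractions must be in (0, 1]")
    rng = _as_rng(rng)
    s = pd.Series(tip_states)
    u = rng.random(tree.n_tips)
    keep = [lab for lab, ui in zip(tree.tip_labels, u)
            if ui < (f1 if s[lab] == 1 else f0)]
    if len(keep) < 2:
        raise ValueError(f"only {len(keep)} tips retained; need >= 2")
    sub = tree.retain_tips(keep)
    return sub, s[sub.tip_labels].astype(int)


def simulate_painted_bm(painted: PaintedTree, truth: TraitTruth, rng=0) -> np.ndarray:
    """Draw tip values from the exact MVN a painted-BM model implies.

    Mean by pendant-edge state; covariance
    ``λ-transform(σ²·(C_0 + r·C_1))``; one joint draw via Cholesky
    factorization.
    """
    rng = _as_rng(rng)
    pc = painted_covariance(painted)
    V = lambda_transform(truth.sigma2 * (pc.C0 + truth.rate_ratio * pc.C1),
                         truth.lam)
    states = painted.tip_states
    mean = np.where(states == 1, truth.mean1, truth.mean0).astype(float)
    if truth.sigma2 == 0:
        return mean
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(V)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("painted covariance is not PSD") from None
        L = U @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return mean + L @ rng.standard_normal(painted.tree.n_tips)


def _bm_residual(tree: Phylogeny, sigma2: float, lam: float, rng) -> np.ndarray:
    if sigma2 == 0:
        return np.zeros(tree.n_tips)
    C = tree.vcv()
    h = np.diag(C).max()
    V = lambda_transform(sigma2 * C / h, lam)  # unit-height scaling: tip var = sigma2
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    return L @ rng.standard_normal(tree.n_tips)


def simulate_regression_data(tree: Phylogeny, tip_states, rng=0,
                             pinnae_truth: RegressionTruth | None = None,
                             leaves_truth: RegressionTruth | None = None) -> pd.DataFrame:
    """Build a specimen table with habitat×altitude structure on both traits.

    Altitude is uniform over the per-habitat range; each log trait follows
    its :class:`RegressionTruth` linear predictor plus a λ-transformed BM
    residual on the tree. Traits are stored on their natural scale
    (pinnae_length in mm; leaves_per_frond as a count, rounded, min 1).
    """
    rng = _as_rng(rng)
    pinnae_truth = pinnae_truth or RegressionTruth()
    leaves_truth = leaves_truth or SimConfig().leaves_truth
    s = pd.Series(tip_states)[tree.tip_labels].to_numpy(dtype=int)
    alt = np.empty(tree.n_tips)
    for i, st in enumerate(s):
        lo, hi = pinnae_truth.alt_range1 if st == 1 else pinnae_truth.alt_range0
        alt[i] = rng.uniform(lo, hi)

    def linpred(tr):
        return (tr.beta0 + tr.beta1 * alt + tr.beta2 * s
                + tr.beta3 * alt * s)

    log_pin = linpred(pinnae_truth) + _bm_residual(
        tree, pinnae_truth.resid_sigma2, pinnae_truth.resid_lambda, rng)
    log_lvs = linpred(leaves_truth) + _bm_residual(
        tree, leaves_truth.resid_sigma2, leaves_truth.resid_lambda, rng)
    leaves = np.maximum(np.rint(np.exp(log_lvs)), 1.0)
    return pd.DataFrame({
        "specimen_id": tree.tip_labels,
        "species_id": tree.tip_labels,
        "paramo": s,
        "microhabitat": np.where(s == 1, "exposed", "sheltered"),
        "altitude": np.clip(alt, 0.0, 6000.0),
        "pinnae_length": np.exp(log_pin),
        "leaves_per_frond": leaves,
    })


def simulate_tree_sample(tree: Phylogeny, n: int, rng=0, rel_sd: float = 0.05,
                         scale_sd: float = 0.1) -> TreeSample:
    """Emulate a posterior sample: jittered, re-ultrametrized copies.

    Each replicate rescales the whole tree by a lognormal factor
    (divergence-time uncertainty) and every edge by independent lognormal
    noise, then restores ultrametricity by extending pendant edges to the
    maximum depth. Topology is common to all replicates, as is typical of
    a well-resolved posterior.
    """
    rng = _as_rng(rng)
    trees = []
    for _ in range(n):
        factor = float(np.exp(rng.normal(0.0, scale_sd)))
        elen = tree.edge_length * factor * np.exp(
            rng.normal(0.0, rel_sd, size=tree.n_nodes))
        t2 = Phylogeny(tree.tip_labels, tree.parent, elen,
                       [list(c) for c in tree.children])
        d = t2.node_depths()[: t2.n_tips]
        elen2 = t2.edge_length.copy()
        elen2[: t2.n_tips] += d.max() - d
        trees.append(Phylogeny(tree.tip_labels, tree.parent, elen2,
                               [list(c) for c in tree.children]))
    return TreeSample(trees, source="synthetic-posterior")


def simulate_study(config: SimConfig):
    """Generate a full synthetic study: posterior-like tree sample + table.

    Returns ``(TreeSample, specimen table, tip_states, true tree)``. The
    same Newick/CSV formats the I/O layer reads are used when writing, so
    synthetic runs exercise the full input path.
    """
    rng_tree = stream_rng(config.seed, "tree")
    full_tree, full_states = simulate_bisse_tree(
        config.params_array(), stop_taxa=config.stop_taxa,
        stop_time=config.stop_time, rng=rng_tree)
    # the 'described species' world is the complete clade; the phylogeny
    # samples it with the per-state fractions the analysis will assume
    if config.f0 < 1.0 or config.f1 < 1.0:
        tree, states = subsample_tips(full_tree, full_states, config.f0,
                                      config.f1,
                                      rng=stream_rng(config.seed, "subsample"))
    else:
        tree, states = full_tree, full_states
    sample = simulate_tree_sample(tree, config.n_trees,
                                  rng=stream_rng(config.seed, "posterior"))
    table = simulate_regression_data(
        tree, states, rng=stream_rng(config.seed, "regression"),
        pinnae_truth=config.pinnae_truth, leaves_truth=config.leaves_truth)
    return sample, table, states, full_tree
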