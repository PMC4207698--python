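"""State-dependent Brownian-motion models on painted trees.

A *painting* assigns every edge a binary state. The Brownian covariance of
the tips then splits exactly into per-state parts: ``C_s(i,j)`` is the
length of state-``s`` edges on the shared root→MRCA path of tips i and j,
and ``C_0 + C_1`` recovers the ordinary BM covariance. The four candidate
models share or split the trait mean and the BM rate between states:

    1. common mean, common rate            (k = 3: mean, σ², λ)
    2. common mean, state rates            (k = 4: + rate ratio r)
    3. state means, common rate            (k = 4: + second mean)
    4. state means, state rates            (k = 5)

Rates are reported as a ratio r of the state-1 (exposed/páramo) rate to the
state-0 (sheltered) rate, state 0 ≡ 1. Pagel's λ is fitted simultaneously,
applied to the off-diagonals of the already state-scaled covariance
``σ²(C_0 + r·C_1)`` — a tip-measurement-noise adjustment. Mean groups are
keyed to each tip's observed state (the pendant-edge state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .modelselect import aicc as _aicc
from .pgls import lambda_transform
from .trees import Phylogeny

__all__ = ["PaintedTree", "PaintedCovariance", "painted_covariance",
           "TraitFit", "fit_trait_model", "bm_ancestral_states",
           "TRAIT_MODELS"]

TRAIT_MODELS = (1, 2, 3, 4)
_STATE_MEANS = {1: False, 2: False, 3: True, 4: True}
_STATE_RATES = {1: False, 2: True, 3: False, 4: True}
_K = {1: 3, 2: 4, 3: 4, 4: 5}


@dataclass
class PaintedTree:
    """A phylogeny plus a binary state for every edge.

    ``edge_state[n]`` is the state of the edge subtending node ``n`` (for
    the root, the state assigned to the root node itself). Pendant edges
    carry their tip's observed state.
    """

    tree: Phylogeny
    edge_state: np.ndarray
    tie_nodes: list = field(default_factory=list)

    def __post_init__(self):
        self.edge_state = np.asarray(self.edge_state, dtype=np.int8)
        if self.edge_state.shape[0] != self.tree.n_nodes:
            raise ValueError("edge_state must cover every node")
        if np.any((self.edge_state != 0) & (self.edge_state != 1)):
            raise ValueError("unpainted or non-binary edge state")

    @property
    def tip_states(self) -> np.ndarray:
        return self.edge_state[: self.tree.n_tips]


@dataclass
class PaintedCovariance:
    """Per-state shared-path covariance components (C_0 + C_1 = full BM C)."""

    C0: np.ndarray
    C1: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.C0 + self.C1


def painted_covariance(painted: PaintedTree) -> PaintedCovariance:
    """Split the BM covariance by the painting, exactly conserving the sum."""
    tree = painted.tree
    ntip = tree.n_tips
    # per-state root-to-node path lengths
    plen = np.zeros((tree.n_nodes, 2))
    for n in tree.postorder[::-1]:
        par = tree.parent[n]
        if par < 0:
            continue
        plen[n] = plen[par]
        plen[n, painted.edge_state[n]] += tree.edge_length[n]
    C = [np.zeros((ntip, ntip)), np.zeros((ntip, ntip))]
    tipsets: dict[int, np.ndarray] = {}
    for n in tree.postorder:
        if len(tree.children[n]) == 0:
            tipsets[n] = np.array([n])
            for s in (0, 1):
                C[s][n, n] = plen[n, s]
        else:
            kids = [tipsets[int(c)] for c in tree.children[n]]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for s in (0, 1):
                        C[s][np.ix_(kids[a], kids[b])] = plen[n, s]
                        C[s][np.ix_(kids[b], kids[a])] = plen[n, s]
            tipsets[n] = np.concatenate(kids)
    return PaintedCovariance(C0=C[0], C1=C[1])


@dataclass
class TraitFit:
    """An ML fit of one state-dependent BM model."""

    model: int
    mean0: float           # sheltered / non-páramo (state 0)
    mean1: float           # exposed / páramo (state 1); == mean0 for models 1, 2
    sigma2: float          # state-0 BM rate
    rate_ratio: float      # state-1 rate relative to state 0 (1 for models 1, 3)
    lam: float
    loglik: float
    k: int
    n: int
    aicc: float
    degenerate: bool = False
    degraded: bool = False


def _mvn_profile(X, y, V):
    n = len(y)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = cho_solve(cf, X)
    beta = np.linalg.solve(X.T @ Vi_X, X.T @ cho_solve(cf, y))
    e = y - X @ beta
    sigma2 = float(e @ cho_solve(cf, e)) / n
    if sigma2 <= 0 or not np.isfinite(sigma2):
        return None
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2


def fit_trait_model(painted: PaintedTree, y, model: int,
                    lambda_mode: str = "ml") -> TraitFit:
    """ML fit of one of the four state-dependent BM models.

    σ² and the mean(s) are profiled in closed form; λ (and log r where the
    model licenses state rates) are optimized numerically with multiple
    starts. If one state is absent from the tips the state-mean design
    degrades to a common mean (flagged ``degraded``).
    """
    if model not in TRAIT_MODELS:
        raise ValueError(f"unknown trait model {model}")
    y = np.asarray(y, dtype=float)
    tree = painted.tree
    n = tree.n_tips
    if y.shape[0] != n:
        raise ValueError("y must have one value per tip")
    pc = painted_covariance(painted)
    states = painted.tip_states.astype(float)

    degraded = False
    if _STATE_MEANS[model] and len(np.unique(states)) < 2:
        warnings.warn(f"model {model}: one state absent from tips; "
                      "degrading to a common mean")
        degraded = True
    use_means = _STATE_MEANS[model] and not degraded
    if use_means:
        X = np.column_stack([1.0 - states, states])  # per-state group means
    else:
        X = np.ones((n, 1))

    state_rates = _STATE_RATES[model]
    if state_rates and not np.any(pc.C1) or state_rates and not np.any(pc.C0):
        warnings.warn(f"model {model}: painting is single-state; rate ratio "
                      "not identifiable, fixed at 1")
        state_rates = False
        degraded = True

    if np.allclose(y, y[0]):
        m = float(y[0])
        return TraitFit(model=model, mean0=m, mean1=m, sigma2=0.0,
                        rate_ratio=1.0, lam=0.0, loglik=np.nan, k=_K[model],
                        n=n, aicc=np.nan, degenerate=True, degraded=degraded)

    fixed_lam = lambda_mode == "fixed"

    def eval_at(lam, logr):
        V0 = pc.C0 + np.exp(logr) * pc.C1
        out = _mvn_profile(X, y, lambda_transform(V0, lam))
        return out

    def neg(theta):
        if state_rates and not fixed_lam:
            lam, logr = theta
        elif state_rates:
            lam, logr = 1.0, theta[0]
        else:
            lam, logr = theta[0], 0.0
        if not (0.0 <= lam <= 1.0):
            return 1e10
        out = eval_at(lam, logr)
        return -out[0] if out is not None else 1e10

    lr_b = (np.log(1e-6), np.log(1e6))
    if state_rates:
        starts, bounds = [], []
        lam_starts = [1.0] if fixed_lam else [0.0, 0.5, 1.0]
        for lam0 in lam_starts:
            for lr0 in (-1.5, 0.0, 1.5):
                starts.append(([lr0] if fixed_lam else [lam0, lr0]))
        bounds = ([lr_b] if fixed_lam else [(0.0, 1.0), lr_b])
        best = None
        for x0 in starts:
            res = minimize(neg, np.asarray(x0, float), method="L-BFGS-B",
                           bounds=bounds, options={"ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        if fixed_lam:
            lam, logr = 1.0, float(best.x[0])
        else:
            lam, logr = float(best.x[0]), float(best.x[1])
    else:
        if fixed_lam:
            lam, logr = 1.0, 0.0
        else:
            grid = np.linspace(0.0, 1.0, 21)
            vals = [neg([g]) for g in grid]
            i = int(np.argmin(vals))
            lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
            res = minimize_scalar(lambda g: neg([g]), bounds=(lo, hi),
                                  method="bounded", options={"xatol": 1e-6})
            lam = float(res.x) if res.fun <= vals[i] else float(grid[i])
            logr = 0.0

    out = eval_at(lam, logr)
    if out is None:
        return TraitFit(model=model, mean0=np.nan, mean1=np.nan, sigma2=np.nan,
                        rate_ratio=np.exp(logr), lam=lam, loglik=-np.inf,
                        k=_K[model], n=n, aicc=np.inf, degenerate=True,
                        degraded=degraded)
    ll, beta, sigma2 = out
    if use_means:
        mean0, mean1 = float(beta[0]), float(beta[1])
    else:
        mean0 = mean1 = float(beta[0])
    k = _K[model]
    return TraitFit(model=model, mean0=mean0, mean1=mean1, sigma2=sigma2,
                    rate_ratio=float(np.exp(logr)), lam=lam, loglik=float(ll),
                    k=k, n=n, aicc=_aicc(ll, k, n) if n > k + 1 else np.nan,
                    degraded=degraded)


# ---------------------------------------------------------------------
# BM ancestral states (phylomorphospace support)

def bm_ancestral_states(tree: Phylogeny, y) -> np.ndarray:
    """ML ancestral values at internal nodes under Brownian motion.

    Equals the GLS/conditional-expectation estimate: the root takes the GLS
    grand mean and every node the conditional mean of the joint Gaussian
    given the tips. Returns an array over all nodes (tips carry their
    observed values).
    """
    y = np.asarray(y, dtype=float)
    ntip = tree.n_tips
    depth = tree.node_depths()
    C = tree.vcv()
    cf = cho_factor(C, lower=True)
    ones = np.ones(ntip)
    Vi_y = cho_solve(cf, y)
    Vi_1 = cho_solve(cf, ones)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)

    # descendant-tip indicator per node
    desc = np.zeros((tree.n_nodes, ntip), dtype=bool)
    for n in tree.postorder:
        if len(tree.children[n]) == 0:
            desc[n, n] = True
        else:
            for c in tree.children[n]:
                desc[n] |= desc[int(c)]

    out = np.empty(tree.n_nodes)
    out[:ntip] = y
    resid_w = cho_solve(cf, y - mu * ones)
    for v in range(ntip, tree.n_nodes):
        # cov(node v, tip i) = depth of MRCA(v, i)
        cov = np.empty(ntip)
        a = v
        covered = np.zeros(ntip, dtype=bool)
        while a >= 0:
            new = desc[a] & ~covered
            cov[new] = depth[a]
            covered |= desc[a]
            a = tree.parent[a]
        cov[desc[v]] = depth[v]
        out[v] = mu + float(cov @ resid_w)
    return out
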