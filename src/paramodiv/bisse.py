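"""Binary-state speciation and extinction (BiSSE) likelihood machinery.

The model: a lineage in binary state ``i`` speciates at rate λ_i, goes
extinct at rate μ_i, and switches state anagenetically at rate q_ij. Along
each branch the standard coupled ODEs are integrated (time measured
rootward from the branch's tipward end):

    dE_i/dt = μ_i − (λ_i + μ_i + q_ij) E_i + q_ij E_j + λ_i E_i²
    dD_i/dt = −(λ_i + μ_i + q_ij) D_i + q_ij D_j + 2 λ_i E_i D_i

``E_i`` is the probability that a lineage in state ``i`` leaves no sampled
descendant; ``D_i`` the likelihood density of the observed subtree.
Incomplete, state-biased sampling enters through per-state sampling
fractions ``f_i``: at a tip in state ``i``, ``D_i = f_i`` (other state 0)
and ``E = 1 − f`` for both states. At internal nodes
``D_i ← D_i^left · D_i^right · λ_i``.

Integration uses an adaptive Cash–Karp Runge–Kutta (rtol 1e-8, atol 1e-10)
compiled with numba; per-node rescaling keeps D in range, with the log
compensation accumulated into the log-likelihood.

State coding throughout the package: 0 = non-páramo, 1 = páramo-present
(the field data scores presence as 0; it is recoded on input so that λ1 is
the páramo speciation rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .modelselect import aicc as _aicc
from .trees import Phylogeny, SamplingFractions
from .traitrate import PaintedTree

__all__ = [
    "BisseParams", "BisseModelSpec", "BisseFit", "MODEL_SPECS",
    "bisse_loglik", "fit_bisse", "marginal_asr", "paint_branches",
    "tip_state_array",
]

_ROOT_MODES = {"obs": 0, "equal": 1, "stationary": 2}


@dataclass
class BisseParams:
    """The six BiSSE rates (per lineage per unit branch length)."""

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float

    def __post_init__(self):
        for name in ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda0, self.lambda1, self.mu0, self.mu1,
                         self.q01, self.q10])

    @classmethod
    def from_array(cls, a) -> "BisseParams":
        return cls(*[float(x) for x in a])


# ---------------------------------------------------------------------
# numba core

_SAFETY = 0.9


@njit(cache=True)
def _rkck(y, p, t_total, rtol, atol, nvar, matrix_mode):
    """Adaptive Cash–Karp RK4(5) over [0, t_total], in place on y.

    ``matrix_mode`` switches the D-part derivative between a single D-pair
    (nvar=4) and a 2x2 fundamental-matrix system (nvar=6, columns of the
    branch propagator). Returns 0 on success, 1 on step-size failure.
    """
    if t_total <= 0.0:
        return 0
    k1 = np.empty(nvar)
    k2 = np.empty(nvar)
    k3 = np.empty(nvar)
    k4 = np.empty(nvar)
    k5 = np.empty(nvar)
    k6 = np.empty(nvar)
    ytmp = np.empty(nvar)
    y4 = np.empty(nvar)
    y5 = np.empty(nvar)

    rate = p[0] + p[2] + p[4]
    r2 = p[1] + p[3] + p[5]
    if r2 > rate:
        rate = r2
    h = t_total
    if rate > 0.0 and 0.1 / rate < h:
        h = 0.1 / rate
    t = 0.0
    hmin = t_total * 1e-14
    it = 0
    while t < t_total:
        it += 1
        if it > 1000000:
            return 1
        if t + h > t_total:
            h = t_total - t

        _dstep(y, p, k1, nvar, matrix_mode)
        for i in range(nvar):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _dstep(ytmp, p, k2, nvar, matrix_mode)
        for i in range(nvar):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _dstep(ytmp, p, k3, nvar, matrix_mode)
        for i in range(nvar):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _dstep(ytmp, p, k4, nvar, matrix_mode)
        for i in range(nvar):
            ytmp[i] = y[i] + h * ((-11.0 / 54.0) * k1[i] + 2.5 * k2[i]
                                  + (-70.0 / 27.0) * k3[i] + (35.0 / 27.0) * k4[i])
        _dstep(ytmp, p, k5, nvar, matrix_mode)
        for i in range(nvar):
            ytmp[i] = y[i] + h * ((1631.0 / 55296.0) * k1[i]
                                  + (175.0 / 512.0) * k2[i]
                                  + (575.0 / 13824.0) * k3[i]
                                  + (44275.0 / 110592.0) * k4[i]
                                  + (253.0 / 4096.0) * k5[i])
        _dstep(ytmp, p, k6, nvar, matrix_mode)

        err = 0.0
        for i in range(nvar):
            y5[i] = y[i] + h * ((37.0 / 378.0) * k1[i]
                                + (250.0 / 621.0) * k3[i]
                                + (125.0 / 594.0) * k4[i]
                                + (512.0 / 1771.0) * k6[i])
            y4[i] = y[i] + h * ((2825.0 / 27648.0) * k1[i]
                                + (18575.0 / 48384.0) * k3[i]
                                + (13525.0 / 55296.0) * k4[i]
                                + (277.0 / 14336.0) * k5[i]
                                + 0.25 * k6[i])
            sc = atol + rtol * (abs(y[i]) if abs(y[i]) > abs(y5[i]) else abs(y5[i]))
            e = abs(y5[i] - y4[i]) / sc
            if e > err:
                err = e
        if err <= 1.0:
            t += h
            for i in range(nvar):
                y[i] = y5[i]
            fac = 5.0
            if err > 0.0:
                fac = _SAFETY * err ** (-0.2)
                if fac > 5.0:
                    fac = 5.0
            h *= fac
        else:
            fac = _SAFETY * err ** (-0.25)
            if fac < 0.1:
                fac = 0.1
            h *= fac
            if h < hmin:
                return 1
    return 0


@njit(cache=True)
def _dstep(y, p, dy, nvar, matrix_mode):
    la0, la1, mu0, mu1, q01, q10 = p[0], p[1], p[2], p[3], p[4], p[5]
    E0 = y[0]
    E1 = y[1]
    dy[0] = mu0 - (la0 + mu0 + q01) * E0 + q01 * E1 + la0 * E0 * E0
    dy[1] = mu1 - (la1 + mu1 + q10) * E1 + q10 * E0 + la1 * E1 * E1
    a00 = -(la0 + mu0 + q01) + 2.0 * la0 * E0
    a11 = -(la1 + mu1 + q10) + 2.0 * la1 * E1
    if matrix_mode == 0:
        dy[2] = a00 * y[2] + q01 * y[3]
        dy[3] = q10 * y[2] + a11 * y[3]
    else:
        # columns of the propagator: y[2:4] first column, y[4:6] second
        dy[2] = a00 * y[2] + q01 * y[3]
        dy[3] = q10 * y[2] + a11 * y[3]
        dy[4] = a00 * y[4] + q01 * y[5]
        dy[5] = q10 * y[4] + a11 * y[5]


@njit(cache=True)
def _loglik_core(children, order, elen, tip_state, n_tips, p,
                 f0, f1, root_mode, condition, rtol, atol):
    n_nodes = order.shape[0]
    Etop = np.zeros((n_nodes, 2))
    Dtop = np.zeros((n_nodes, 2))
    y = np.empty(4)
    logcomp = 0.0
    root = order[n_nodes - 1]
    rootE0 = 0.0
    rootE1 = 0.0
    rootD0 = 0.0
    rootD1 = 0.0
    for oi in range(n_nodes):
        n = order[oi]
        if children[n, 0] < 0:  # tip
            s = tip_state[n]
            y[0] = 1.0 - f0
            y[1] = 1.0 - f1
            if s == 0:
                y[2] = f0
                y[3] = 0.0
            elif s == 1:
                y[2] = 0.0
                y[3] = f1
            else:  # unknown state
                y[2] = f0
                y[3] = f1
        else:
            c1 = children[n, 0]
            c2 = children[n, 1]
            y[0] = 0.5 * (Etop[c1, 0] + Etop[c2, 0])
            y[1] = 0.5 * (Etop[c1, 1] + Etop[c2, 1])
            y[2] = Dtop[c1, 0] * Dtop[c2, 0] * p[0]
            y[3] = Dtop[c1, 1] * Dtop[c2, 1] * p[1]
            s = y[2] + y[3]
            if not (s > 0.0) or not np.isfinite(s):
                return -np.inf
            y[2] /= s
            y[3] /= s
            logcomp += np.log(s)
        if n == root:
            rootE0 = y[0]
            rootE1 = y[1]
            rootD0 = y[2]
            rootD1 = y[3]
            break
        ok = _rkck(y, p, elen[n], rtol, atol, 4, 0)
        if ok != 0:
            return -np.inf
        if y[2] < 0.0:
            y[2] = 0.0
        if y[3] < 0.0:
            y[3] = 0.0
        s = y[2] + y[3]
        if not (s > 0.0) or not np.isfinite(s):
            return -np.inf
        Etop[n, 0] = y[0]
        Etop[n, 1] = y[1]
        Dtop[n, 0] = y[2] / s
        Dtop[n, 1] = y[3] / s
        logcomp += np.log(s)

    if root_mode == 0:  # relative D ("obs", FitzJohn weighting)
        tot = rootD0 + rootD1
        w0 = rootD0 / tot
        w1 = rootD1 / tot
    elif root_mode == 1:
        w0 = 0.5
        w1 = 0.5
    else:
        qs = p[4] + p[5]
        if qs > 0.0:
            w0 = p[5] / qs
            w1 = p[4] / qs
        else:
            w0 = 0.5
            w1 = 0.5
    lik = w0 * rootD0 + w1 * rootD1
    if condition == 1:
        denom = (w0 * p[0] * (1.0 - rootE0) ** 2
                 + w1 * p[1] * (1.0 - rootE1) ** 2)
        if not (denom > 0.0):
            return -np.inf
        lik /= denom
    if not (lik > 0.0) or not np.isfinite(lik):
        return -np.inf
    return np.log(lik) + logcomp


@njit(cache=True)
def _branch_propagator(E0, E1, length, p, rtol, atol):
    """Integrate E and the 2x2 D-propagator M along one branch.

    Returns (Etop0, Etop1, M) with D_top = M @ D_bottom.
    """
    y = np.empty(6)
    y[0] = E0
    y[1] = E1
    y[2] = 1.0
    y[3] = 0.0
    y[4] = 0.0
    y[5] = 1.0
    ok = _rkck(y, p, length, rtol, atol, 6, 1)
    M = np.empty((2, 2))
    M[0, 0] = y[2]
    M[1, 0] = y[3]
    M[0, 1] = y[4]
    M[1, 1] = y[5]
    return y[0], y[1], M, ok


# ---------------------------------------------------------------------
# public likelihood API

def tip_state_array(tree: Phylogeny, tip_states) -> np.ndarray:
    """Coerce tip states (mapping/Series/array) to an int8 array in tip order.

    Unknown states may be passed as -1.
    """
    if isinstance(tip_states, (dict, pd.Series)):
        arr = np.array([int(tip_states[lab]) for lab in tree.tip_labels],
                       dtype=np.int8)
    else:
        arr = np.asarray(tip_states, dtype=np.int8)
        if arr.shape[0] != tree.n_tips:
            raise ValueError("tip state vector length != number of tips")
    if not np.all(np.isin(arr, [-1, 0, 1])):
        raise ValueError("tip states must be 0, 1 or -1 (unknown)")
    return arr


def _prep_tree(tree: Phylogeny):
    if not tree.is_binary:
        raise ValueError("BiSSE requires a binary tree; call "
                         "tree.resolve_polytomies() first")
    children = np.full((tree.n_nodes, 2), -1, dtype=np.int64)
    for n, kids in enumerate(tree.children):
        for j, c in enumerate(kids):
            children[n, j] = c
    return children


def bisse_loglik(tree: Phylogeny, tip_states, params: BisseParams,
                 f: SamplingFractions | None = None, root_mode: str = "obs",
                 condition_on_survival: bool = False,
                 rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Log-likelihood of tip states and tree under BiSSE.

    ``root_mode``: "obs" weights root states by their relative D (the
    default of the standard reference implementation), "equal" uses 1/2,
    "stationary" the q-stationary frequencies. Returns ``-inf`` when the
    likelihood underflows to zero.
    """
    f = f or SamplingFractions(1.0, 1.0)
    if root_mode not in _ROOT_MODES:
        raise ValueError(f"unknown root_mode {root_mode!r}")
    children = _prep_tree(tree)
    states = np.full(tree.n_nodes, -1, dtype=np.int8)
    states[: tree.n_tips] = tip_state_array(tree, tip_states)
    p = params.as_array() if isinstance(params, BisseParams) else np.asarray(params, float)
    if np.any(p < 0):
        raise ValueError("negative BiSSE parameters")
    return float(_loglik_core(children, tree.postorder, tree.edge_length,
                              states, tree.n_tips, p, f.f0, f.f1,
                              _ROOT_MODES[root_mode],
                              1 if condition_on_survival else 0, rtol, atol))


# ---------------------------------------------------------------------
# model specifications and fitting

@dataclass(frozen=True)
class BisseModelSpec:
    """A parameter-sharing scheme over the six BiSSE rates."""

    name: str
    free_names: tuple
    # maps index into the full 6-vector -> index into the free vector
    share_map: tuple

    @property
    def k(self) -> int:
        return len(self.free_names)

    def expand(self, free: np.ndarray) -> np.ndarray:
        return np.asarray(free, float)[list(self.share_map)]

    def reduce(self, full: np.ndarray) -> np.ndarray:
        out = np.empty(self.k)
        for i6, ifree in enumerate(self.share_map):
            out[ifree] = full[i6]
        return out


MODEL_SPECS = {
    "full6": BisseModelSpec(
        "full6", ("lambda0", "lambda1", "mu0", "mu1", "q01", "q10"),
        (0, 1, 2, 3, 4, 5)),
    "eq_rates4": BisseModelSpec(
        "eq_rates4", ("lambda", "mu", "q01", "q10"), (0, 0, 1, 1, 2, 3)),
    "sdd_speciation4": BisseModelSpec(
        "sdd_speciation4", ("lambda0", "lambda1", "mu", "q"),
        (0, 1, 2, 2, 3, 3)),
    "null3": BisseModelSpec("null3", ("lambda", "mu", "q"),
                            (0, 0, 1, 1, 2, 2)),
}


@dataclass
class BisseFit:
    """A maximum-likelihood BiSSE fit scored by AICc."""

    spec: BisseModelSpec
    params: BisseParams
    free: dict
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    root_mode: str = "obs"
    condition_on_survival: bool = False

    @property
    def model(self) -> str:
        return self.spec.name


def _init_heuristic(tree: Phylogeny) -> tuple[float, float, float]:
    """Rate starting values from tree shape: a crown Kendall–Moran-style
    speciation estimate, half of it for extinction, slow transitions."""
    h = max(tree.height, 1e-8)
    la = max(math.log(max(tree.n_tips, 3) / 2.0) / h, 1e-4)
    return la, la / 2.0, 0.1 / h


def fit_bisse(tree: Phylogeny, tip_states, f: SamplingFractions | None = None,
              spec: BisseModelSpec | str = "full6", n_restarts: int = 3,
              seed: int = 0, root_mode: str = "obs",
              condition_on_survival: bool = False,
              bounds: tuple[float, float] = (1e-8, 1e3)) -> BisseFit:
    """Maximum-likelihood BiSSE fit under a parameter-sharing scheme.

    Optimization runs in log-parameter space (L-BFGS-B with numerical
    gradients) from a birth–death-informed start plus ``n_restarts``
    jittered restarts; the best optimum found is reported. A fit where no
    start converged is returned with ``converged=False`` and should be
    excluded from cross-tree averaging.
    """
    from scipy.optimize import minimize

    if isinstance(spec, str):
        spec = MODEL_SPECS[spec]
    f = f or SamplingFractions(1.0, 1.0)
    children = _prep_tree(tree)
    states = np.full(tree.n_nodes, -1, dtype=np.int8)
    states[: tree.n_tips] = tip_state_array(tree, tip_states)
    rm = _ROOT_MODES[root_mode]
    cond = 1 if condition_on_survival else 0
    lo, hi = math.log(bounds[0]), math.log(bounds[1])

    def negll(logfree):
        p = spec.expand(np.exp(logfree))
        ll = _loglik_core(children, tree.postorder, tree.edge_length, states,
                          tree.n_tips, p, f.f0, f.f1, rm, cond, 1e-8, 1e-10)
        return -ll if np.isfinite(ll) else 1e10

    la, mu, q = _init_heuristic(tree)
    base_full = np.array([la, la, mu, mu, q, q])
    base = np.log(np.clip(spec.reduce(base_full), bounds[0], bounds[1]))
    rng = np.random.Generator(np.random.Philox(seed))
    starts = [base]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(np.clip(base + rng.normal(0.0, 0.75, size=spec.k), lo, hi))

    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(negll, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * spec.k,
                       options={"maxiter": 500, "ftol": 1e-10})
        val = res.fun if np.isfinite(res.fun) else np.inf
        if best is None or val < best[0]:
            best = (val, res.x)
        any_ok = any_ok or (res.success and np.isfinite(res.fun) and res.fun < 1e9)

    val, x = best
    free = np.exp(x)
    full = spec.expand(free)
    loglik = -val if val < 1e9 else -np.inf
    n = tree.n_tips
    return BisseFit(spec=spec, params=BisseParams.from_array(full),
                    free=dict(zip(spec.free_names, free.tolist())),
                    loglik=float(loglik), k=spec.k, n=n,
                    aicc=_aicc(loglik, spec.k, n) if np.isfinite(loglik) else np.inf,
                    converged=bool(any_ok and np.isfinite(loglik)),
                    root_mode=root_mode,
                    condition_on_survival=condition_on_survival)


# ---------------------------------------------------------------------
# marginal ancestral states and branch painting

def marginal_asr(tree: Phylogeny, tip_states, params: BisseParams,
                 f: SamplingFractions | None = None, root_mode: str = "obs",
                 condition_on_survival: bool = False) -> np.ndarray:
    """Marginal ancestral state probabilities at every internal node.

    P(node in state i) is proportional to the whole-tree likelihood with
    that node's state clamped to ``i``. Computed in one post-order pass
    (storing the per-branch linear D-propagators) plus one pre-order pass,
    so a tree costs O(n) branch integrations rather than O(n²).

    Returns an (n_nodes, 2) array; tip rows are NaN.
    """
    f = f or SamplingFractions(1.0, 1.0)
    if root_mode not in _ROOT_MODES:
        raise ValueError(f"unknown root_mode {root_mode!r}")
    children = _prep_tree(tree)
    sarr = tip_state_array(tree, tip_states)
    p = params.as_array() if isinstance(params, BisseParams) else np.asarray(params, float)
    n_nodes = tree.n_nodes
    ntip = tree.n_tips
    lam = p[:2]
    db = np.zeros((n_nodes, 2))      # normalized D at node (bottom of its edge)
    M = [None] * n_nodes             # propagator along edge above node
    dtop = np.zeros((n_nodes, 2))
    etop = np.zeros((n_nodes, 2))
    root = tree.root
    rootE = np.zeros(2)
    for n in tree.postorder:
        if children[n, 0] < 0:
            s = sarr[n]
            e0, e1 = 1.0 - f.f0, 1.0 - f.f1
            if s == 0:
                d = np.array([f.f0, 0.0])
            elif s == 1:
                d = np.array([0.0, f.f1])
            else:
                d = np.array([f.f0, f.f1])
        else:
            c1, c2 = int(children[n, 0]), int(children[n, 1])
            e0 = 0.5 * (etop[c1, 0] + etop[c2, 0])
            e1 = 0.5 * (etop[c1, 1] + etop[c2, 1])
            d = lam * dtop[c1] * dtop[c2]
        ssum = d.sum()
        if not ssum > 0:
            raise FloatingPointError("likelihood underflow in ASR pass")
        db[n] = d / ssum
        if n == root:
            rootE[:] = (e0, e1)
            break
        E0t, E1t, Mn, ok = _branch_propagator(e0, e1, tree.edge_length[n],
                                              p, 1e-8, 1e-10)
        if ok != 0:
            raise FloatingPointError("branch integration failed in ASR pass")
        M[n] = Mn
        etop[n] = (E0t, E1t)
        dt = Mn @ db[n]
        dt = np.clip(dt, 0.0, None)
        st = dt.sum()
        if not st > 0:
            raise FloatingPointError("likelihood underflow in ASR pass")
        dtop[n] = dt / st

    # pre-order: K[n] maps D at node n to D at the root (up to scale)
    K = [None] * n_nodes
    K[root] = np.eye(2)
    for n in tree.postorder[::-1]:
        if children[n, 0] < 0:
            continue
        c1, c2 = int(children[n, 0]), int(children[n, 1])
        for c, sib in ((c1, c2), (c2, c1)):
            Kc = K[n] @ np.diag(lam * dtop[sib]) @ M[c]
            m = np.abs(Kc).max()
            K[c] = Kc / m if m > 0 else Kc

    rm = _ROOT_MODES[root_mode]
    if rm == 2:
        qs = p[4] + p[5]
        w_fix = np.array([p[5], p[4]]) / qs if qs > 0 else np.array([0.5, 0.5])

    def clamped_lik(r):
        tot = r.sum()
        if not tot > 0:
            return 0.0
        if rm == 0:
            w = r / tot
        elif rm == 1:
            w = np.array([0.5, 0.5])
        else:
            w = w_fix
        lik = float(w @ r)
        if condition_on_survival:
            denom = float(w @ (lam * (1.0 - rootE) ** 2))
            if denom <= 0:
                return 0.0
            lik /= denom
        return lik

    out = np.full((n_nodes, 2), np.nan)
    for n in range(ntip, n_nodes):
        L = np.array([clamped_lik(K[n][:, i] * db[n, i]) for i in (0, 1)])
        tot = L.sum()
        out[n] = L / tot if tot > 0 else np.array([0.5, 0.5])
    return out


def paint_branches(tree: Phylogeny, marginals: np.ndarray, tip_states,
                   tie_tol: float = 1e-12) -> PaintedTree:
    """Assign each edge the state of its child node.

    Internal nodes take the argmax marginal; exact ties take the parent's
    assignment (root ties state 0). Pendant edges take the observed tip
    state.
    """
    sarr = tip_state_array(tree, tip_states)
    if np.any(sarr < 0):
        raise ValueError("painting requires known tip states")
    assign = np.full(tree.n_nodes, -1, dtype=np.int8)
    ties = []
    for n in tree.postorder[::-1]:  # preorder: parents before children
        if n < tree.n_tips:
            assign[n] = sarr[n]
            continue
        p0, p1 = marginals[n]
        if abs(p0 - p1) <= tie_tol:
            par = tree.parent[n]
            assign[n] = assign[par] if par >= 0 else 0
            ties.append(int(n))
        else:
            assign[n] = 0 if p0 > p1 else 1
    return PaintedTree(tree=tree, edge_state=assign, tie_nodes=ties)
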