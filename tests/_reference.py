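"""Independent reference implementations used as oracles by the tests.

These deliberately share no code with the package's likelihood paths:
the BiSSE reference integrates the branch ODEs with scipy's LSODA (or a
fixed-grid classical RK4), walks trees as plain dicts, and supports
clamping a node's state for marginal-probability checks.
"""

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp


def _rhs(p):
    la0, la1, mu0, mu1, q01, q10 = p

    def rhs(t, y):
        E0, E1, D0, D1 = y
        return [
            mu0 - (la0 + mu0 + q01) * E0 + q01 * E1 + la0 * E0 * E0,
            mu1 - (la1 + mu1 + q10) * E1 + q10 * E0 + la1 * E1 * E1,
            -(la0 + mu0 + q01) * D0 + q01 * D1 + 2 * la0 * E0 * D0,
            -(la1 + mu1 + q10) * D1 + q10 * D0 + 2 * la1 * E1 * D1,
        ]

    return rhs


def _integrate_branch(y, length, p, method):
    if length <= 0:
        return list(y)
    if method == "lsoda":
        sol = solve_ivp(_rhs(p), [0.0, length], y, rtol=1e-10, atol=1e-12,
                        method="LSODA")
        return list(sol.y[:, -1])
    # fixed-grid classical RK4
    h = 1e-4
    nstep = max(int(np.ceil(length / h)), 1)
    h = length / nstep
    rhs = _rhs(p)
    y = np.asarray(y, dtype=float)
    for _ in range(nstep):
        k1 = np.asarray(rhs(0.0, y))
        k2 = np.asarray(rhs(0.0, y + 0.5 * h * k1))
        k3 = np.asarray(rhs(0.0, y + 0.5 * h * k2))
        k4 = np.asarray(rhs(0.0, y + h * k3))
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return list(y)


def ref_bisse_loglik(tree, tip_states, p, f0=1.0, f1=1.0, root_mode="obs",
                     condition=False, clamp=None, method="lsoda"):
    """Postorder BiSSE log-likelihood via scipy integration.

    ``clamp=(node, state)`` zeroes the other state's D at that node, giving
    the clamped likelihoods whose ratio defines marginal ancestral states.
    """
    la0, la1 = p[0], p[1]
    s = pd.Series(tip_states)
    vals = {}
    logc = 0.0
    for n in tree.postorder:
        if len(tree.children[n]) == 0:
            st = s[tree.tip_labels[n]]
            y = [1 - f0, 1 - f1, f0 if st == 0 else 0.0, f1 if st == 1 else 0.0]
        else:
            c1, c2 = tree.children[n]
            y1, y2 = vals[c1], vals[c2]
            y = [0.5 * (y1[0] + y2[0]), 0.5 * (y1[1] + y2[1]),
                 y1[2] * y2[2] * la0, y1[3] * y2[3] * la1]
            sm = y[2] + y[3]
            if sm <= 0:
                return -np.inf
            y = [y[0], y[1], y[2] / sm, y[3] / sm]
            logc += np.log(sm)
        if clamp is not None and n == clamp[0]:
            y = list(y)
            y[2 + (1 - clamp[1])] = 0.0
            sm = y[2] + y[3]
            if sm <= 0:
                return -np.inf
            y = [y[0], y[1], y[2] / sm, y[3] / sm]
            logc += np.log(sm)
        if n == tree.root:
            E0, E1, D0, D1 = y
            break
        y = _integrate_branch(y, tree.edge_length[n], p, method)
        sm = y[2] + y[3]
        if sm <= 0:
            return -np.inf
        y = [y[0], y[1], y[2] / sm, y[3] / sm]
        logc += np.log(sm)
        vals[n] = y

    if root_mode == "obs":
        w0, w1 = D0 / (D0 + D1), D1 / (D0 + D1)
    elif root_mode == "equal":
        w0 = w1 = 0.5
    elif root_mode == "stationary":
        qs = p[4] + p[5]
        w0, w1 = (p[5] / qs, p[4] / qs) if qs > 0 else (0.5, 0.5)
    else:
        raise ValueError(root_mode)
    lik = w0 * D0 + w1 * D1
    if condition:
        lik /= w0 * la0 * (1 - E0) ** 2 + w1 * la1 * (1 - E1) ** 2
    if lik <= 0:
        return -np.inf
    return np.log(lik) + logc


def ref_vcv_pathwalk(tree):
    """Tip covariance by walking every tip pair's root paths."""
    n = tree.n_tips
    paths = []
    for t in range(n):
        path = {}
        a = t
        while a >= 0:
            path[a] = tree.edge_length[a]
            a = int(tree.parent[a])
        paths.append(path)
    depth = tree.node_depths()
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = set(paths[i]) & set(paths[j])
            # shared path from root to the MRCA: sum of edges above the
            # shallowest common ancestors' chain
            mrca = max(shared, key=lambda a: depth[a])
            C[i, j] = depth[mrca]
    return C
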