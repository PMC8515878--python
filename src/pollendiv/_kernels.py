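"""Numba kernels for the SSE pruning likelihood.

The coupled per-lineage ODEs, integrated tip-to-root along every branch
(states indexed over the combined observed x hidden space):

    dD_i/dt = -(lambda_i + mu_i) D_i + sum_j Qd_ij D_j + 2 lambda_i E_i D_i
    dE_i/dt = mu_i - (lambda_i + mu_i) E_i + sum_j Qd_ij E_j + lambda_i E_i^2

with ``Qd`` the transition-rate matrix including its negative diagonal.
Integration is classical RK4 with the substep bounded by ``h_max``; the
caller chooses ``h_max`` as a small multiple of the inverse of the fastest
total rate, which keeps the accumulated per-path error well below 1e-8
(verified against an adaptive reference integrator in the test suite).
D is log-rescaled at nodes (and on underflowing branches) to avoid underflow
on large trees.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _rhs(D, E, lam, mu, Qd, dD, dE):
    k = lam.shape[0]
    for i in range(k):
        sd = 0.0
        se = 0.0
        for j in range(k):
            sd += Qd[i, j] * D[j]
            se += Qd[i, j] * E[j]
        tot = lam[i] + mu[i]
        dD[i] = sd - tot * D[i] + 2.0 * lam[i] * E[i] * D[i]
        dE[i] = mu[i] + se - tot * E[i] + lam[i] * E[i] * E[i]


MAX_SUBSTEPS_PER_EDGE = 100_000  # safety net against pathological rate regions


@njit(cache=True, fastmath=True)
def _integrate_edge_k2(D, E, lam0, lam1, mu0, mu1, q01, q10, t, h_max):
    """Scalar-specialised 2-state RK4 (the BiSSE hot path)."""
    n_sub = int(np.ceil(t / h_max))
    if n_sub < 1:
        n_sub = 1
    elif n_sub > MAX_SUBSTEPS_PER_EDGE:
        n_sub = MAX_SUBSTEPS_PER_EDGE
    h = t / n_sub
    d0, d1 = D[0], D[1]
    e0, e1 = E[0], E[1]
    t0 = lam0 + mu0 + q01
    t1 = lam1 + mu1 + q10
    log_scale = 0.0
    for _ in range(n_sub):
        ad0 = -t0 * d0 + q01 * d1 + 2.0 * lam0 * e0 * d0
        ad1 = -t1 * d1 + q10 * d0 + 2.0 * lam1 * e1 * d1
        ae0 = mu0 - t0 * e0 + q01 * e1 + lam0 * e0 * e0
        ae1 = mu1 - t1 * e1 + q10 * e0 + lam1 * e1 * e1
        xd0 = d0 + 0.5 * h * ad0
        xd1 = d1 + 0.5 * h * ad1
        xe0 = e0 + 0.5 * h * ae0
        xe1 = e1 + 0.5 * h * ae1
        bd0 = -t0 * xd0 + q01 * xd1 + 2.0 * lam0 * xe0 * xd0
        bd1 = -t1 * xd1 + q10 * xd0 + 2.0 * lam1 * xe1 * xd1
        be0 = mu0 - t0 * xe0 + q01 * xe1 + lam0 * xe0 * xe0
        be1 = mu1 - t1 * xe1 + q10 * xe0 + lam1 * xe1 * xe1
        xd0 = d0 + 0.5 * h * bd0
        xd1 = d1 + 0.5 * h * bd1
        xe0 = e0 + 0.5 * h * be0
        xe1 = e1 + 0.5 * h * be1
        cd0 = -t0 * xd0 + q01 * xd1 + 2.0 * lam0 * xe0 * xd0
        cd1 = -t1 * xd1 + q10 * xd0 + 2.0 * lam1 * xe1 * xd1
        ce0 = mu0 - t0 * xe0 + q01 * xe1 + lam0 * xe0 * xe0
        ce1 = mu1 - t1 * xe1 + q10 * xe0 + lam1 * xe1 * xe1
        xd0 = d0 + h * cd0
        xd1 = d1 + h * cd1
        xe0 = e0 + h * ce0
        xe1 = e1 + h * ce1
        dd0 = -t0 * xd0 + q01 * xd1 + 2.0 * lam0 * xe0 * xd0
        dd1 = -t1 * xd1 + q10 * xd0 + 2.0 * lam1 * xe1 * xd1
        de0 = mu0 - t0 * xe0 + q01 * xe1 + lam0 * xe0 * xe0
        de1 = mu1 - t1 * xe1 + q10 * xe0 + lam1 * xe1 * xe1
        h6 = h / 6.0
        d0 += h6 * (ad0 + 2.0 * bd0 + 2.0 * cd0 + dd0)
        d1 += h6 * (ad1 + 2.0 * bd1 + 2.0 * cd1 + dd1)
        e0 += h6 * (ae0 + 2.0 * be0 + 2.0 * ce0 + de0)
        e1 += h6 * (ae1 + 2.0 * be1 + 2.0 * ce1 + de1)
        m = d0 if d0 > d1 else d1
        if 0.0 < m < 1e-150:
            d0 /= m
            d1 /= m
            log_scale += np.log(m)
    if e0 < 0.0:
        e0 = 0.0
    elif e0 > 1.0:
        e0 = 1.0
    if e1 < 0.0:
        e1 = 0.0
    elif e1 > 1.0:
        e1 = 1.0
    D[0], D[1] = d0, d1
    E[0], E[1] = e0, e1
    return log_scale


@njit(cache=True)
def integrate_edge(D, E, lam, mu, Qd, t, h_max):
    """RK4-integrate (D, E) in place over duration t; returns log rescale."""
    if t <= 0.0:
        return 0.0
    k = lam.shape[0]
    if k == 2:
        return _integrate_edge_k2(
            D, E, lam[0], lam[1], mu[0], mu[1], Qd[0, 1], Qd[1, 0], t, h_max
        )
    n_sub = int(np.ceil(t / h_max))
    if n_sub < 1:
        n_sub = 1
    elif n_sub > MAX_SUBSTEPS_PER_EDGE:
        n_sub = MAX_SUBSTEPS_PER_EDGE
    h = t / n_sub
    k1D = np.empty(k)
    k1E = np.empty(k)
    k2D = np.empty(k)
    k2E = np.empty(k)
    k3D = np.empty(k)
    k3E = np.empty(k)
    k4D = np.empty(k)
    k4E = np.empty(k)
    tD = np.empty(k)
    tE = np.empty(k)
    log_scale = 0.0
    for _ in range(n_sub):
        _rhs(D, E, lam, mu, Qd, k1D, k1E)
        for i in range(k):
            tD[i] = D[i] + 0.5 * h * k1D[i]
            tE[i] = E[i] + 0.5 * h * k1E[i]
        _rhs(tD, tE, lam, mu, Qd, k2D, k2E)
        for i in range(k):
            tD[i] = D[i] + 0.5 * h * k2D[i]
            tE[i] = E[i] + 0.5 * h * k2E[i]
        _rhs(tD, tE, lam, mu, Qd, k3D, k3E)
        for i in range(k):
            tD[i] = D[i] + h * k3D[i]
            tE[i] = E[i] + h * k3E[i]
        _rhs(tD, tE, lam, mu, Qd, k4D, k4E)
        for i in range(k):
            D[i] += (h / 6.0) * (k1D[i] + 2.0 * k2D[i] + 2.0 * k3D[i] + k4D[i])
            E[i] += (h / 6.0) * (k1E[i] + 2.0 * k2E[i] + 2.0 * k3E[i] + k4E[i])
        m = 0.0
        for i in range(k):
            if D[i] > m:
                m = D[i]
        if 0.0 < m < 1e-150:
            for i in range(k):
                D[i] /= m
            log_scale += np.log(m)
    for i in range(k):
        if E[i] < 0.0:
            E[i] = 0.0
        elif E[i] > 1.0:
            E[i] = 1.0
    return log_scale


@njit(cache=True)
def tree_loglik(
    postorder, left, right, blen, tipD, tipE, lam, mu, Qd,
    h_max, condition_on_survival, root_mode,
):
    """Post-order SSE pruning over the whole tree.

    root_mode: 0 = equal root weights, 1 = weights proportional to root D.
    Returns the log-likelihood; -inf for impossible data; NaN on a
    conditioning degeneracy (zero lambda (1-E)^2 with positive D).
    """
    n_nodes = blen.shape[0]
    n_tips = tipD.shape[0]
    k = lam.shape[0]
    D = np.zeros((n_nodes, k))
    E = np.zeros((n_nodes, k))
    for i in range(n_tips):
        for j in range(k):
            D[i, j] = tipD[i, j]
            E[i, j] = tipE[i, j]
    acc = 0.0
    for idx in range(postorder.shape[0]):
        node = postorder[idx]
        l = left[node]
        r = right[node]
        acc += integrate_edge(D[l], E[l], lam, mu, Qd, blen[l], h_max)
        acc += integrate_edge(D[r], E[r], lam, mu, Qd, blen[r], h_max)
        m = 0.0
        for j in range(k):
            D[node, j] = lam[j] * D[l, j] * D[r, j]
            E[node, j] = 0.5 * (E[l, j] + E[r, j])
            if D[node, j] > m:
                m = D[node, j]
        if m <= 0.0:
            return -np.inf
        for j in range(k):
            D[node, j] /= m
        acc += np.log(m)
    root = postorder[postorder.shape[0] - 1]
    sD = 0.0
    for j in range(k):
        sD += D[root, j]
    total = 0.0
    for j in range(k):
        if root_mode == 1:
            w = D[root, j] / sD
        else:
            w = 1.0 / k
        term = w * D[root, j]
        if term > 0.0 and condition_on_survival:
            one_minus_e = 1.0 - E[root, j]
            denom = lam[j] * one_minus_e * one_minus_e
            if denom <= 0.0:
                return np.nan
            term /= denom
        total += term
    if total <= 0.0:
        return -np.inf
    return np.log(total) + acc
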