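"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops directly from the
metric definitions, deliberately sharing no code with the package, so a
match on random instances is evidence of correctness rather than of
consistency with itself.
"""

from __future__ import annotations

import math

import numpy as np


# --- degrees ---------------------------------------------------------------

def bf_degrees(H, A1, A2, tissue, mrsn_of_roi, mrsn_pos, gm_order, wm_order):
    """Per-ROI (D1, D2, D3) by explicit neighbor counting.

    tissue/mrsn_of_roi are per-ROI (0-based lists); gm_order / wm_order map
    ROI position -> row/col position in A1/A2.
    """
    n = len(tissue)
    out = []
    for i in range(n):
        if tissue[i] == "GM":
            m = mrsn_pos[mrsn_of_roi[i]]
            d1 = sum(int(H[m][e]) for e in range(len(H[m])))
            gi = gm_order[i]
            d2 = sum(int(A1[gi][j]) for j in range(len(A1)) if j != gi)
            d3 = sum(int(A2[w][gi]) for w in range(len(A2)))
        else:
            wi = wm_order[i]
            d1 = d2 = 0
            d3 = sum(int(A2[wi][g]) for g in range(len(A2[wi])))
        out.append((d1, d2, d3))
    return out


def bf_max_degrees(tissue, mrsn_of_roi, mrsn_sizes, n_mrsn_gm, n_gm, n_wm):
    out = []
    for i in range(len(tissue)):
        if tissue[i] == "GM":
            out.append((n_mrsn_gm - 1, mrsn_sizes[mrsn_of_roi[i]] - 1, n_wm))
        else:
            out.append((0, 0, n_gm))
    return out


def bf_select_core(norm_deg, n_core):
    order = sorted(range(len(norm_deg)), key=lambda i: (-norm_deg[i], i))
    core = set(order[:n_core])
    return [1 if i in core else 0 for i in range(len(norm_deg))]


# --- temporal metrics ------------------------------------------------------

def bf_tc(R):
    n, T = len(R), len(R[0])
    return [sum(R[i]) / T for i in range(n)]


def bf_ts_literal(R):
    n, T = len(R), len(R[0])
    out = []
    for i in range(n):
        delta = sum(1 for t in range(T - 1) if R[i][t] == R[i][t + 1])
        out.append(1 - delta / (T - 1))
    return out


# --- shared-core matrix and functionalities --------------------------------

def bf_union_graph(H, A1, A2, tissue, mrsn_of_roi, mrsn_pos, gm_order, wm_order):
    """Symmetric ROI-level connectivity: A1 within MRSN, hyperedge
    co-membership (members + central) across MRSNs, A2 across tissue."""
    n = len(tissue)
    M = len(H)
    hyper_members = []
    for e in range(M):
        members = {j for j in range(M) if H[j][e]} | {e}
        hyper_members.append(members)
    U = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if tissue[i] == "GM" and tissue[j] == "GM":
                mi, mj = mrsn_pos[mrsn_of_roi[i]], mrsn_pos[mrsn_of_roi[j]]
                if mi == mj:
                    U[i][j] = bool(A1[gm_order[i]][gm_order[j]])
                else:
                    U[i][j] = any(
                        mi in mem and mj in mem for mem in hyper_members
                    )
            elif tissue[i] == "WM" and tissue[j] == "GM":
                U[i][j] = bool(A2[wm_order[i]][gm_order[j]])
            elif tissue[i] == "GM" and tissue[j] == "WM":
                U[i][j] = bool(A2[wm_order[j]][gm_order[i]])
            # WM-WM: never connected
    return U


def bf_shared_core(union_graphs, R, n_core):
    """P_ij by the exhaustive quadruple loop over (i, j, core c, layer t)."""
    T = len(union_graphs)
    n = len(R)
    P = [[0.0] * n for _ in range(n)]
    for t in range(T):
        U = union_graphs[t]
        cores = [c for c in range(n) if R[c][t] == 1]
        for i in range(n):
            if R[i][t] == 1:
                continue
            for j in range(n):
                if j == i or R[j][t] == 1:
                    continue
                beta = sum(1 for c in cores if U[i][c] and U[j][c])
                P[i][j] += beta
    for i in range(n):
        for j in range(n):
            P[i][j] /= T * n_core
        P[i][i] = 0.0
    return P


def bf_lf(P, mrsn_of_roi):
    n = len(P)
    out = []
    for i in range(n):
        peers = [j for j in range(n) if mrsn_of_roi[j] == mrsn_of_roi[i]]
        n_s = len(peers)
        out.append(sum(P[i][j] for j in peers if j != i) / n_s)
    return out


def bf_jf(P, mrsn_of_roi):
    n = len(P)
    out = []
    for i in range(n):
        others = [j for j in range(n) if mrsn_of_roi[j] != mrsn_of_roi[i]]
        out.append(sum(P[i][j] for j in others) / len(others))
    return out


# --- construction primitives ----------------------------------------------

def bf_threshold(values_matrix, symmetric):
    """mean + sample-SD threshold computed with plain Python arithmetic."""
    rows = len(values_matrix)
    cols = len(values_matrix[0])
    if symmetric:
        vals = [values_matrix[i][j] for i in range(rows) for j in range(i + 1, cols)]
    else:
        vals = [v for row in values_matrix for v in row]
    mean = sum(vals) / len(vals)
    if len(vals) > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    else:
        sd = 0.0
    theta = mean + sd
    out = [[1 if values_matrix[i][j] > theta else 0 for j in range(cols)]
           for i in range(rows)]
    if symmetric:
        for i in range(rows):
            out[i][i] = 0
    return out


def bf_lasso_qp(y, B, lam):
    """Lasso by an independent solver: split a = u - v (u, v >= 0) turns
    the L1 objective into a smooth bound-constrained problem solved with
    L-BFGS-B.  Objective: (1/2n)||y - B a||^2 + lam * sum(u + v)."""
    import numpy as np
    from scipy.optimize import minimize

    y = np.asarray(y, float)
    B = np.asarray(B, float)
    n, p = B.shape

    def obj(z):
        u, v = z[:p], z[p:]
        a = u - v
        r = y - B @ a
        g_a = -(B.T @ r) / n
        f = 0.5 * (r @ r) / n + lam * z.sum()
        grad = np.concatenate([g_a + lam, -g_a + lam])
        return f, grad

    res = minimize(
        obj, np.zeros(2 * p), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * 2 * p,
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
    )
    z = res.x
    return z[:p] - z[p:]


def bf_lasso_single(y, x, lam):
    """Closed-form single-predictor Lasso on standardized data.

    For the per-sample objective (1/2n)||y - a x||^2 + lam |a| with x
    standardized to unit population variance, the minimizer is the
    soft-thresholded sample covariance: a = sign(c) max(|c| - lam, 0)
    with c = <x, y> / n.
    """
    n = len(y)
    c = sum(xi * yi for xi, yi in zip(x, y)) / n
    return math.copysign(max(abs(c) - lam, 0.0), c)


# --- statistics ------------------------------------------------------------

def bf_icc_anova(x):
    """One-way random-effects ICC via explicit ANOVA sums of squares."""
    x = [list(row) for row in x]
    k = len(x)
    n = len(x[0])
    grand = sum(sum(row) for row in x) / (k * n)
    means = [sum(row) / n for row in x]
    ss_between = n * sum((m - grand) ** 2 for m in means)
    ss_within = sum((v - means[i]) ** 2 for i, row in enumerate(x) for v in row)
    msb = ss_between / (k - 1)
    msw = ss_within / (k * (n - 1))
    denom = msb + (n - 1) * msw
    if denom == 0:
        return float("nan")
    return (msb - msw) / denom


def bf_bh(pvals):
    """Benjamini-Hochberg step-up adjusted q-values, by enumeration."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
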