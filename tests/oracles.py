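"""Independent oracles for the DEA solver.

These deliberately avoid scipy's LP machinery: the envelopment programs are
solved by exhaustive enumeration of candidate vertices (every choice of
active constraints), which is exact for the tiny instances used in tests.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_lp_min(c, A_ub, b_ub, A_eq=None, b_eq=None, tol=1e-9):
    """Minimise c'z subject to A_ub z <= b_ub, A_eq z = b_eq, z >= 0, by
    enumerating all basic feasible points (intersections of d active
    constraints in R^d). Exact for small d; returns (optimum, argmin)."""
    c = np.asarray(c, dtype=float)
    d = c.size
    rows = []
    rhs = []
    always = []
    if A_eq is not None:
        A_eq = np.atleast_2d(A_eq)
        for r, b in zip(A_eq, np.atleast_1d(b_eq)):
            always.append(len(rows))
            rows.append(np.asarray(r, float))
            rhs.append(float(b))
    A_ub = np.atleast_2d(A_ub)
    ub_idx = []
    for r, b in zip(A_ub, np.atleast_1d(b_ub)):
        ub_idx.append(len(rows))
        rows.append(np.asarray(r, float))
        rhs.append(float(b))
    for j in range(d):  # z_j >= 0 as candidate active constraints
        e = np.zeros(d)
        e[j] = 1.0
        rows.append(e)
        rhs.append(0.0)
    rows = np.asarray(rows)
    rhs = np.asarray(rhs)

    candidates = [i for i in range(len(rows)) if i not in always]
    best, best_z = np.inf, None
    need = d - len(always)
    for combo in itertools.combinations(candidates, need):
        idx = list(always) + list(combo)
        A = rows[idx]
        if np.linalg.matrix_rank(A) < d:
            continue
        z, *_ = np.linalg.lstsq(A, rhs[idx], rcond=None)
        if np.max(np.abs(A @ z - rhs[idx])) > 1e-7:
            continue
        # feasibility of the full system
        if np.any(z < -tol):
            continue
        if np.any(rows[ub_idx] @ z > rhs[ub_idx] + tol):
            continue
        val = float(c @ z)
        if val < best:
            best, best_z = val, z
    return best, best_z


def oracle_theta(X, Y, index, rts="crs"):
    """Input-oriented radial score by vertex enumeration (exact, tiny n)."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    m, n = X.shape
    s = Y.shape[0]
    d = 1 + n  # variables (theta, lambda)
    c = np.zeros(d)
    c[0] = 1.0
    A_ub = np.zeros((m + s + (1 if rts == "nirs" else 0), d))
    b_ub = np.zeros(A_ub.shape[0])
    A_ub[:m, 0] = -X[:, index]
    A_ub[:m, 1:] = X
    A_ub[m : m + s, 1:] = -Y
    b_ub[m : m + s] = -Y[:, index]
    if rts == "nirs":
        A_ub[m + s, 1:] = 1.0
        b_ub[m + s] = 1.0
    A_eq = b_eq = None
    if rts == "vrs":
        A_eq = np.zeros((1, d))
        A_eq[0, 1:] = 1.0
        b_eq = np.array([1.0])
    val, _ = enumerate_lp_min(c, A_ub, b_ub, A_eq, b_eq)
    return val


def crs_ratio_score(x, y, index):
    """Closed form for one input and one output under constant returns."""
    ratios = np.asarray(y, float) / np.asarray(x, float)
    return ratios[index] / ratios.max()
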