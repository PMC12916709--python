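"""Input-oriented radial data envelopment analysis.

Solves the envelopment (primal) linear program for each decision-making unit
(DMU): minimise the radial input contraction theta subject to

    X lambda <= theta * x0,   Y lambda >= y0,   lambda >= 0,

with the intensity-weight constraint sum(lambda) = 1 under variable returns to
scale (VRS, the BCC model) or sum(lambda) <= 1 under non-increasing returns
(NIRS); no constraint gives constant returns (CRS, the CCR model). The
envelopment form is used because the intensity weights drive the
returns-to-scale diagnostics.

All programs are solved with HiGHS through :func:`scipy.optimize.linprog`.
Because a frontier run solves one small LP per DMU (and a bootstrap run solves
thousands), independent programs are assembled into a single block-diagonal
sparse LP and solved in one call; the blocks do not interact, so the joint
optimum equals the per-block optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .errors import SolverError

__all__ = [
    "DMUSet",
    "DEASolution",
    "EfficiencyRecord",
    "solve_efficiency",
    "maximize_slacks",
    "scale_efficiency",
    "classify_rts",
    "efficiency_table",
    "radial_scores",
    "radial_scores_multi",
    "EFFICIENT_TOL",
    "RTS_TOL",
]

RTS = Literal["crs", "vrs", "nirs"]

#: a DMU counts as efficient when theta >= 1 - EFFICIENT_TOL
EFFICIENT_TOL = 1e-6
#: tolerance on sum(lambda) for returns-to-scale classification
RTS_TOL = 1e-6
#: validation gate for score comparisons (solver is asked for ~1e-9)
SCORE_TOL = 1e-7


@dataclass
class DMUSet:
    """An m x n input matrix, s x n output matrix and n DMU labels."""

    inputs: np.ndarray
    outputs: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        self.outputs = np.atleast_2d(np.asarray(self.outputs, dtype=float))
        m, n = self.inputs.shape
        s, n2 = self.outputs.shape
        if n != n2 or len(self.labels) != n:
            raise ValueError("inconsistent DMU-set dimensions")
        if np.any(self.inputs < 0) or np.any(self.outputs < 0):
            raise ValueError("inputs and outputs must be non-negative")
        if np.any((self.inputs <= 0).all(axis=0)):
            raise ValueError("a DMU has an all-zero input column")
        if np.any((self.outputs <= 0).all(axis=0)):
            raise ValueError("a DMU has no positive output")

    @property
    def m(self) -> int:
        return self.inputs.shape[0]

    @property
    def s(self) -> int:
        return self.outputs.shape[0]

    @property
    def n(self) -> int:
        return self.inputs.shape[1]


@dataclass
class DEASolution:
    """Optimal radial score and diagnostics for one DMU."""

    label: str
    theta: float
    lambdas: np.ndarray
    input_slacks: np.ndarray
    output_slacks: np.ndarray
    rts_assumption: str
    lambda_sum: float
    solver_status: str = "optimal"


@dataclass
class EfficiencyRecord:
    """CCR + BCC scores, scale efficiency and RTS label for one DMU."""

    label: str
    te_ccr: float
    pte_bcc: float
    se: float
    rts_label: str
    lambda_sum_crs: float = field(default=np.nan)


# ---------------------------------------------------------------------------
# Batched envelopment solver

def _block_matrices(Xe, Ye, Xr, Yr, rts: str):
    """Per-evaluated-DMU LP blocks for a common reference set.

    Variables per block: (theta, lambda_1..lambda_nr).
    """
    m, ne = Xe.shape
    s = Ye.shape[0]
    nr = Xr.shape[1]
    cols = 1 + nr
    ub_rows = m + s + (1 if rts == "nirs" else 0)

    base = np.zeros((ub_rows, cols))
    base[:m, 1:] = Xr
    base[m : m + s, 1:] = -Yr
    if rts == "nirs":
        base[m + s, 1:] = 1.0

    data, rowi, coli, b_ub = [], [], [], np.empty(ne * ub_rows)
    for i in range(ne):
        base[:m, 0] = -Xe[:, i]
        blk = sparse.coo_matrix(base)
        data.append(blk.data.copy())
        rowi.append(blk.row + i * ub_rows)
        coli.append(blk.col + i * cols)
        b_ub[i * ub_rows : i * ub_rows + m] = 0.0
        b_ub[i * ub_rows + m : i * ub_rows + m + s] = -Ye[:, i]
        if rts == "nirs":
            b_ub[i * ub_rows + m + s] = 1.0
    A_ub = sparse.csc_matrix(
        (np.concatenate(data), (np.concatenate(rowi), np.concatenate(coli))),
        shape=(ne * ub_rows, ne * cols),
    )

    A_eq = b_eq = None
    if rts == "vrs":
        eq_cols = np.concatenate(
            [np.arange(1, cols) + i * cols for i in range(ne)]
        )
        eq_rows = np.repeat(np.arange(ne), nr)
        A_eq = sparse.csc_matrix(
            (np.ones(ne * nr), (eq_rows, eq_cols)), shape=(ne, ne * cols)
        )
        b_eq = np.ones(ne)
    return A_ub, b_ub, A_eq, b_eq, cols


def radial_scores(
    X_eval: np.ndarray,
    Y_eval: np.ndarray,
    X_ref: np.ndarray,
    Y_ref: np.ndarray,
    rts: RTS = "crs",
    return_lambdas: bool = False,
):
    """Radial input-efficiency of each evaluated DMU against a reference set.

    Returns ``(theta, status)`` or ``(theta, lambdas, status)``; infeasible or
    failed blocks get ``theta = nan`` and a non-'optimal' status, never a
    silent default.
    """
    X_eval = np.atleast_2d(np.asarray(X_eval, float))
    Y_eval = np.atleast_2d(np.asarray(Y_eval, float))
    X_ref = np.atleast_2d(np.asarray(X_ref, float))
    Y_ref = np.atleast_2d(np.asarray(Y_ref, float))
    ne = X_eval.shape[1]
    A_ub, b_ub, A_eq, b_eq, cols = _block_matrices(X_eval, Y_eval, X_ref, Y_ref, rts)
    c = np.zeros(ne * cols)
    c[::cols] = 1.0
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
        bounds=(0, None), method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    if res.status == 0:
        theta = res.x[::cols].copy()
        lambdas = res.x.reshape(ne, cols)[:, 1:].copy()
        statuses = ["optimal"] * ne
    elif res.status == 2 and ne > 1:
        # at least one block infeasible: fall back to per-block solves so the
        # feasible blocks still get scores
        theta = np.empty(ne)
        lambdas = np.empty((ne, cols - 1))
        statuses = []
        for i in range(ne):
            t, lam, st = _solve_single(X_eval[:, [i]], Y_eval[:, [i]], X_ref, Y_ref, rts)
            theta[i], lambdas[i] = t, lam
            statuses.append(st)
    else:
        status = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
        theta = np.full(ne, np.nan)
        lambdas = np.full((ne, cols - 1), np.nan)
        statuses = [status] * ne
    if return_lambdas:
        return theta, lambdas, statuses
    return theta, statuses


def _solve_single(Xe, Ye, Xr, Yr, rts):
    A_ub, b_ub, A_eq, b_eq, cols = _block_matrices(Xe, Ye, Xr, Yr, rts)
    c = np.zeros(cols)
    c[0] = 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if res.status == 0:
        return res.x[0], res.x[1:], "optimal"
    status = {2: "infeasible", 3: "unbounded"}.get(res.status, "failed")
    return np.nan, np.full(cols - 1, np.nan), status


def radial_scores_multi(
    X_eval: np.ndarray,
    Y_eval: np.ndarray,
    refs: Sequence[tuple[np.ndarray, np.ndarray]],
    rts: RTS = "crs",
) -> tuple[np.ndarray, np.ndarray]:
    """Score the same evaluated DMUs against several reference sets at once.

    Used by the bootstrap: each replicate supplies its own pseudo reference
    set. All ``len(refs) * ne`` programs go into one block-diagonal LP.
    Returns ``(theta, ok)`` of shape (R, ne); failed replicates are nan.
    """
    ne = X_eval.shape[1]
    R = len(refs)
    subs = [_block_matrices(X_eval, Y_eval, Xr, Yr, rts) for Xr, Yr in refs]
    cols = subs[0][4]
    A_ub = sparse.block_diag([s[0] for s in subs], format="csc")
    b_ub = np.concatenate([s[1] for s in subs])
    if rts == "vrs":
        A_eq = sparse.block_diag([s[2] for s in subs], format="csc")
        b_eq = np.concatenate([s[3] for s in subs])
    else:
        A_eq = b_eq = None
    c = np.zeros(R * ne * cols)
    c[::cols] = 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if res.status == 0:
        theta = res.x[::cols].reshape(R, ne).copy()
        ok = np.ones((R, ne), dtype=bool)
        return theta, ok
    # joint failure: resolve per replicate
    theta = np.empty((R, ne))
    ok = np.ones((R, ne), dtype=bool)
    for r, (Xr, Yr) in enumerate(refs):
        t, statuses = radial_scores(X_eval, Y_eval, Xr, Yr, rts)
        theta[r] = t
        ok[r] = [st == "optimal" for st in statuses]
    return theta, ok


# ---------------------------------------------------------------------------
# Public per-DMU operations

def solve_efficiency(dmus: DMUSet, index: int, rts: RTS = "crs") -> DEASolution:
    """Two-phase envelopment solution for one DMU of the set.

    Phase 1 minimises the radial contraction theta; phase 2 maximises the
    slack sum at fixed theta. The DMU is in its own reference set, so the
    program is always feasible; a solver failure is reported, never defaulted.
    """
    if not 0 <= index < dmus.n:
        raise IndexError(index)
    theta, lambdas, statuses = radial_scores(
        dmus.inputs[:, [index]], dmus.outputs[:, [index]],
        dmus.inputs, dmus.outputs, rts, return_lambdas=True,
    )
    if statuses[0] != "optimal":
        raise SolverError(f"phase-1 LP {statuses[0]} for DMU {dmus.labels[index]}")
    t = float(theta[0])
    s_in, s_out, lam2 = _phase2(dmus, index, t, rts)
    return DEASolution(
        label=dmus.labels[index],
        theta=t,
        lambdas=lam2,
        input_slacks=s_in,
        output_slacks=s_out,
        rts_assumption=rts,
        lambda_sum=float(lam2.sum()),
    )


def _phase2(dmus: DMUSet, index: int, theta: float, rts: str):
    """Maximise total slack at fixed radial score (standard second phase)."""
    m, s, n = dmus.m, dmus.s, dmus.n
    X, Y = dmus.inputs, dmus.outputs
    x0, y0 = X[:, index], Y[:, index]
    # variables: lambda (n), s_in (m), s_out (s)
    nv = n + m + s
    c = np.zeros(nv)
    c[n:] = -1.0  # maximise slack sum
    A_eq = np.zeros((m + s, nv))
    A_eq[:m, :n] = X
    A_eq[:m, n : n + m] = np.eye(m)
    A_eq[m:, :n] = Y
    A_eq[m:, n + m :] = -np.eye(s)
    # tiny relaxation keeps the phase-1 optimum feasible numerically
    b_eq = np.concatenate([theta * x0 * (1 + 1e-9) + 1e-12, y0])
    A_ub = b_ub = None
    if rts == "nirs":
        A_ub = np.zeros((1, nv))
        A_ub[0, :n] = 1.0
        b_ub = [1.0]
    eq_extra = None
    if rts == "vrs":
        row = np.zeros((1, nv))
        row[0, :n] = 1.0
        A_eq = np.vstack([A_eq, row])
        b_eq = np.concatenate([b_eq, [1.0]])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=(0, None), method="highs")
    if res.status != 0:
        raise SolverError(
            f"phase-2 LP failed (status {res.status}) for DMU {dmus.labels[index]}; "
            "is theta the optimal radial score?"
        )
    lam = res.x[:n]
    s_in = np.maximum(res.x[n : n + m], 0.0)
    s_out = np.maximum(res.x[n + m :], 0.0)
    return s_in, s_out, lam


def maximize_slacks(dmus: DMUSet, index: int, theta: float, rts: RTS = "crs"):
    """Phase-2 slacks for a given optimal radial score."""
    s_in, s_out, _ = _phase2(dmus, index, theta, rts)
    return s_in, s_out


def scale_efficiency(te_crs: float, pte_vrs: float) -> float:
    """SE = TE(CRS) / PTE(VRS)."""
    if pte_vrs <= 0:
        raise ValueError("VRS score must be positive")
    return te_crs / pte_vrs


def _lambda_sum_range(dmus: DMUSet, index: int, theta: float) -> tuple[float, float]:
    """Min and max of sum(lambda) over alternate CRS optima at fixed theta."""
    m, s, n = dmus.m, dmus.s, dmus.n
    X, Y = dmus.inputs, dmus.outputs
    A_ub = np.vstack([X, -Y])
    b_ub = np.concatenate(
        [theta * X[:, index] * (1 + 1e-9) + 1e-12, -Y[:, index]]
    )
    out = []
    for sign in (1.0, -1.0):
        res = linprog(sign * np.ones(n), A_ub=A_ub, b_ub=b_ub,
                      bounds=(0, None), method="highs")
        if res.status != 0:
            raise SolverError(f"lambda-range LP failed for DMU {dmus.labels[index]}")
        out.append(sign * res.fun)
    return out[0], out[1]


def classify_rts(dmus: DMUSet, index: int, tol: float = RTS_TOL) -> str:
    """Returns-to-scale label (crs / drs / irs) for one DMU.

    Primary rule: the interval of sum(lambda) over alternate CRS optima —
    entirely above 1 means decreasing returns, entirely below 1 increasing,
    otherwise constant. Cross-checked against the CRS/NIRS/VRS score ordering;
    a determinate conflict is flagged 'indeterminate' rather than guessed.
    """
    x0 = dmus.inputs[:, [index]]
    y0 = dmus.outputs[:, [index]]
    th = {}
    for r in ("crs", "nirs", "vrs"):
        t, st = radial_scores(x0, y0, dmus.inputs, dmus.outputs, r)
        if st[0] != "optimal":
            raise SolverError(f"{r} LP {st[0]} for DMU {dmus.labels[index]}")
        th[r] = float(t[0])
    lmin, lmax = _lambda_sum_range(dmus, index, th["crs"])
    if lmin > 1 + tol:
        primary = "drs"
    elif lmax < 1 - tol:
        primary = "irs"
    else:
        primary = "crs"
    # score-comparison diagnostic (only informative when VRS > CRS)
    stol = 1e-7
    if th["vrs"] - th["crs"] <= stol:
        secondary = "crs"
    elif abs(th["nirs"] - th["crs"]) <= stol:
        secondary = "irs"
    elif abs(th["nirs"] - th["vrs"]) <= stol:
        secondary = "drs"
    else:
        secondary = None  # numerically ambiguous; rely on the interval rule
    if secondary is not None and secondary != primary:
        # CRS-frontier DMUs can be reached with sum(lambda)=1, where both
        # diagnostics agree; a genuine disagreement is flagged.
        if not (primary == "crs" and th["vrs"] - th["crs"] <= stol):
            return "indeterminate"
    return primary


def efficiency_table(dmus: DMUSet, classify: bool = True) -> list[EfficiencyRecord]:
    """CCR and BCC scores, scale efficiency and RTS label for every DMU."""
    te, lam_crs, st_c = radial_scores(
        dmus.inputs, dmus.outputs, dmus.inputs, dmus.outputs, "crs",
        return_lambdas=True,
    )
    pte, st_v = radial_scores(
        dmus.inputs, dmus.outputs, dmus.inputs, dmus.outputs, "vrs"
    )
    bad = [lab for lab, a, b in zip(dmus.labels, st_c, st_v)
           if a != "optimal" or b != "optimal"]
    if bad:
        raise SolverError(f"LP failure for DMUs {bad}")
    records = []
    for i, lab in enumerate(dmus.labels):
        rts_label = classify_rts(dmus, i) if classify else ""
        records.append(
            EfficiencyRecord(
                label=lab,
                te_ccr=float(te[i]),
                pte_bcc=float(pte[i]),
                se=scale_efficiency(float(te[i]), float(pte[i])),
                rts_label=rts_label,
                lambda_sum_crs=float(lam_crs[i].sum()),
            )
        )
    return records
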