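"""Shared fixtures and independent brute-force oracles.

The oracles re-solve the DEA programs without linear programming: for a
candidate reference-weight vector lambda the slacks are determined (standard
stage: by the equality constraints; super stage: minimal values satisfying
the inequalities), so each fractional objective is a function of lambda
alone.  Dense random sampling plus Nelder-Mead polishing with feasibility
penalties then locates the minimum.  These paths share no code with the
Charnes-Cooper LP implementation they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from healtheff.panel import PanelDataset

PENALTY = 1e6


def make_panel(x, y, b=None, units=None, periods=None, z=None, group=None):
    """Small panel from per-observation input/output arrays.

    ``x``/``y``/``b`` are (n_obs, dim) arrays or lists of vectors; units
    default to A, B, C, ...; one period unless ``periods`` given.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n = x.shape[0]
    if units is None:
        units = [chr(65 + i) for i in range(n)]
    if periods is None:
        periods = [2015] * n
    df = pd.DataFrame({"unit": units, "period": periods})
    for j in range(x.shape[1]):
        df[f"x{j+1}"] = x[:, j]
    for r in range(y.shape[1]):
        df[f"y{r+1}"] = y[:, r]
    bads = ()
    if b is not None:
        b = np.atleast_2d(np.asarray(b, float))
        for k in range(b.shape[1]):
            df[f"b{k+1}"] = b[:, k]
        bads = tuple(f"b{k+1}" for k in range(b.shape[1]))
    covs = ()
    if z is not None:
        z = np.atleast_2d(np.asarray(z, float))
        for s in range(z.shape[1]):
            df[f"z{s+1}"] = z[:, s]
        covs = tuple(f"z{s+1}" for s in range(z.shape[1]))
    if group is not None:
        df["group"] = group
    return PanelDataset(
        frame=df,
        inputs=tuple(f"x{j+1}" for j in range(x.shape[1])),
        outputs=tuple(f"y{r+1}" for r in range(y.shape[1])),
        bads=bads, covariates=covs, has_group=group is not None,
    )


FEAS_TOL = 1e-9  # rounding slack at polytope vertices


def _sbm_objective_standard(lam, x_o, y_o, b_o, X, Y, B):
    s_minus = x_o - X.T @ lam
    s_plus = Y.T @ lam - y_o
    s_bad = b_o - B.T @ lam if B.size else np.zeros(0)
    viol = (np.sum(np.minimum(s_minus + FEAS_TOL, 0) ** 2)
            + np.sum(np.minimum(s_plus + FEAS_TOL, 0) ** 2)
            + np.sum(np.minimum(s_bad + FEAS_TOL, 0) ** 2)
            + np.sum(np.minimum(lam + FEAS_TOL, 0) ** 2))
    if viol > 0:
        return 1.0 + PENALTY * viol
    s_minus, s_plus = np.maximum(s_minus, 0.0), np.maximum(s_plus, 0.0)
    s_bad = np.maximum(s_bad, 0.0)
    m, q, h = len(x_o), len(y_o), len(b_o)
    num = 1.0 - np.mean(s_minus / x_o)
    den = 1.0 + (np.sum(s_plus / y_o)
                 + (np.sum(s_bad / b_o) if h else 0.0)) / (q + h)
    return num / den


def _sbm_objective_super(lam, x_o, y_o, b_o, X, Y, B):
    lam = np.maximum(lam, 0.0)
    s_minus = np.maximum(X.T @ lam - x_o, 0.0)
    s_plus = np.maximum(y_o - Y.T @ lam, 0.0)
    s_bad = np.maximum(B.T @ lam - b_o, 0.0) if B.size else np.zeros(0)
    m, q, h = len(x_o), len(y_o), len(b_o)
    num = 1.0 + np.mean(s_minus / x_o)
    den = 1.0 - (np.sum(s_plus / y_o)
                 + (np.sum(s_bad / b_o) if h else 0.0)) / (q + h)
    if den <= 1e-9:
        # sloped penalty: keeps a descent direction toward den > 0
        return PENALTY * (1.0 + (1e-9 - den))
    return num / den


def brute_force_sbm(data: PanelDataset, unit, period, super_stage=False,
                    rts="CRS", n_samples=2000, n_polish=8, seed=0):
    """Global minimum of the SBM fractional program, independent of the LP.

    Both stages are (piecewise) linear-fractional in lambda once the slacks
    take their constraint-determined values, so every candidate optimum
    lies at a vertex of the hyperplane arrangement

        { lambda_j = 0,  (X lam)_i = x_oi,  (Y lam)_r = y_or,
          (B lam)_k = b_ok }            (plus sum lam = 1 under VRS).

    All vertices are enumerated exactly (the instances are tiny by
    construction) and a random-sampling + Nelder-Mead pass is layered on
    top as a safety net against degenerate arrangements; the smallest
    feasible objective wins.
    """
    from itertools import combinations

    rng = np.random.default_rng(seed)
    x_o, y_o, b_o = data.xyb(unit, period)
    ref = data.reference_frame(
        period=period, exclude=(unit, period) if super_stage else None)
    X = ref[list(data.inputs)].to_numpy(float)
    Y = ref[list(data.outputs)].to_numpy(float)
    B = ref[list(data.bads)].to_numpy(float) if data.h else np.zeros((len(ref), 0))
    if data.h == 0:
        b_o = np.zeros(0)
    nref = len(ref)
    obj_fn = _sbm_objective_super if super_stage else _sbm_objective_standard

    def objective(lam):
        if rts == "VRS":
            pen = PENALTY * (np.sum(lam) - 1.0) ** 2
        else:
            pen = 0.0
        return obj_fn(lam, x_o, y_o, b_o, X, Y, B) + pen

    # --- exact vertex enumeration -----------------------------------
    rows = [np.eye(nref)[j] for j in range(nref)]          # lambda_j = 0
    rhs = [0.0] * nref
    for i in range(X.shape[1]):
        rows.append(X[:, i]); rhs.append(x_o[i])
    for r in range(Y.shape[1]):
        rows.append(Y[:, r]); rhs.append(y_o[r])
    for k in range(B.shape[1]):
        rows.append(B[:, k]); rhs.append(b_o[k])
    forced = []
    if rts == "VRS":
        forced = [(np.ones(nref), 1.0)]
    free = nref - len(forced)
    cands = [np.zeros(nref)]
    for combo in combinations(range(len(rows)), free):
        A = np.array([rows[c] for c in combo] + [f[0] for f in forced])
        bb = np.array([rhs[c] for c in combo] + [f[1] for f in forced])
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        lam = np.linalg.solve(A, bb)
        if np.all(lam >= -1e-9):
            cands.append(np.maximum(lam, 0.0))
    best_val = min(objective(c) for c in cands)

    # --- sampling + polish safety net -------------------------------
    lam_hi = 3.0 * max(np.max(x_o) / X.min(), np.max(y_o) / Y.min(), 1.0)
    samples = rng.uniform(0.0, lam_hi, size=(n_samples, nref))
    if rts == "VRS":
        samples = rng.dirichlet(np.ones(nref), size=n_samples)
    pool = np.vstack([np.array(cands), samples])
    vals = np.array([objective(c) for c in pool])
    for idx in np.argsort(vals)[:n_polish]:
        res = minimize(objective, pool[idx], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        best_val = min(best_val, res.fun)
    return float(best_val)


def brute_force_output_distance(data: PanelDataset, unit, data_period,
                                frontier_period, bad_mode="as_input",
                                n_samples=6000, n_polish=10, seed=0):
    """Shephard output distance by direct phi maximization over lambda (CRS).

    For feasible lambda (X lam <= x_o), the largest expansion is
    phi(lam) = min_r (Y lam)_r / y_or; maximize over lambda and return
    1/phi*.
    """
    rng = np.random.default_rng(seed)
    x_o, y_o, b_o = data.xyb(unit, data_period)
    ref = data.reference_frame(period=frontier_period)
    X = ref[list(data.inputs)].to_numpy(float)
    Y = ref[list(data.outputs)].to_numpy(float)
    if bad_mode == "as_input" and data.h:
        X = np.hstack([X, ref[list(data.bads)].to_numpy(float)])
        x_o = np.concatenate([x_o, b_o])
    nref = len(ref)

    def neg_phi(lam):
        lam = np.maximum(lam, 0.0)
        slack = x_o - X.T @ lam
        if np.any(slack < 0):
            return PENALTY * float(np.sum(np.minimum(slack, 0) ** 2)) + 1.0
        return -float(np.min((Y.T @ lam) / y_o))

    lam_hi = 2.0 * max(np.max(x_o) / X.min(), 1.0)
    cands = rng.uniform(0.0, lam_hi, size=(n_samples, nref))
    vals = np.array([neg_phi(c) for c in cands])
    best_val = np.inf
    for idx in np.argsort(vals)[:n_polish]:
        res = minimize(neg_phi, cands[idx], method="Nelder-Mead",
                       options={"xatol": 1e-11, "fatol": 1e-13,
                                "maxiter": 4000})
        best_val = min(best_val, res.fun)
    phi_star = -best_val
    if phi_star <= 0:
        return np.nan
    return 1.0 / phi_star


def random_instance(rng, max_n=4, max_dims=3, with_bads=None):
    """Random small DEA instance within the oracle-checkable size bounds."""
    n = int(rng.integers(2, max_n + 1))
    if with_bads is None:
        with_bads = bool(rng.integers(0, 2))
    h = 1 if with_bads else 0
    m = int(rng.integers(1, max_dims - h))
    q = max_dims - h - m if rng.integers(0, 2) else int(rng.integers(1, max_dims - h - m + 1))
    q = max(q, 1)
    x = rng.uniform(0.5, 5.0, size=(n, m))
    y = rng.uniform(0.5, 5.0, size=(n, q))
    b = rng.uniform(0.5, 5.0, size=(n, h)) if h else None
    return make_panel(x, y, b)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150)
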