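"""Slacks-based-measure (SBM) DEA with undesirable outputs and super-efficiency.

Efficiency of each decision-making unit (DMU) is measured non-radially
through input excesses and output shortfalls.  Two fractional programs are
solved, each linearized by the Charnes-Cooper transformation into an LP
(scipy/HiGHS backend):

standard SBM (DMU inside the reference set)::

    rho = min [1 - (1/m) sum_i s_i^-/x_io]
              / [1 + 1/(q+h) (sum_r s_r^+/y_ro + sum_k s_k^b/b_ko)]
    s.t.  x_o = X lam + s^-,   y_o = Y lam - s^+,   b_o = B lam + s^b,
          lam, s >= 0   (VRS adds sum lam = 1)

with rho in (0, 1], and rho = 1 exactly when a zero-slack reference
combination exists;

super-efficiency SBM (DMU excluded from the reference set)::

    sigma* = min [1 + (1/m) sum_i s_i^-/x_io]
                 / [1 - 1/(q+h) (sum_r s_r^+/y_ro + sum_k s_k^-/b_ko)]
    s.t.  X lam <= x_o + s^-,  Y lam >= y_o - s^+,  B lam <= b_o + s^b

which scores standard-efficient DMUs above 1, making frontier units
comparable.  Undesirable outputs b enter as reference-technology outputs
whose expansion is penalized symmetrically with input excess.

The published scores combine the two: a DMU dominated by peers receives its
sub-unity standard score, while a frontier DMU receives its super-efficiency
score (see :func:`efficiency_score`).  The CRS/VRS pair yields the
comprehensive / pure-technical / scale decomposition
(:func:`decompose_scale`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import PanelDataset

__all__ = [
    "DEAOptions",
    "EfficiencyResult",
    "solve_sbm_standard",
    "solve_sbm_super",
    "efficiency_score",
    "efficiency_table",
    "decompose_scale",
]

_SNAP = 1e-6  # |score - 1| below this counts as exactly efficient


@dataclass(frozen=True)
class DEAOptions:
    """Model options for the SBM programs.

    rts
        "CRS" (constant returns) or "VRS" (adds the convexity constraint
        sum lambda = 1).
    frontier_scope
        "contemporaneous": the reference technology of a unit-period is the
        set of same-period observations (one frontier per year).  "global":
        all unit-periods pooled into one frontier.
    undesirable_mode
        "eq1": bads constrain the reference technology as described above;
        "none": bads are dropped (sensitivity runs).
    denominator_floor
        lower bound on the Charnes-Cooper scaling variable t, guarding the
        fractional objective's denominator.
    solver_tolerance
        tolerance handed to the LP backend and used when snapping
        near-unity scores.
    """

    rts: str = "CRS"
    frontier_scope: str = "contemporaneous"
    super: bool = True
    undesirable_mode: str = "eq1"
    denominator_floor: float = 1e-9
    solver_tolerance: float = 1e-7

    def __post_init__(self):
        if self.rts not in ("CRS", "VRS"):
            raise ValueError(f"rts must be CRS or VRS, got {self.rts!r}")
        if self.frontier_scope not in ("contemporaneous", "global"):
            raise ValueError(f"bad frontier_scope: {self.frontier_scope!r}")
        if self.undesirable_mode not in ("eq1", "none"):
            raise ValueError(f"bad undesirable_mode: {self.undesirable_mode!r}")
        if not (self.denominator_floor > 0 and self.solver_tolerance > 0):
            raise ValueError("denominator_floor and solver_tolerance must be > 0")


@dataclass
class EfficiencyResult:
    """Solution of one SBM program for one unit-period."""

    unit_id: object
    period: int
    score: float
    s_minus: np.ndarray
    s_plus: np.ndarray
    s_bad: np.ndarray
    lam: dict = field(default_factory=dict)  # (unit, period) -> weight
    status: str = "optimal"                  # optimal | infeasible | degenerate
    stage: str = "standard"                  # standard | super

    @property
    def slacks_zero(self) -> bool:
        tol = 1e-6
        return (np.all(self.s_minus <= tol) and np.all(self.s_plus <= tol)
                and np.all(self.s_bad <= tol))


def _reference(data: PanelDataset, period: int, opts: DEAOptions,
               exclude=None):
    ref_period = None if opts.frontier_scope == "global" else period
    df = data.reference_frame(period=ref_period, exclude=exclude)
    keys = list(zip(df[data.UNIT], df[data.PERIOD]))
    X = df[list(data.inputs)].to_numpy(float)          # (nref, m)
    Y = df[list(data.outputs)].to_numpy(float)
    if opts.undesirable_mode == "none" or data.h == 0:
        B = np.zeros((len(df), 0))
    else:
        B = df[list(data.bads)].to_numpy(float)
    return keys, X, Y, B


def _solve_cc(x_o, y_o, b_o, X, Y, B, opts: DEAOptions, super_stage: bool):
    """Charnes-Cooper linearized SBM program.

    Decision vector: [t, Lam (nref), S^- (m), S^+ (q), S^b (h)], all of
    which are the t-scaled originals.  Returns (score, lam, s_minus,
    s_plus, s_bad, status).
    """
    nref, m = X.shape
    q = Y.shape[1]
    h = B.shape[1]
    nvar = 1 + nref + m + q + h
    iT = 0
    iL = slice(1, 1 + nref)
    iSm = slice(1 + nref, 1 + nref + m)
    iSp = slice(1 + nref + m, 1 + nref + m + q)
    iSb = slice(1 + nref + m + q, nvar)
    w = 1.0 / (q + h)

    c = np.zeros(nvar)
    c[iT] = 1.0
    c[iSm] = (1.0 if super_stage else -1.0) / (m * x_o)

    A_eq, b_eq = [], []
    # normalization row: t -/+ w * (S^+/y_o + S^b/b_o) = 1
    row = np.zeros(nvar)
    row[iT] = 1.0
    sgn = -1.0 if super_stage else 1.0
    row[iSp] = sgn * w / y_o
    if h:
        row[iSb] = sgn * w / b_o
    A_eq.append(row)
    b_eq.append(1.0)

    A_ub, b_ub = [], []
    if super_stage:
        # X Lam - S^- <= t x_o ; -Y Lam - S^+ <= -t y_o ; B Lam - S^b <= t b_o
        for i in range(m):
            row = np.zeros(nvar)
            row[iL] = X[:, i]
            row[1 + nref + i] = -1.0
            row[iT] = -x_o[i]
            A_ub.append(row); b_ub.append(0.0)
        for r in range(q):
            row = np.zeros(nvar)
            row[iL] = -Y[:, r]
            row[1 + nref + m + r] = -1.0
            row[iT] = y_o[r]
            A_ub.append(row); b_ub.append(0.0)
        for k in range(h):
            row = np.zeros(nvar)
            row[iL] = B[:, k]
            row[1 + nref + m + q + k] = -1.0
            row[iT] = -b_o[k]
            A_ub.append(row); b_ub.append(0.0)
    else:
        # t x_o = X Lam + S^- ; t y_o = Y Lam - S^+ ; t b_o = B Lam + S^b
        for i in range(m):
            row = np.zeros(nvar)
            row[iT] = x_o[i]
            row[iL] = -X[:, i]
            row[1 + nref + i] = -1.0
            A_eq.append(row); b_eq.append(0.0)
        for r in range(q):
            row = np.zeros(nvar)
            row[iT] = y_o[r]
            row[iL] = -Y[:, r]
            row[1 + nref + m + r] = 1.0
            A_eq.append(row); b_eq.append(0.0)
        for k in range(h):
            row = np.zeros(nvar)
            row[iT] = b_o[k]
            row[iL] = -B[:, k]
            row[1 + nref + m + q + k] = -1.0
            A_eq.append(row); b_eq.append(0.0)

    if opts.rts == "VRS":
        row = np.zeros(nvar)
        row[iL] = 1.0
        row[iT] = -1.0
        A_eq.append(row); b_eq.append(0.0)

    bounds = [(opts.denominator_floor, None)] + [(0, None)] * (nvar - 1)
    res = linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if A_ub else None,
        A_eq=np.array(A_eq),
        b_eq=np.array(b_eq),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": opts.solver_tolerance,
                 "dual_feasibility_tolerance": opts.solver_tolerance},
    )
    if not res.success:
        return np.nan, None, None, None, None, "infeasible"
    t = res.x[iT]
    if t <= opts.denominator_floor * 10:
        status = "degenerate"
    else:
        status = "optimal"
    lam = res.x[iL] / t
    s_minus = res.x[iSm] / t
    s_plus = res.x[iSp] / t
    s_bad = res.x[iSb] / t
    score = float(res.fun)
    if abs(score - 1.0) < _SNAP:
        score = 1.0
    return score, lam, s_minus, s_plus, s_bad, status


def solve_sbm_standard(data: PanelDataset, unit, period: int,
                       opts: DEAOptions = DEAOptions()) -> EfficiencyResult:
    """Standard (non-super) SBM score of one unit-period, in (0, 1].

    The evaluated DMU belongs to its own reference set, so the program is
    always feasible and the score is 1 exactly when no reference
    combination improves on the DMU slack-wise.
    """
    x_o, y_o, b_all = data.xyb(unit, period)
    keys, X, Y, B = _reference(data, period, opts)
    b_o = b_all if B.shape[1] else np.zeros(0)
    score, lam, sm, sp, sb, status = _solve_cc(x_o, y_o, b_o, X, Y, B, opts,
                                               super_stage=False)
    if status == "infeasible":
        return EfficiencyResult(unit, period, np.nan, np.zeros(0), np.zeros(0),
                                np.zeros(0), {}, "infeasible", "standard")
    lam_map = {k: v for k, v in zip(keys, lam) if v > 1e-9}
    return EfficiencyResult(unit, period, score, sm, sp, sb, lam_map,
                            status, "standard")


def solve_sbm_super(data: PanelDataset, unit, period: int,
                    opts: DEAOptions = DEAOptions()) -> EfficiencyResult:
    """Super-efficiency SBM score, evaluated against all *other* DMUs.

    Scores are >= 1 for standard-efficient DMUs.  With an empty reference
    set (single DMU) or an unreachable reference combination (possible
    under VRS) the result carries ``status="infeasible"`` and an undefined
    score — never a silently substituted value.
    """
    x_o, y_o, b_all = data.xyb(unit, period)
    keys, X, Y, B = _reference(data, period, opts, exclude=(unit, period))
    if len(keys) == 0:
        return EfficiencyResult(unit, period, np.nan, np.zeros(0), np.zeros(0),
                                np.zeros(0), {}, "infeasible", "super")
    b_o = b_all if B.shape[1] else np.zeros(0)
    score, lam, sm, sp, sb, status = _solve_cc(x_o, y_o, b_o, X, Y, B, opts,
                                               super_stage=True)
    if status == "infeasible":
        return EfficiencyResult(unit, period, np.nan, np.zeros(0), np.zeros(0),
                                np.zeros(0), {}, "infeasible", "super")
    lam_map = {k: v for k, v in zip(keys, lam) if v > 1e-9}
    return EfficiencyResult(unit, period, score, sm, sp, sb, lam_map,
                            status, "super")


def efficiency_score(data: PanelDataset, unit, period: int,
                     opts: DEAOptions = DEAOptions()) -> EfficiencyResult:
    """Two-stage comprehensive efficiency score.

    Runs the standard SBM first; dominated DMUs keep their sub-unity score
    (stage="standard").  DMUs found efficient (score 1 within tolerance)
    are re-scored by the super-efficiency program (stage="super"), which
    separates frontier units from one another.  The super program alone
    would assign 1 to every dominated DMU, so both stages are needed for a
    full ranking.
    """
    std = solve_sbm_standard(data, unit, period, opts)
    if std.status == "infeasible" or std.score < 1.0:
        return std
    if not opts.super:
        return std
    sup = solve_sbm_super(data, unit, period, opts)
    if sup.status == "infeasible":
        # frontier unit with no feasible exclusion score: keep the standard 1.0
        # but surface the super-stage failure
        std.status = "degenerate" if data.n_units > 1 else std.status
        return std
    return sup


def efficiency_table(data: PanelDataset,
                     opts: DEAOptions = DEAOptions()) -> pd.DataFrame:
    """Two-stage scores for every unit-period, as a tidy frame."""
    rows = []
    for _, rec in data.frame.iterrows():
        unit, period = rec[data.UNIT], int(rec[data.PERIOD])
        res = efficiency_score(data, unit, period, opts)
        rows.append({
            "unit": unit, "period": period, "score": res.score,
            "stage": res.stage, "status": res.status,
            "slack_input_total": float(np.sum(res.s_minus)) if res.s_minus.size else 0.0,
            "slack_output_total": float(np.sum(res.s_plus)) if res.s_plus.size else 0.0,
            "slack_bad_total": float(np.sum(res.s_bad)) if res.s_bad.size else 0.0,
        })
    return pd.DataFrame(rows)


def decompose_scale(data: PanelDataset,
                    opts: DEAOptions = DEAOptions()) -> pd.DataFrame:
    """CRS / VRS / scale efficiency decomposition per unit-period.

    crste is the two-stage score under constant returns, vrste under
    variable returns, and scale = crste / vrste measures the distance of
    the unit's operating scale from the most productive scale size.  An
    infeasible VRS super stage leaves scale undefined for that record,
    flagged in ``status``.
    """
    crs_opts = replace(opts, rts="CRS")
    vrs_opts = replace(opts, rts="VRS")
    rows = []
    for _, rec in data.frame.iterrows():
        unit, period = rec[data.UNIT], int(rec[data.PERIOD])
        crs = efficiency_score(data, unit, period, crs_opts)
        vrs = efficiency_score(data, unit, period, vrs_opts)
        ok = crs.status != "infeasible" and vrs.status != "infeasible" \
            and np.isfinite(crs.score) and np.isfinite(vrs.score)
        rows.append({
            "unit": unit, "period": period,
            "crste": crs.score, "vrste": vrs.score,
            "scale": crs.score / vrs.score if ok else np.nan,
            "status": "optimal" if ok else "undefined",
        })
    return pd.DataFrame(rows)
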