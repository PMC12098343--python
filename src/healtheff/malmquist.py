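"""Malmquist total-factor-productivity index and its decomposition.

Productivity change of a DMU between consecutive periods t and t+1 is
measured from output-oriented radial distance functions D^s(x, y): the
Shephard distance of an observation against the frontier of period s
(<= 1 inside the frontier, > 1 outside).  The index

    Mi = sqrt[ (D^t(x^{t+1}, y^{t+1}) / D^t(x^t, y^t))
             * (D^{t+1}(x^{t+1}, y^{t+1}) / D^{t+1}(x^t, y^t)) ]

exceeds 1 when total factor productivity improved.  It factors exactly into

    effch  = D^{t+1}(x^{t+1}, y^{t+1}) / D^t(x^t, y^t)   (catch-up)
    techch = Mi / effch                                   (frontier shift)

with effch further split under variable returns to scale into

    pech = VRS analogue of effch        (pure technical-efficiency change)
    sech = effch / pech                 (scale-efficiency change, residual)

Four CRS and two VRS linear programs per unit and period pair.
Undesirable outputs enter the distance technology as inputs by default
(``bad_mode="as_input"``) or are dropped (``"ignore"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import PanelDataset

__all__ = [
    "DistanceValue",
    "MalmquistResult",
    "radial_distance",
    "malmquist_pair",
    "malmquist_table",
    "malmquist_summary",
]


@dataclass
class DistanceValue:
    unit_id: object
    data_period: int
    frontier_period: int
    rts: str
    value: float        # Shephard output distance, > 0 when optimal
    status: str         # optimal | infeasible


@dataclass
class MalmquistResult:
    unit_id: object
    from_period: int
    to_period: int
    mi: float
    effch: float
    techch: float
    pech: float
    sech: float
    n_infeasible: int = 0


def radial_distance(data: PanelDataset, unit, data_period: int,
                    frontier_period: int, rts: str = "CRS",
                    bad_mode: str = "as_input") -> DistanceValue:
    """Output-oriented radial (Farrell/Shephard) distance of one point.

    Solves  max phi  s.t.  X lam <= x_o,  Y lam >= phi * y_o,  lam >= 0
    (plus sum lam = 1 under VRS; bads appended to the input block when
    ``bad_mode="as_input"``) over the frontier period's observations, and
    returns the Shephard distance 1/phi*.  Cross-period VRS programs can
    be infeasible; that is reported, not patched.
    """
    if rts not in ("CRS", "VRS"):
        raise ValueError(f"rts must be CRS or VRS, got {rts!r}")
    if bad_mode not in ("as_input", "ignore"):
        raise ValueError(f"bad_mode must be as_input or ignore, got {bad_mode!r}")
    x_o, y_o, b_o = data.xyb(unit, data_period)
    ref = data.reference_frame(period=frontier_period)
    if ref.empty:
        raise ValueError(f"no observations in frontier period {frontier_period}")
    X = ref[list(data.inputs)].to_numpy(float)
    Y = ref[list(data.outputs)].to_numpy(float)
    if bad_mode == "as_input" and data.h > 0:
        X = np.hstack([X, ref[list(data.bads)].to_numpy(float)])
        x_o = np.concatenate([x_o, b_o])
    nref, m = X.shape
    q = Y.shape[1]
    nvar = 1 + nref                      # [phi, lam]
    c = np.zeros(nvar)
    c[0] = -1.0                          # maximize phi
    A_ub, b_ub = [], []
    for i in range(m):
        row = np.zeros(nvar)
        row[1:] = X[:, i]
        A_ub.append(row); b_ub.append(x_o[i])
    for r in range(q):
        row = np.zeros(nvar)
        row[0] = y_o[r]
        row[1:] = -Y[:, r]
        A_ub.append(row); b_ub.append(0.0)
    A_eq = b_eq = None
    if rts == "VRS":
        row = np.zeros(nvar)
        row[1:] = 1.0
        A_eq, b_eq = [row], [1.0]
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  A_eq=np.array(A_eq) if A_eq else None,
                  b_eq=np.array(b_eq) if b_eq else None,
                  bounds=[(0, None)] * nvar, method="highs")
    if not res.success or res.x[0] <= 0:
        return DistanceValue(unit, data_period, frontier_period, rts,
                             np.nan, "infeasible")
    return DistanceValue(unit, data_period, frontier_period, rts,
                         1.0 / res.x[0], "optimal")


def malmquist_pair(data: PanelDataset, unit, t: int, t_plus_1: int,
                   bad_mode: str = "as_input") -> MalmquistResult:
    """Malmquist index and decomposition for one unit over (t, t+1).

    Six distance LPs: the four CRS distances of the index and the two
    contemporaneous VRS distances behind pech.  Any infeasible component
    leaves the affected quantities NaN and increments ``n_infeasible``.
    """
    D = {}
    n_inf = 0
    for dp, fp, rts in [(t, t, "CRS"), (t, t_plus_1, "CRS"),
                        (t_plus_1, t, "CRS"), (t_plus_1, t_plus_1, "CRS"),
                        (t, t, "VRS"), (t_plus_1, t_plus_1, "VRS")]:
        dv = radial_distance(data, unit, dp, fp, rts, bad_mode)
        if dv.status != "optimal":
            n_inf += 1
        D[(dp, fp, rts)] = dv.value

    def ratio(a, b):
        if not (np.isfinite(a) and np.isfinite(b)) or b == 0:
            return np.nan
        return a / b

    effch = ratio(D[(t_plus_1, t_plus_1, "CRS")], D[(t, t, "CRS")])
    # mi = sqrt( [D^t(t+1)/D^t(t)] * [D^{t+1}(t+1)/D^{t+1}(t)] )
    a = ratio(D[(t_plus_1, t, "CRS")], D[(t, t, "CRS")])
    b = ratio(D[(t_plus_1, t_plus_1, "CRS")], D[(t, t_plus_1, "CRS")])
    mi = math.sqrt(a * b) if np.isfinite(a) and np.isfinite(b) and a * b > 0 else np.nan
    techch = ratio(mi, effch)
    pech = ratio(D[(t_plus_1, t_plus_1, "VRS")], D[(t, t, "VRS")])
    sech = ratio(effch, pech)
    return MalmquistResult(unit, t, t_plus_1, mi, effch, techch, pech, sech,
                           n_infeasible=n_inf)


def malmquist_table(data: PanelDataset,
                    bad_mode: str = "as_input") -> pd.DataFrame:
    """Per-unit, consecutive-period-pair Malmquist results as a frame."""
    periods = data.periods
    rows = []
    for unit in data.units:
        have = set(data.frame.loc[data.frame[data.UNIT] == unit,
                                  data.PERIOD].tolist())
        for t, t1 in zip(periods[:-1], periods[1:]):
            if t not in have or t1 not in have:
                continue
            r = malmquist_pair(data, unit, t, t1, bad_mode)
            rows.append({
                "unit": unit, "from_period": t, "to_period": t1,
                "mi": r.mi, "effch": r.effch, "techch": r.techch,
                "pech": r.pech, "sech": r.sech,
                "n_infeasible": r.n_infeasible,
            })
    return pd.DataFrame(rows)


_COMPONENTS = ["effch", "techch", "pech", "sech", "mi"]


def _gmean(s: pd.Series) -> float:
    v = s.dropna()
    v = v[v > 0]
    if v.empty:
        return np.nan
    return float(np.exp(np.mean(np.log(v))))


def malmquist_summary(results: pd.DataFrame, grouping: dict | None = None,
                      by: str = "unit") -> pd.DataFrame:
    """Geometric-mean summaries of Malmquist components.

    ``by="unit"``: one row per unit with the geometric mean of each
    component over its period pairs, plus a rank by mean mi (rank 1 =
    largest).  ``by="period"``: one row per period pair, averaged over
    units (optionally within groups from ``grouping``: unit -> group,
    plus an all-units total row).  Undefined (NaN) components are excluded,
    with exclusion counts reported.
    """
    if results.empty:
        raise ValueError("empty Malmquist results")
    df = results.copy()
    if by == "unit":
        agg = df.groupby("unit", sort=True).agg(
            **{c: (c, _gmean) for c in _COMPONENTS},
            n_pairs=("mi", "size"),
            n_excluded=("mi", lambda s: int(s.isna().sum())),
        ).reset_index()
        order = agg["mi"].rank(ascending=False, method="first", na_option="bottom")
        agg["rank"] = order.astype(int)
        return agg
    if by == "period":
        if grouping is not None:
            df["group"] = df["unit"].map(grouping)
            missing = df["group"].isna()
            if missing.any():
                raise ValueError(
                    f"unit {df.loc[missing.idxmax(), 'unit']!r} has no group")
            total = df.copy()
            total["group"] = "All"
            df = pd.concat([df, total], ignore_index=True)
            keys = ["group", "from_period", "to_period"]
        else:
            keys = ["from_period", "to_period"]
        agg = df.groupby(keys, sort=True).agg(
            **{c: (c, _gmean) for c in _COMPONENTS},
            n_units=("mi", "size"),
            n_excluded=("mi", lambda s: int(s.isna().sum())),
        ).reset_index()
        return agg
    raise ValueError(f"by must be 'unit' or 'period', got {by!r}")
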