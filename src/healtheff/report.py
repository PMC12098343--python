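"""Aggregation and ranking of efficiency scores.

Reproduces the benchmark study's summary layouts: per-city yearly scores
with their arithmetic mean and descending rank, and per-group (province)
arithmetic means by year, optionally with the CRS/VRS/scale decomposition
columns.

Efficiency scores are averaged arithmetically (Malmquist components, being
index numbers, are averaged geometrically in :mod:`healtheff.malmquist`).
Rounding is half-up to 3 decimals for display only; means and ranks are
computed at full precision.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "city_averages_and_ranks", "group_means"]


def round_half_up(value: float, decimals: int = 3) -> float:
    """Decimal half-up rounding of a float's exact binary value."""
    if not np.isfinite(value):
        return value
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(value).quantize(quantum, rounding=ROUND_HALF_UP))


def _as_long(eff: pd.DataFrame) -> pd.DataFrame:
    required = {"unit", "period", "score"}
    if not required <= set(eff.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    return eff


def city_averages_and_ranks(eff: pd.DataFrame,
                            decimals: int | None = None) -> pd.DataFrame:
    """Per-unit yearly scores, mean and rank.

    ``eff`` is a long score table (unit, period, score).  Returns one row
    per unit with a column per period, the arithmetic mean across the
    unit's periods, and a rank by descending mean (ties take the smaller
    index by first occurrence).  Ranks and means are computed before any
    rounding; pass ``decimals`` to round the value columns for display.
    """
    eff = _as_long(eff)
    if eff.empty:
        raise ValueError("empty score table")
    wide = eff.pivot_table(index="unit", columns="period", values="score",
                           aggfunc="first", sort=True)
    wide = wide.reindex(eff["unit"].drop_duplicates().tolist())
    mean = wide.mean(axis=1)
    rank = mean.rank(ascending=False, method="first", na_option="bottom")
    out = wide.copy()
    out["mean"] = mean
    out["rank"] = rank.astype(int)
    out = out.reset_index().rename_axis(columns=None)
    if decimals is not None:
        for col in out.columns:
            if col not in ("unit", "rank"):
                out[col] = out[col].map(lambda v: round_half_up(v, decimals))
    return out


def group_means(eff: pd.DataFrame, grouping: dict,
                decomposed: pd.DataFrame | None = None,
                total_label: str = "All") -> pd.DataFrame:
    """Arithmetic score means per group and period, plus an all-units row.

    ``grouping`` maps every unit to its group (province).  When a
    CRS/VRS/scale decomposition table (unit, period, crste, vrste, scale)
    is supplied, its columns are averaged the same way and merged in.
    Permutation-invariant to row order of ``eff``.
    """
    eff = _as_long(eff).copy()
    eff["group"] = eff["unit"].map(grouping)
    unmapped = eff["group"].isna()
    if unmapped.any():
        raise ValueError(
            f"unit {eff.loc[unmapped.idxmax(), 'unit']!r} has no group")

    def _agg(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        per_group = df.groupby(["group", "period"], sort=True)[cols].mean()
        total = df.groupby("period", sort=True)[cols].mean()
        total.index = pd.MultiIndex.from_product(
            [[total_label], total.index], names=["group", "period"])
        return pd.concat([per_group, total]).reset_index()

    out = _agg(eff, ["score"])
    if decomposed is not None:
        dec = decomposed.copy()
        dec["group"] = dec["unit"].map(grouping)
        if dec["group"].isna().any():
            raise ValueError("decomposition table has unmapped units")
        cols = [c for c in ("crste", "vrste", "scale") if c in dec.columns]
        out = out.merge(_agg(dec, cols), on=["group", "period"], how="left")
    return out
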