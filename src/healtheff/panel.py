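"""Panel data model and CSV I/O for city-by-year efficiency analysis.

The central container is :class:`PanelDataset`: a long-format table with one
row per decision-making unit (DMU, here a city) and period (year), carrying

* ``m`` input columns ``x`` (e.g. healthcare institutions, beds per thousand,
  technical personnel per thousand),
* ``q`` desirable output columns ``y`` (e.g. outpatient/emergency visits,
  bed utilization rate),
* ``h`` undesirable ("bad") output columns ``b`` (e.g. medical-expense share
  of household consumption, stored on the 0-100 percent scale),
* ``p`` optional covariate columns ``z`` used by the second-stage regression,
* an optional group label (province) per unit.

All downstream modules (SBM DEA, Malmquist, Tobit, reporting) consume this
container only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "PanelSchema",
    "PanelDataset",
    "read_panel",
    "write_table",
    "build_indicators",
    "INDICATOR_COLUMNS",
]


class SchemaError(ValueError):
    """A declared column is absent or the schema itself is malformed."""


class IntegrityError(ValueError):
    """Structural violation: duplicate (unit, period) keys, ragged panel."""


class ValidationError(ValueError):
    """A value violates a domain constraint (e.g. nonpositive input)."""


@dataclass(frozen=True)
class PanelSchema:
    """Maps CSV columns onto panel roles.

    ``inputs``/``outputs`` must be non-empty; ``bads``, ``covariates`` and
    ``group`` are optional.  Loadable from a YAML config block via
    :meth:`from_mapping`.
    """

    unit: str = "unit"
    period: str = "period"
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    bads: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    group: str | None = None

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PanelSchema":
        known = {"unit", "period", "inputs", "outputs", "bads", "covariates", "group"}
        unknown = set(mapping) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        kw = dict(mapping)
        for key in ("inputs", "outputs", "bads", "covariates"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PanelSchema":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict) or "schema" not in cfg:
            raise SchemaError(f"config {path} lacks a 'schema' block")
        return cls.from_mapping(cfg["schema"])


@dataclass
class PanelDataset:
    """Validated long-format panel of DMU observations.

    ``frame`` is sorted by (unit, period) with columns ``unit``, ``period``
    (integer years), the role columns listed in ``inputs`` / ``outputs`` /
    ``bads`` / ``covariates``, and optionally ``group``.
    """

    frame: pd.DataFrame
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    bads: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    has_group: bool = field(default=False)

    UNIT = "unit"
    PERIOD = "period"
    GROUP = "group"

    def __post_init__(self) -> None:
        self.inputs = tuple(self.inputs)
        self.outputs = tuple(self.outputs)
        self.bads = tuple(self.bads)
        self.covariates = tuple(self.covariates)
        self._validate()

    # -- structure -------------------------------------------------------
    def _validate(self) -> None:
        df = self.frame
        required = [self.UNIT, self.PERIOD, *self.inputs, *self.outputs,
                    *self.bads, *self.covariates]
        if self.has_group:
            required.append(self.GROUP)
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"missing column: {col!r}")
        if not self.inputs or not self.outputs:
            raise SchemaError("at least one input and one output column required")
        dup = df.duplicated([self.UNIT, self.PERIOD])
        if dup.any():
            first = df.loc[dup.idxmax(), [self.UNIT, self.PERIOD]]
            raise IntegrityError(
                f"duplicate (unit, period): ({first[self.UNIT]!r}, {first[self.PERIOD]})"
            )
        for col in (*self.inputs, *self.outputs, *self.bads):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad_rows = ~(vals > 0) | vals.isna()
            if bad_rows.any():
                row = df.loc[bad_rows.idxmax()]
                raise ValidationError(
                    f"nonpositive or missing value in column {col!r} for unit "
                    f"{row[self.UNIT]!r}, period {row[self.PERIOD]}"
                )
        df = df.sort_values([self.UNIT, self.PERIOD], kind="mergesort")
        df = df.reset_index(drop=True)
        df[self.PERIOD] = df[self.PERIOD].astype(int)
        self.frame = df

    # -- dimensions ------------------------------------------------------
    @property
    def units(self) -> list:
        return sorted(self.frame[self.UNIT].unique().tolist())

    @property
    def periods(self) -> list[int]:
        return sorted(self.frame[self.PERIOD].unique().tolist())

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def m(self) -> int:
        return len(self.inputs)

    @property
    def q(self) -> int:
        return len(self.outputs)

    @property
    def h(self) -> int:
        return len(self.bads)

    @property
    def p(self) -> int:
        return len(self.covariates)

    # -- access ----------------------------------------------------------
    def record(self, unit, period: int) -> pd.Series:
        df = self.frame
        mask = (df[self.UNIT] == unit) & (df[self.PERIOD] == period)
        if not mask.any():
            raise KeyError(f"no record for unit {unit!r}, period {period}")
        return df.loc[mask].iloc[0]

    def xyb(self, unit, period: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Input, output and bad-output vectors of one observation."""
        rec = self.record(unit, period)
        return (
            rec[list(self.inputs)].to_numpy(float),
            rec[list(self.outputs)].to_numpy(float),
            rec[list(self.bads)].to_numpy(float),
        )

    def reference_frame(self, period: int | None = None,
                        exclude: tuple | None = None) -> pd.DataFrame:
        """Observations forming a reference technology.

        ``period=None`` pools every unit-period (global frontier);
        an integer restricts to that period (contemporaneous frontier).
        ``exclude=(unit, period)`` drops one observation (super-efficiency).
        """
        df = self.frame
        if period is not None:
            df = df[df[self.PERIOD] == period]
        if exclude is not None:
            u, t = exclude
            df = df[~((df[self.UNIT] == u) & (df[self.PERIOD] == t))]
        return df

    def group_of(self, unit) -> str | None:
        if not self.has_group:
            return None
        sub = self.frame.loc[self.frame[self.UNIT] == unit, self.GROUP]
        return None if sub.empty else sub.iloc[0]

    def group_map(self) -> dict:
        if not self.has_group:
            raise ValidationError("dataset carries no group labels")
        return dict(
            self.frame.drop_duplicates(self.UNIT)
            .set_index(self.UNIT)[self.GROUP]
        )

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, PanelDataset):
            return NotImplemented
        if (self.inputs, self.outputs, self.bads, self.covariates) != (
            other.inputs, other.outputs, other.bads, other.covariates
        ):
            return False
        cols = list(self.frame.columns)
        if set(cols) != set(other.frame.columns):
            return False
        return self.frame[cols].equals(other.frame[cols])


def read_panel(path, schema: PanelSchema) -> PanelDataset:
    """Read a long CSV into a validated :class:`PanelDataset`.

    Columns are renamed from the schema's names onto the canonical role
    names; rows are normalized to (unit, period) order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {schema.unit: PanelDataset.UNIT, schema.period: PanelDataset.PERIOD}
    needed = [schema.unit, schema.period, *schema.inputs, *schema.outputs,
              *schema.bads, *schema.covariates]
    if schema.group:
        needed.append(schema.group)
        rename[schema.group] = PanelDataset.GROUP
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"missing column: {col!r} (file {path})")
    df = df[needed].rename(columns=rename)
    return PanelDataset(
        frame=df,
        inputs=schema.inputs,
        outputs=schema.outputs,
        bads=schema.bads,
        covariates=schema.covariates,
        has_group=schema.group is not None,
    )


def write_table(result, path) -> None:
    """Write a tabular result to CSV with deterministic column order.

    Accepts a DataFrame or a :class:`PanelDataset`.  Values round-trip at
    full precision (``repr`` formatting).  An empty table is an error: a
    silent empty file would mask an upstream failure.
    """
    if isinstance(result, PanelDataset):
        frame = result.frame
    elif isinstance(result, pd.DataFrame):
        frame = result
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    if frame.empty:
        raise ValidationError(f"refusing to write empty table to {path}")
    frame.to_csv(path, index=False, float_format="%.17g")


#: canonical names produced by :func:`build_indicators`, in role order
INDICATOR_COLUMNS = {
    "inputs": ("institutions", "beds_per_thousand", "technicians_per_thousand"),
    "outputs": ("visits", "bed_utilization"),
    "bads": ("medical_expense_share",),
    "covariates": (
        "urbanization_rate",
        "gdp_per_capita",
        "income_gap_index",
        "health_expenditure_share",
        "fiscal_autonomy",
        "doctor_nurse_ratio",
        "staff_technician_ratio",
        "avg_length_of_stay",
    ),
}

_RAW_DENOMS = {
    "population": ("beds_per_thousand", "technicians_per_thousand",
                   "urbanization_rate", "gdp_per_capita"),
    "total_consumption": ("medical_expense_share",),
    "bed_days_open": ("bed_utilization",),
    "rural_income": ("income_gap_index",),
    "budget_expenditure": ("health_expenditure_share", "fiscal_autonomy"),
    "nurses": ("doctor_nurse_ratio",),
    "health_technical_personnel": ("staff_technician_ratio",),
    "discharged_patients": ("avg_length_of_stay",),
}


def build_indicators(raw: pd.DataFrame, group_col: str | None = None) -> PanelDataset:
    """Construct the efficiency-analysis indicator panel from raw counts.

    ``raw`` holds one row per city-year of administrative quantities
    (institutions, beds, population, visit counts, expenditures, personnel
    counts, ...).  Emits per record:

    inputs
        institutions; beds per thousand residents; health technical
        personnel per thousand residents
    outputs
        outpatient+emergency visits; bed utilization rate
        (bed-days used / bed-days open)
    undesirable output
        medical expense share of household consumption, percent
    covariates
        urbanization rate (%), per-capita GDP, urban/rural income ratio,
        health fiscal-expenditure share (%), fiscal autonomy (%),
        doctor-to-nurse ratio (%), (physicians+nurses)/technical staff (%),
        average length of stay (days)
    """
    required = ["unit", "period", "institutions", "beds", "population",
                "technicians", "visits", "bed_days_used", "bed_days_open",
                "medical_expense", "total_consumption", "urban_population",
                "gdp", "urban_income", "rural_income", "health_expenditure",
                "budget_expenditure", "budget_revenue", "physicians", "nurses",
                "health_technical_personnel", "inpatient_days",
                "discharged_patients"]
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"missing raw column: {col!r}")
    for denom in _RAW_DENOMS:
        nz = ~(pd.to_numeric(raw[denom], errors="coerce") > 0)
        if nz.any():
            row = raw.loc[nz.idxmax()]
            raise ValidationError(
                f"nonpositive denominator {denom!r} for unit {row['unit']!r}, "
                f"period {row['period']}"
            )

    out = pd.DataFrame({
        "unit": raw["unit"],
        "period": raw["period"].astype(int),
        "institutions": raw["institutions"].astype(float),
        "beds_per_thousand": raw["beds"] / raw["population"] * 1000.0,
        "technicians_per_thousand": raw["technicians"] / raw["population"] * 1000.0,
        "visits": raw["visits"].astype(float),
        "bed_utilization": raw["bed_days_used"] / raw["bed_days_open"],
        "medical_expense_share": raw["medical_expense"] / raw["total_consumption"] * 100.0,
        "urbanization_rate": raw["urban_population"] / raw["population"] * 100.0,
        "gdp_per_capita": raw["gdp"] / raw["population"],
        "income_gap_index": raw["urban_income"] / raw["rural_income"],
        "health_expenditure_share": raw["health_expenditure"] / raw["budget_expenditure"] * 100.0,
        "fiscal_autonomy": raw["budget_revenue"] / raw["budget_expenditure"] * 100.0,
        "doctor_nurse_ratio": raw["physicians"] / raw["nurses"] * 100.0,
        "staff_technician_ratio": (raw["physicians"] + raw["nurses"])
        / raw["health_technical_personnel"] * 100.0,
        "avg_length_of_stay": raw["inpatient_days"] / raw["discharged_patients"],
    })
    has_group = group_col is not None
    if has_group:
        if group_col not in raw.columns:
            raise SchemaError(f"missing group column: {group_col!r}")
        out["group"] = raw[group_col]
    return PanelDataset(
        frame=out,
        inputs=INDICATOR_COLUMNS["inputs"],
        outputs=INDICATOR_COLUMNS["outputs"],
        bads=INDICATOR_COLUMNS["bads"],
        covariates=INDICATOR_COLUMNS["covariates"],
        has_group=has_group,
    )
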