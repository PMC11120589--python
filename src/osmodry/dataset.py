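"""Run tables for osmotic-dehydration experiments.

The central object is the :class:`DesignTable`: one row per experimental run
of a 3-factor Box-Behnken design (temperature ``T`` in degC, osmotic-solution
concentration ``Conc`` in % mass, process time ``t`` in h) together with the
measured responses.  Two reference tables ship with the package:

``table1``
    The 15-run design with 13 responses (dehydration indices, minerals,
    antioxidant IC50s, flavonoids, phenols, acidity, betaine), stored as
    replicate means with their standard deviations.
``table4``
    A 28-day storage-stability series for the optimally dehydrated product,
    uncoated (``OD``) and coated with a biopolymer film (``ODC``).

Tables are plain CSV (comma separator, period decimal mark, UTF-8); a
standard deviation column for response ``X`` is named ``X_sd``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "RESPONSES",
    "STORAGE_ANALYTES",
    "STORAGE_DAYS",
    "UNITS",
    "DataValidationError",
    "FactorSettings",
    "DesignTable",
    "StorageSeries",
    "load_design_table",
    "load_storage_series",
    "retention_summary",
]

FACTORS = ["T", "Conc", "t"]

RESPONSES = [
    "DMC", "WL", "SG", "Mg", "K", "Na", "Ca",
    "DPPH", "ABTS", "flavonoids", "phenols", "acidity", "betaine",
]

STORAGE_ANALYTES = ["acidity", "phenols", "flavonoids", "betaine", "DPPH", "ABTS"]
STORAGE_DAYS = (0, 7, 14, 21, 28)

#: Measurement units, verbatim from the source tables' footnotes.  Note the
#: mineral unit is recorded as mg/kg (the table header) although parts of the
#: accompanying narrative quote mg/100 g; the discrepancy is documented, not
#: resolved.
UNITS = {
    "T": "degC",
    "Conc": "% mass",
    "t": "h",
    "DMC": "%",
    "WL": "g/g f.s.",
    "SG": "g/g f.s.",
    "Mg": "mg/kg",
    "K": "mg/kg",
    "Na": "mg/kg",
    "Ca": "mg/kg",
    "DPPH": "IC50 (mg/mL)",
    "ABTS": "IC50 (mg/mL)",
    "flavonoids": "mg ECA/100 g d.m.",
    "phenols": "mg eq.GA/100 g d.m.",
    "acidity": "% d.m.",
    "betaine": "mg/100 g d.m.",
}

_BUILTINS = {"table1": "table1.csv", "table4": "table4.csv"}


class DataValidationError(ValueError):
    """A run table failed validation; the message names the offending cell."""


@dataclass(frozen=True)
class FactorSettings:
    """Process settings of one osmotic-dehydration run."""

    T: float      # temperature, degC
    Conc: float   # osmotic-solution concentration, % mass
    t: float      # process time, h

    def __post_init__(self) -> None:
        for name in FACTORS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise DataValidationError(
                    f"factor {name!r} must be a positive finite number, got {value!r}"
                )


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = out.index[converted.isna() & out[col].notna()]
        if len(bad):
            row = bad[0]
            raise DataValidationError(
                f"non-numeric value {out.loc[row, col]!r} in column {col!r}, row {row + 1}"
            )
        if converted.isna().any():
            row = out.index[converted.isna()][0]
            raise DataValidationError(f"missing value in column {col!r}, row {row + 1}")
        out[col] = converted.astype(float)
    return out


class DesignTable:
    """A validated run table: run ids, factor settings and response means.

    Parameters
    ----------
    data:
        One row per run.  Required columns: ``run``, the three factors, and
        at least one response column.  Optional ``*_sd`` columns carry
        replicate standard deviations.
    units:
        Column unit strings; defaults to :data:`UNITS` for known columns.
    """

    def __init__(self, data: pd.DataFrame, units: dict[str, str] | None = None):
        missing = [c for c in ["run", *FACTORS] if c not in data.columns]
        if missing:
            raise DataValidationError(f"missing required column(s): {missing}")
        data = data.reset_index(drop=True)
        response_cols = [
            c for c in data.columns
            if c not in ("run", *FACTORS) and not c.endswith("_sd")
        ]
        if not response_cols:
            raise DataValidationError("table has no response columns")
        sd_cols = [c for c in data.columns if c.endswith("_sd")]
        data = _coerce_numeric(data, ["run", *FACTORS, *response_cols, *sd_cols])
        if (data["run"] % 1 == 0).all():
            data["run"] = data["run"].astype(int)

        dup = data["run"][data["run"].duplicated()]
        if len(dup):
            raise DataValidationError(f"duplicate run id(s): {sorted(set(dup))}")
        for _, row in data.iterrows():
            FactorSettings(row["T"], row["Conc"], row["t"])
        for col in response_cols:
            if (data[col] < 0).any():
                row = data.index[data[col] < 0][0]
                raise DataValidationError(f"negative value in column {col!r}, row {row + 1}")
        if "WL" in response_cols and (data["WL"] > 1).any():
            raise DataValidationError("WL values must lie in [0, 1] g/g fresh sample")
        if "DMC" in response_cols and (data["DMC"] > 100).any():
            raise DataValidationError("DMC values must lie in [0, 100] %")

        self._data = data
        self.response_columns: list[str] = response_cols
        self.units = dict(units) if units is not None else {
            c: UNITS.get(c, "") for c in ("run", *FACTORS, *response_cols)
        }

    # -- accessors ---------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """The full table (copy), including any ``*_sd`` columns."""
        return self._data.copy()

    @property
    def n_runs(self) -> int:
        return len(self._data)

    @property
    def run_ids(self) -> list[int]:
        return [int(r) for r in self._data["run"]]

    def factors(self) -> pd.DataFrame:
        """Factor settings, indexed by run id."""
        return self._data.set_index("run")[FACTORS]

    def responses(self) -> pd.DataFrame:
        """Response means, indexed by run id."""
        return self._data.set_index("run")[self.response_columns]

    def run(self, run_id: int) -> tuple[FactorSettings, pd.Series]:
        """Factor settings and response vector of a single run."""
        match = self._data[self._data["run"] == run_id]
        if match.empty:
            raise KeyError(f"no run with id {run_id}")
        row = match.iloc[0]
        return FactorSettings(row["T"], row["Conc"], row["t"]), row[self.response_columns]

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        self._data.to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "units": self.units,
            "runs": json.loads(self._data.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DesignTable":
        return cls(pd.read_csv(path))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DesignTable({self.n_runs} runs x {len(self.response_columns)} responses)"


@dataclass(frozen=True)
class StorageSeries:
    """Storage-stability measurements of one arm (coated or uncoated).

    ``data`` is indexed by storage day and holds one column per analyte
    (plus optional ``*_sd`` columns).
    """

    arm: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        days = list(self.data.index)
        if days != sorted(days) or len(set(days)) != len(days):
            raise DataValidationError(f"arm {self.arm!r}: days must be strictly increasing")
        missing = [d for d in STORAGE_DAYS if d not in days]
        if missing:
            raise DataValidationError(f"arm {self.arm!r}: missing storage day(s) {missing}")

    @property
    def analytes(self) -> list[str]:
        return [c for c in self.data.columns if not c.endswith("_sd")]


def _resolve(path_or_builtin: Union[str, Path]) -> Union[str, Path]:
    name = str(path_or_builtin)
    if name in _BUILTINS:
        return resources.files("osmodry") / "data" / _BUILTINS[name]
    return path_or_builtin


def load_design_table(path_or_builtin: Union[str, Path] = "table1") -> DesignTable:
    """Load a design table from CSV, or a packaged table by name.

    ``"table1"`` loads the bundled 15-run reference experiment.
    """
    source = _resolve(path_or_builtin)
    table = DesignTable(pd.read_csv(source))
    if str(path_or_builtin) == "table1":
        # the reference table is complete by construction
        assert table.n_runs == 15 and table.response_columns == RESPONSES
    return table


def load_storage_series(path_or_builtin: Union[str, Path] = "table4") -> list[StorageSeries]:
    """Load storage-stability series (one per arm) from CSV.

    ``"table4"`` loads the bundled 28-day storage experiment, two arms
    (``OD`` uncoated, ``ODC`` coated) at days 0/7/14/21/28.
    """
    df = pd.read_csv(_resolve(path_or_builtin))
    for col in ("arm", "day"):
        if col not in df.columns:
            raise DataValidationError(f"missing required column(s): ['{col}']")
    value_cols = [c for c in df.columns if c not in ("arm", "day")]
    df = _coerce_numeric(df, ["day", *value_cols])
    series = []
    for arm, group in df.groupby("arm", sort=True):
        frame = group.set_index(group["day"].astype(int)).drop(columns=["arm", "day"])
        frame.index.name = "day"
        series.append(StorageSeries(arm=str(arm), data=frame))
    return series


def retention_summary(series: StorageSeries) -> pd.DataFrame:
    """Percent change of each analyte relative to day 0.

    Returns a day-indexed table where entry ``(d, a)`` is
    ``100 * (value_d - value_0) / value_0``; the day-0 row is zero by
    construction.  Raises if any analyte's baseline is zero.
    """
    values = series.data[series.analytes]
    baseline = values.iloc[0]
    zero = baseline.index[baseline == 0]
    if len(zero):
        raise DataValidationError(
            f"arm {series.arm!r}: zero day-0 baseline for {list(zero)}; percent change undefined"
        )
    return 100.0 * (values - baseline) / baseline
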