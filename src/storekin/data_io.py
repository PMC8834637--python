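"""Observation data model, CSV round-trip and study-design validation.

The on-disk exchange format is a plain UTF-8 CSV with a mandatory header
and decimal points (never commas)::

    carotenoid,packaging,condition,temperature_C,exposure,exposure_unit,replicate,concentration_ug_per_g

``exposure_unit`` is "day" for dark storage (exposure in days) and
"Mlux_h" for illuminated storage (cumulative light dose in Mlux·h). The
unit is carried explicitly per row and cross-checked against the axis so a
time table and a dose table can never silently mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kinetics import AXIS_UNIT, Axis

__all__ = [
    "COLUMNS",
    "SchemaError",
    "ValidationError",
    "Observation",
    "StudyTable",
    "StudyDesign",
    "read_observations",
    "write_observations",
    "validate_design",
    "DesignReport",
]

COLUMNS = (
    "carotenoid",
    "packaging",
    "condition",
    "temperature_C",
    "exposure",
    "exposure_unit",
    "replicate",
    "concentration_ug_per_g",
)

PACKAGINGS = ("glass", "PET")
CONDITIONS = ("dark", "illuminated")

#: Group key: one fit is performed per unique combination of these.
GROUP_KEYS = ("carotenoid", "packaging", "condition")

TEMP_RANGE = (-20.0, 100.0)


class SchemaError(ValueError):
    """The file header does not match the documented CSV schema."""


class ValidationError(ValueError):
    """A row violates an invariant (sign, range, unit consistency)."""


@dataclass(frozen=True)
class Observation:
    """One measured concentration point.

    ``exposure`` is in days (dark) or Mlux·h (illuminated); ``concentration``
    is µg carotenoid per g beverage.
    """

    carotenoid: str
    packaging: str
    condition: str
    temperature_C: float
    exposure: float
    replicate: int
    concentration: float


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout: temperatures, per-temperature exposure grids, replicates.

    Grids must start at 0 (a baseline sample taken immediately after
    processing) and increase strictly.
    """

    temperatures: tuple[float, ...]
    exposure_grid: dict[float, tuple[float, ...]]
    replicates: int = 2

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for t in self.temperatures:
            grid = np.asarray(self.exposure_grid[t], dtype=float)
            if grid[0] != 0:
                raise ValueError(f"exposure grid at {t} °C must start at 0")
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"exposure grid at {t} °C must increase strictly")


class StudyTable:
    """An ordered collection of observations on a single exposure axis.

    Thin wrapper over a :class:`pandas.DataFrame` with the schema columns;
    ``axis`` declares whether exposure is time (days) or light dose (Mlux·h).
    """

    def __init__(self, df: pd.DataFrame, axis: Axis):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        if axis not in AXIS_UNIT:
            raise ValueError(f"unknown axis {axis!r}")
        self.df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        self.axis: Axis = axis
        _validate_rows(self.df, axis)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyTable):
            return NotImplemented
        return self.axis == other.axis and self.df.equals(other.df)

    def observations(self) -> list[Observation]:
        return [
            Observation(
                carotenoid=r.carotenoid,
                packaging=r.packaging,
                condition=r.condition,
                temperature_C=float(r.temperature_C),
                exposure=float(r.exposure),
                replicate=int(r.replicate),
                concentration=float(r.concentration_ug_per_g),
            )
            for r in self.df.itertuples(index=False)
        ]

    def groups(self) -> dict[tuple, "StudyTable"]:
        """Split by (carotenoid, packaging, condition), preserving row order."""
        out: dict[tuple, StudyTable] = {}
        for key, sub in self.df.groupby(list(GROUP_KEYS), sort=False):
            out[tuple(key)] = StudyTable(sub.reset_index(drop=True), self.axis)
        return out

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(temperature °C, exposure, concentration) as float arrays."""
        return (
            self.df["temperature_C"].to_numpy(float),
            self.df["exposure"].to_numpy(float),
            self.df["concentration_ug_per_g"].to_numpy(float),
        )

    def averaged_replicates(self) -> "StudyTable":
        """Optional pre-averaging of replicates at each design point.

        The default analysis keeps replicates as independent observations
        (preserving degrees of freedom in m); this offers the alternative.
        """
        keys = [*GROUP_KEYS, "temperature_C", "exposure", "exposure_unit"]
        agg = (
            self.df.groupby(keys, sort=False, as_index=False)["concentration_ug_per_g"]
            .mean()
            .assign(replicate=1)
        )
        return StudyTable(agg.loc[:, list(COLUMNS)], self.axis)


def _validate_rows(df: pd.DataFrame, axis: Axis) -> None:
    expected_unit = AXIS_UNIT[axis]
    for i, r in enumerate(df.itertuples(index=False)):
        row = i + 1  # 1-based data-row number, as in the file after the header
        if r.concentration_ug_per_g < 0:
            raise ValidationError(f"row {row}: negative concentration {r.concentration_ug_per_g}")
        if r.exposure < 0:
            raise ValidationError(f"row {row}: negative exposure {r.exposure}")
        if not (TEMP_RANGE[0] <= r.temperature_C <= TEMP_RANGE[1]):
            raise ValidationError(
                f"row {row}: temperature {r.temperature_C} °C outside {TEMP_RANGE}"
            )
        if r.exposure_unit != expected_unit:
            raise ValidationError(
                f"row {row}: exposure_unit {r.exposure_unit!r} does not match axis "
                f"{axis!r} (expected {expected_unit!r})"
            )
        if r.replicate < 1 or int(r.replicate) != r.replicate:
            raise ValidationError(f"row {row}: replicate must be a positive integer")
        if r.packaging not in PACKAGINGS:
            raise ValidationError(f"row {row}: packaging must be one of {PACKAGINGS}")
        if r.condition not in CONDITIONS:
            raise ValidationError(f"row {row}: condition must be one of {CONDITIONS}")


def read_observations(path: str | Path, axis: Axis) -> StudyTable:
    """Read a CSV of the documented schema into a :class:`StudyTable`.

    Row order is preserved; every row's ``exposure_unit`` is cross-checked
    against ``axis``. Raises :class:`SchemaError` for a bad header and
    :class:`ValidationError` (citing the 1-based data row) for bad values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"carotenoid": str, "packaging": str, "condition": str},
        float_precision="round_trip",
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    if df.empty:  # header-only file: give numeric columns their proper dtype
        df = df.astype(
            {
                "temperature_C": float,
                "exposure": float,
                "concentration_ug_per_g": float,
                "replicate": int,
            }
        )
    for col in ("temperature_C", "exposure", "concentration_ug_per_g"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"{path.name}: column {col!r} is not numeric")
        df[col] = df[col].astype(float)
    return StudyTable(df, axis)


def write_observations(table: StudyTable, path: str | Path) -> None:
    """Write the table to CSV, re-readable to an equal table.

    Floats are written at repr precision (shortest exact form), and
    :func:`read_observations` parses with round-trip precision, so values
    survive the text round trip bit-for-bit.
    """
    table.df.to_csv(path, index=False)


@dataclass
class DesignReport:
    """Outcome of :func:`validate_design`: findings plus the fittable groups."""

    findings: list[str] = field(default_factory=list)
    fittable: list[tuple] = field(default_factory=list)
    unfittable: dict[tuple, str] = field(default_factory=dict)
    group_counts: dict[tuple, dict] = field(default_factory=dict)

    def is_fittable(self, key: tuple) -> bool:
        return key in self.fittable


def validate_design(table: StudyTable) -> DesignReport:
    """Label each (carotenoid, packaging, condition) group fittable or not.

    A fittable group has ≥ 2 distinct temperatures with ≥ 3 exposure points
    each (the one-step Arrhenius regression needs both a decay signal and a
    temperature contrast). Pure reporting: the table is never mutated.
    """
    report = DesignReport()
    dup_keys = [*GROUP_KEYS, "temperature_C", "exposure", "replicate"]
    dups = table.df.duplicated(subset=dup_keys)
    if dups.any():
        report.findings.append(
            f"{int(dups.sum())} duplicate (group, temperature, exposure, replicate) key(s)"
        )
    for key, sub in table.df.groupby(list(GROUP_KEYS), sort=False):
        key = tuple(key)
        temps = sub["temperature_C"].unique()
        pts_per_temp = {
            float(t): sub.loc[sub["temperature_C"] == t, "exposure"].nunique() for t in temps
        }
        usable = [t for t, n in pts_per_temp.items() if n >= 3]
        counts = {
            "n_observations": len(sub),
            "n_temperatures": len(temps),
            "exposures_per_temperature": pts_per_temp,
            "n_replicates": int(sub["replicate"].nunique()),
        }
        report.group_counts[key] = counts
        if len(temps) < 2:
            report.unfittable[key] = "Arrhenius needs >=2 temperatures"
        elif len(usable) < 2:
            report.unfittable[key] = "needs >=2 temperatures with >=3 exposure points each"
        else:
            report.fittable.append(key)
        if not (sub["exposure"] == 0).any():
            report.findings.append(f"{key}: no time-0 observation")
    for key, reason in report.unfittable.items():
        report.findings.append(f"{key}: unfittable — {reason}")
    return report


def table_from_observations(obs: Iterable[Observation], axis: Axis) -> StudyTable:
    """Build a StudyTable from Observation records (test/synthesis helper)."""
    unit = AXIS_UNIT[axis]
    rows = [
        {
            "carotenoid": o.carotenoid,
            "packaging": o.packaging,
            "condition": o.condition,
            "temperature_C": o.temperature_C,
            "exposure": o.exposure,
            "exposure_unit": unit,
            "replicate": o.replicate,
            "concentration_ug_per_g": o.concentration,
        }
        for o in obs
    ]
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    if df.empty:
        df = df.astype(
            {
                "temperature_C": float,
                "exposure": float,
                "concentration_ug_per_g": float,
                "replicate": int,
            }
        )
    return StudyTable(df, axis)
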