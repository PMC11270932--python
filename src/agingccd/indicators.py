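"""Indicator system data model, validation and CSV ingestion.

The package evaluates three interacting subsystems — the elderly population,
healthcare resource demand and healthcare resource supply — from a panel of
observed indicators.  Each indicator belongs to exactly one subsystem and has
a polarity: a *positive* indicator improves the subsystem as it grows (e.g.
number of hospital beds), a *negative* one worsens it (e.g. out-of-pocket
share of medical spending).  Polarity drives the direction of min–max
normalization downstream.

An :class:`IndicatorPanel` holds the raw values ``x[region, year, indicator]``
as a pandas DataFrame indexed by ``(region, year)`` with one column per
indicator.  Construction validates completeness and finiteness, so downstream
stages can assume a dense, numeric panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

SUBSYSTEMS: tuple[str, ...] = ("elderly_population", "demand", "supply")
POLARITIES: tuple[str, ...] = ("positive", "negative")

#: indicators measured as counts/levels that cannot meaningfully be negative
_COUNT_LIKE_UNITS = ("people", "beds", "piece", "time", "rmb", "yuan", "km")


@dataclass(frozen=True)
class IndicatorSpec:
    """Identity and metadata of one evaluation indicator.

    Parameters
    ----------
    indicator_id
        Short stable identifier (snake_case), unique within a specification
        set; used as the column name in all tabular outputs.
    label
        Human-readable name.
    subsystem
        One of ``elderly_population``, ``demand``, ``supply``.
    polarity
        ``positive`` if larger raw values improve the subsystem,
        ``negative`` otherwise.
    unit
        Free-text unit; metadata only, no conversion is ever applied
        (min–max normalization is scale invariant).
    reference_weight
        Optional published weight kept for cross-checking; never used in
        computation.
    """

    indicator_id: str
    label: str
    subsystem: str
    polarity: str
    unit: str = ""
    reference_weight: float | None = None

    def __post_init__(self) -> None:
        if self.subsystem not in SUBSYSTEMS:
            raise ValueError(
                f"subsystem {self.subsystem!r} not one of {SUBSYSTEMS}"
            )
        if self.polarity not in POLARITIES:
            raise ValueError(
                f"polarity {self.polarity!r} not one of {POLARITIES}"
            )
        if not self.indicator_id:
            raise ValueError("indicator_id must be non-empty")


@dataclass
class ValidationIssue:
    severity: Literal["error", "warning"]
    where: str
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_panel`; ``ok`` iff no error-level issue."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]


def _check_spec_unique(spec: Sequence[IndicatorSpec]) -> dict[str, IndicatorSpec]:
    by_id: dict[str, IndicatorSpec] = {}
    for s in spec:
        if s.indicator_id in by_id:
            raise ValueError(f"duplicate indicator_id {s.indicator_id!r}")
        by_id[s.indicator_id] = s
    if not by_id:
        raise ValueError("indicator specification set is empty")
    return by_id


class IndicatorPanel:
    """Dense panel of raw indicator values for regions × years.

    ``values`` is a DataFrame with a 2-level MultiIndex ``(region, year)``
    and one float column per indicator_id declared in ``spec``.
    """

    def __init__(self, values: pd.DataFrame, spec: Sequence[IndicatorSpec]):
        self._spec = list(spec)
        self._by_id = _check_spec_unique(self._spec)

        if list(values.index.names) != ["region", "year"]:
            raise ValueError("values must be indexed by (region, year)")
        unknown = [c for c in values.columns if c not in self._by_id]
        if unknown:
            raise ValueError(f"unknown indicator_id(s) in panel: {unknown}")
        missing_cols = [i for i in self._by_id if i not in values.columns]
        if missing_cols:
            raise ValueError(f"panel lacks indicator column(s): {missing_cols}")

        values = values[[s.indicator_id for s in self._spec]].astype(float)
        # dense grid: every (region, year) row must carry every indicator
        bad = values.isna() | ~np.isfinite(values)
        if bad.to_numpy().any():
            cells = [
                f"({r}, {y}, {c})"
                for (r, y), row in bad.iterrows()
                for c in values.columns[row.to_numpy()]
            ]
            raise ValueError(
                "missing or non-finite cell(s): " + ", ".join(cells[:10])
                + ("..." if len(cells) > 10 else "")
            )
        # a full region × year grid, years sorted increasing within region
        regions = list(dict.fromkeys(values.index.get_level_values("region")))
        years = sorted(set(values.index.get_level_values("year")))
        full = pd.MultiIndex.from_product([regions, years], names=["region", "year"])
        if len(values.index) != len(full) or not values.index.sort_values().equals(
            full.sort_values()
        ):
            have = set(values.index)
            missing = [c for c in full if c not in have]
            raise ValueError(
                f"incomplete region × year grid; missing rows: {missing[:10]}"
            )
        self._values = values.reindex(full)

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def spec(self) -> list[IndicatorSpec]:
        return list(self._spec)

    @property
    def spec_by_id(self) -> dict[str, IndicatorSpec]:
        return dict(self._by_id)

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self._values.index.get_level_values("region")))

    @property
    def years(self) -> list[int]:
        return sorted(set(int(y) for y in self._values.index.get_level_values("year")))

    @property
    def indicators(self) -> list[str]:
        return list(self._values.columns)

    def subsystem_indicators(self, subsystem: str) -> list[str]:
        return [s.indicator_id for s in self._spec if s.subsystem == subsystem]

    def value(self, region: str, year: int, indicator_id: str) -> float:
        return float(self._values.loc[(region, year), indicator_id])

    def n_cells(self) -> int:
        return int(self._values.size)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_long(
        cls, df: pd.DataFrame, spec: Sequence[IndicatorSpec]
    ) -> "IndicatorPanel":
        required = {"region", "year", "indicator_id", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(required)}")
        by_id = _check_spec_unique(spec)
        unknown = sorted(set(df["indicator_id"]) - set(by_id))
        if unknown:
            raise ValueError(f"unknown indicator_id(s): {unknown}")
        wide = df.pivot_table(
            index=["region", "year"],
            columns="indicator_id",
            values="value",
            aggfunc="first",
        )
        wide.columns.name = None
        missing = wide.columns[wide.isna().any()].tolist()
        if missing or set(wide.columns) != set(by_id):
            absent = sorted(set(by_id) - set(wide.columns))
            cells = [
                f"({r}, {y}, {c})"
                for (r, y), row in wide.iterrows()
                for c in wide.columns[row.isna().to_numpy()]
            ]
            if absent or cells:
                raise ValueError(
                    "missing cell(s): "
                    + ", ".join(cells[:10] + [f"indicator {a} absent" for a in absent])
                )
        return cls(wide, spec)

    @classmethod
    def from_wide(
        cls, df: pd.DataFrame, spec: Sequence[IndicatorSpec]
    ) -> "IndicatorPanel":
        if not {"region", "year"}.issubset(df.columns):
            raise ValueError("wide layout requires 'region' and 'year' columns")
        wide = df.set_index(["region", "year"])
        return cls(wide, spec)

    def to_long(self) -> pd.DataFrame:
        long = (
            self._values.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_2": "indicator_id"})
        )
        return long[["region", "year", "indicator_id", "value"]]

    def to_wide(self) -> pd.DataFrame:
        return self._values.reset_index()


def load_indicator_spec(path: str | Path) -> list[IndicatorSpec]:
    """Read an indicator specification from a YAML or JSON list of records."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    records = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    if not isinstance(records, list):
        raise ValueError("indicator spec file must contain a list of records")
    specs = []
    for rec in records:
        known = {
            k: rec[k]
            for k in (
                "indicator_id",
                "label",
                "subsystem",
                "polarity",
                "unit",
                "reference_weight",
            )
            if k in rec
        }
        specs.append(IndicatorSpec(**known))
    _check_spec_unique(specs)
    return specs


def load_panel(
    path: str | Path,
    spec: Sequence[IndicatorSpec],
    layout: Literal["long", "wide"] = "long",
) -> IndicatorPanel:
    """Load and validate an indicator panel from CSV.

    ``long`` layout has columns ``region, year, indicator_id, value``;
    ``wide`` layout has ``region, year`` plus one column per indicator_id.
    Any missing cell, unknown indicator or non-numeric value raises
    ``ValueError`` naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if layout == "long":
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        return IndicatorPanel.from_long(df, spec)
    if layout == "wide":
        return IndicatorPanel.from_wide(df, spec)
    raise ValueError(f"unknown layout {layout!r}")


def write_panel(
    panel: IndicatorPanel,
    path: str | Path,
    layout: Literal["long", "wide"] = "long",
) -> None:
    """Write a panel to CSV in the given layout (inverse of :func:`load_panel`)."""
    df = panel.to_long() if layout == "long" else panel.to_wide()
    df.to_csv(path, index=False)


def validate_panel(panel: IndicatorPanel) -> ValidationReport:
    """Run soft diagnostics on an already-constructed panel.

    Completeness and finiteness are hard invariants enforced at construction;
    this reports the quality issues that do not invalidate the panel:
    constant indicators (which carry no information and will receive zero
    entropy weight) and negative raw values on count-like indicators.
    """
    report = ValidationReport()
    vals = panel.values
    for ind in panel.indicators:
        col = vals[ind]
        if float(col.max()) == float(col.min()):
            report.issues.append(
                ValidationIssue(
                    "warning", ind, "constant indicator (max = min over the panel)"
                )
            )
        unit = panel.spec_by_id[ind].unit.lower()
        if any(tok in unit for tok in _COUNT_LIKE_UNITS) and (col < 0).any():
            report.issues.append(
                ValidationIssue(
                    "warning", ind, "negative raw value for a count-type indicator"
                )
            )
    return report


def panels_equal(a: IndicatorPanel, b: IndicatorPanel) -> bool:
    """True if two panels agree cell-for-cell on the same axes."""
    return (
        a.regions == b.regions
        and a.years == b.years
        and a.indicators == b.indicators
        and a.values.equals(b.values)
    )
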