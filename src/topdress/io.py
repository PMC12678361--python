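"""File formats: weather/observation CSVs, soil/management/parameter YAML,
plain-text raster matrices.

All dialects are plain text and round-trip losslessly; malformed rows are
reported with their line number.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .agb import SpectralSample
from .assimilation import ParameterSpec
from .crop_model import (
    FertilizationEvent,
    IrrigationEvent,
    ManagementPlan,
    SoilInit,
    WeatherDay,
    WeatherSeries,
)

__all__ = [
    "ParseError",
    "read_weather_csv",
    "write_weather_csv",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_agb_observations_csv",
    "write_agb_observations_csv",
    "read_soil",
    "write_soil",
    "read_management",
    "write_management",
    "read_parameter_specs",
    "write_parameter_specs",
    "read_raster_csv",
    "write_raster_csv",
]


class ParseError(ValueError):
    """Schema violation carrying the file and 1-based line number."""

    def __init__(self, path: Any, line: int | None, message: str):
        self.path = str(path)
        self.line = line
        where = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{where}: {message}")


def _parse_date(value: str, path: Any, line: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value.strip())
    except ValueError:
        raise ParseError(path, line, f"invalid ISO-8601 date {value!r}") from None


def _parse_float(value: str, field: str, path: Any, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(path, line, f"invalid number for {field}: {value!r}") from None


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def read_weather_csv(path: str | Path, latitude: float = 39.5) -> WeatherSeries:
    """Columns: date, tmax, tmin, precip, and sunshine_hours or srad."""
    path = Path(path)
    days: list[WeatherDay] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(path, 1, "empty file")
        cols = set(reader.fieldnames)
        required = {"date", "tmax", "tmin", "precip"}
        missing = required - cols
        if missing:
            raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
        if not ({"sunshine_hours", "srad"} & cols):
            raise ParseError(path, 1, "need a sunshine_hours or srad column")
        for i, row in enumerate(reader, start=2):
            try:
                day = WeatherDay(
                    date=_parse_date(row["date"], path, i),
                    tmax=_parse_float(row["tmax"], "tmax", path, i),
                    tmin=_parse_float(row["tmin"], "tmin", path, i),
                    precip=_parse_float(row["precip"], "precip", path, i),
                    sunshine_hours=(
                        _parse_float(row["sunshine_hours"], "sunshine_hours", path, i)
                        if row.get("sunshine_hours") not in (None, "")
                        else None
                    ),
                    srad=(
                        _parse_float(row["srad"], "srad", path, i)
                        if row.get("srad") not in (None, "")
                        else None
                    ),
                )
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(path, i, str(exc)) from None
            days.append(day)
    try:
        return WeatherSeries(days, latitude=latitude)
    except ValueError as exc:
        raise ParseError(path, None, str(exc)) from None


def write_weather_csv(path: str | Path, weather: WeatherSeries) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["date", "tmax", "tmin", "precip", "sunshine_hours", "srad"])
        for day in weather.days:
            w.writerow(
                [
                    day.date.isoformat(),
                    repr(day.tmax),
                    repr(day.tmin),
                    repr(day.precip),
                    "" if day.sunshine_hours is None else repr(day.sunshine_hours),
                    "" if day.srad is None else repr(day.srad),
                ]
            )


# ---------------------------------------------------------------------------
# spectral and AGB observations
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | Path) -> list[SpectralSample]:
    """Columns: plot_id, date, nir, red, gdd, agb_measured (optional)."""
    path = Path(path)
    out: list[SpectralSample] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(path, 1, "empty file")
        missing = {"plot_id", "date", "nir", "red", "gdd"} - set(reader.fieldnames)
        if missing:
            raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            agb = row.get("agb_measured")
            try:
                out.append(
                    SpectralSample(
                        plot_id=row["plot_id"],
                        date=_parse_date(row["date"], path, i),
                        nir=_parse_float(row["nir"], "nir", path, i),
                        red=_parse_float(row["red"], "red", path, i),
                        gdd=_parse_float(row["gdd"], "gdd", path, i),
                        agb_measured=(
                            _parse_float(agb, "agb_measured", path, i)
                            if agb not in (None, "")
                            else None
                        ),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(path, i, str(exc)) from None
    return out


def write_spectra_csv(path: str | Path, samples: Sequence[SpectralSample]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plot_id", "date", "nir", "red", "gdd", "agb_measured"])
        for s in samples:
            w.writerow(
                [
                    s.plot_id,
                    s.date.isoformat(),
                    repr(s.nir),
                    repr(s.red),
                    repr(s.gdd),
                    "" if s.agb_measured is None else repr(s.agb_measured),
                ]
            )


def read_agb_observations_csv(path: str | Path) -> dict[str, list[tuple[dt.date, float]]]:
    """Columns: plot_id, date, agb (t/ha); grouped by plot."""
    path = Path(path)
    out: dict[str, list[tuple[dt.date, float]]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError(path, 1, "empty file")
        missing = {"plot_id", "date", "agb"} - set(reader.fieldnames)
        if missing:
            raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            date = _parse_date(row["date"], path, i)
            agb = _parse_float(row["agb"], "agb", path, i)
            out.setdefault(row["plot_id"], []).append((date, agb))
    return out


def write_agb_observations_csv(
    path: str | Path, obs: dict[str, list[tuple[dt.date, float]]]
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plot_id", "date", "agb"])
        for plot_id, rows in obs.items():
            for date, agb in rows:
                w.writerow([plot_id, date.isoformat(), repr(agb)])


# ---------------------------------------------------------------------------
# soil / management / parameter configs (YAML or JSON)
# ---------------------------------------------------------------------------

def _load_config(path: str | Path) -> Any:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_soil(path: str | Path) -> SoilInit:
    data = _load_config(path)
    if not isinstance(data, dict):
        raise ParseError(path, None, "expected a mapping of soil fields")
    try:
        return SoilInit(**data)
    except (TypeError, ValueError) as exc:
        raise ParseError(path, None, str(exc)) from None


def write_soil(path: str | Path, soil: SoilInit) -> None:
    data = {
        "no3_n": soil.no3_n,
        "nh4_n": soil.nh4_n,
        "organic_matter": soil.organic_matter,
        "water_holding_capacity": soil.water_holding_capacity,
        "initial_water": soil.initial_water,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_management(path: str | Path) -> ManagementPlan:
    data = _load_config(path)
    if not isinstance(data, dict) or "sowing_date" not in data:
        raise ParseError(path, None, "expected a mapping with a sowing_date field")
    try:
        sowing = dt.date.fromisoformat(str(data["sowing_date"]))
        irr = tuple(
            IrrigationEvent(dt.date.fromisoformat(str(e["date"])), float(e["amount_mm"]))
            for e in data.get("irrigation_events", [])
        )
        fert = tuple(
            FertilizationEvent(
                dt.date.fromisoformat(str(e["date"])),
                float(e["amount_kg_ha"]),
                bool(e.get("topdress", False)),
            )
            for e in data.get("fertilization_events", [])
        )
        return ManagementPlan(
            sowing_date=sowing,
            plant_density=float(data.get("plant_density", 350.0)),
            irrigation_events=irr,
            fertilization_events=fert,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(path, None, f"invalid management plan: {exc}") from None


def write_management(path: str | Path, mgmt: ManagementPlan) -> None:
    data = {
        "sowing_date": mgmt.sowing_date.isoformat(),
        "plant_density": mgmt.plant_density,
        "irrigation_events": [
            {"date": e.date.isoformat(), "amount_mm": e.amount_mm}
            for e in mgmt.irrigation_events
        ],
        "fertilization_events": [
            {"date": e.date.isoformat(), "amount_kg_ha": e.amount_kg_ha, "topdress": e.topdress}
            for e in mgmt.fertilization_events
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_parameter_specs(path: str | Path) -> list[ParameterSpec]:
    data = _load_config(path)
    if not isinstance(data, list):
        raise ParseError(path, None, "expected a list of parameter specs")
    specs = []
    for entry in data:
        try:
            specs.append(
                ParameterSpec(
                    name=str(entry["name"]),
                    initial_value=float(entry["initial_value"]),
                    lower_bound=float(entry["lower_bound"]),
                    upper_bound=float(entry["upper_bound"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(path, None, f"invalid parameter spec {entry!r}: {exc}") from None
    return specs


def write_parameter_specs(path: str | Path, specs: Sequence[ParameterSpec]) -> None:
    data = [
        {
            "name": s.name,
            "initial_value": s.initial_value,
            "lower_bound": s.lower_bound,
            "upper_bound": s.upper_bound,
        }
        for s in specs
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# plain-text rasters (row-major, origin top-left; empty cell = masked)
# ---------------------------------------------------------------------------

def read_raster_csv(path: str | Path) -> np.ndarray:
    """Numeric matrix with empty cells read as NaN (mask)."""
    path = Path(path)
    rows: list[list[float]] = []
    with path.open(newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            vals = []
            for j, cell in enumerate(row):
                cell = cell.strip()
                if cell == "" or cell.lower() == "nan":
                    vals.append(np.nan)
                else:
                    vals.append(_parse_float(cell, f"column {j + 1}", path, i))
            rows.append(vals)
    if not rows:
        raise ParseError(path, 1, "empty raster")
    width = len(rows[0])
    for i, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ParseError(path, i, f"ragged row: {len(r)} cells, expected {width}")
    return np.array(rows, dtype=float)


def write_raster_csv(path: str | Path, raster: np.ndarray) -> None:
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ValueError("raster must be 2-D")
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        for row in raster:
            w.writerow(["" if np.isnan(v) else repr(float(v)) for v in row])
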