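"""Daily process-based winter-wheat growth surrogate.

A deliberately small stand-in for a full cropping-systems model, exposing
exactly the seven tunable quantities the assimilation step re-estimates:
four genotype traits (photoperiod sensitivity, phyllochron interval, root
depth growth rate, photosynthesis factor) and three management quantities
(plant density, seasonal irrigation, seasonal fertilizer N).

The surrogate combines four textbook components:

* phenology driven by photoperiod-modulated growing degree days,
* radiation-use-efficiency growth with Beer's-law canopy interception,
* a single-layer soil water bucket with a growing rooting front,
* a mineral-N pool with demand from a critical N dilution curve.

All empirical constants live in :data:`CONSTANTS` so an adapter wrapping a
different crop model can replace this module wholesale behind
:class:`CropModel`.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "CONSTANTS",
    "STAGE_THRESHOLDS",
    "WeatherDay",
    "WeatherSeries",
    "SoilInit",
    "FertilizationEvent",
    "IrrigationEvent",
    "ManagementPlan",
    "CultivarParams",
    "Stage",
    "SimulationOutput",
    "CropModel",
    "SurrogateWheatModel",
    "growing_degree_days",
    "solar_radiation_angstrom",
    "daylength_hours",
    "extraterrestrial_radiation",
    "simulate_season",
    "get_model",
    "register_model",
]

#: Empirical constants of the surrogate (one table so a different crop model
#: can be substituted behind the same interface).
CONSTANTS = {
    "tbase": 0.0,               # GDD base temperature, degC
    "k_extinction": 0.5,        # Beer's-law canopy extinction coefficient
    "rue": 3.0,                 # radiation use efficiency, g DM per MJ PAR
    "par_fraction": 0.48,       # PAR fraction of global radiation
    "temp_opt": 14.0,           # degC mean temp at which growth is unlimited
    "crit_n_a": 5.35,           # critical N dilution curve coefficient, % N
    "crit_n_b": 0.442,          # critical N dilution curve exponent
    "harvest_index": 0.45,      # potential harvest index (dry basis)
    "hi_stress_floor": 0.55,    # fraction of HI retained under full grain-fill stress
    "bulk_density": 1.3,        # t m-3, 0-30 cm layer
    "layer_depth_m": 0.30,      # depth of the initial mineral-N accounting layer
    "lai_per_tha": 1.4,         # m2 m-2 of green leaf area per t/ha AGB (pre-senescence)
    "lai_max": 7.0,             # cap on leaf area index
    "transp_efficiency": 55.0,  # kg DM per ha per mm transpired
    "water_extract_frac": 0.12, # daily extractable fraction of root-zone water
    "n_extract_frac": 0.12,     # daily extractable fraction of the mineral-N pool
    "n_stress_exponent": 2.0,   # curvature of the N factor's effect on growth
    "soil_evap_mm": 0.6,        # daily bare-soil evaporation, mm
    "root_depth_max_cm": 100.0, # maximum rooting depth
    "root_depth_init_cm": 10.0, # rooting depth at emergence
    "emergence_agb": 0.08,      # t/ha AGB assigned at emergence (350 plants m-2)
    "photoperiod_crit_h": 12.5, # daylength below which development slows
    "photoperiod_slope": 0.004, # slowdown per unit p1d per hour of deficit
    "moisture_factor_14pct": 1.0 / 0.86,  # optional fresh-weight yield scaling
}

#: Cumulative development-GDD thresholds (degC d) at phint = 100; the
#: thresholds scale linearly with phint / 100.
STAGE_THRESHOLDS = {
    "emergence": 100.0,
    "jointing": 500.0,
    "anthesis": 900.0,
    "maturity": 1600.0,
}

#: Conversion from mg N per kg soil to kg N per ha for the 0-30 cm layer.
MGKG_TO_KGHA = CONSTANTS["bulk_density"] * 1000.0 * CONSTANTS["layer_depth_m"] * 10000.0 * 1e-6


class Stage(IntEnum):
    """Enumerated phenophase of the daily loop."""

    SOWN = 0
    EMERGED = 1
    JOINTING = 2
    ANTHESIS = 3
    MATURE = 4


# ---------------------------------------------------------------------------
# weather primitives
# ---------------------------------------------------------------------------

def growing_degree_days(tmax: float, tmin: float, tbase: float = CONSTANTS["tbase"]) -> float:
    """Daily growing-degree-day increment ``max(0, (tmax+tmin)/2 - tbase)``.

    Raises
    ------
    ValueError
        If ``tmax < tmin``.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    return max(0.0, 0.5 * (tmax + tmin) - tbase)


def solar_radiation_angstrom(
    sunshine_hours: float,
    daylength: float,
    extraterrestrial_radiation: float,
    a: float = 0.25,
    b: float = 0.50,
) -> float:
    """Angstrom-Prescott estimate of global radiation from sunshine duration.

    Returns ``(a + b * s/S) * Ra`` in the units of ``extraterrestrial_radiation``.
    """
    if daylength <= 0:
        raise ValueError("daylength must be positive")
    if sunshine_hours < 0 or sunshine_hours > daylength + 1e-9:
        raise ValueError(
            f"sunshine_hours ({sunshine_hours}) outside [0, daylength={daylength}]"
        )
    return (a + b * sunshine_hours / daylength) * extraterrestrial_radiation


def _solar_geometry(doy: np.ndarray, latitude_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Daylength (h) and extraterrestrial radiation (MJ m-2 d-1), FAO-56 style."""
    lat = math.radians(latitude_deg)
    doy = np.asarray(doy, dtype=float)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)
    daylen = 24.0 / np.pi * ws
    gsc = 0.0820  # MJ m-2 min-1
    ra = (24.0 * 60.0 / np.pi) * gsc * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    return daylen, np.maximum(ra, 0.0)


def daylength_hours(doy: int | np.ndarray, latitude_deg: float) -> float | np.ndarray:
    """Astronomical daylength in hours for a day of year and latitude."""
    d, _ = _solar_geometry(np.atleast_1d(doy), latitude_deg)
    return float(d[0]) if np.isscalar(doy) or np.ndim(doy) == 0 else d


def extraterrestrial_radiation(doy: int | np.ndarray, latitude_deg: float) -> float | np.ndarray:
    """Top-of-atmosphere radiation in MJ m-2 d-1."""
    _, ra = _solar_geometry(np.atleast_1d(doy), latitude_deg)
    return float(ra[0]) if np.isscalar(doy) or np.ndim(doy) == 0 else ra


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological drivers."""

    date: dt.date
    tmax: float
    tmin: float
    precip: float
    sunshine_hours: float | None = None
    srad: float | None = None

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})")
        if self.precip < 0:
            raise ValueError(f"{self.date}: negative precipitation")
        if self.sunshine_hours is None and self.srad is None:
            raise ValueError(f"{self.date}: need sunshine_hours or srad")
        if self.sunshine_hours is not None and self.sunshine_hours < 0:
            raise ValueError(f"{self.date}: negative sunshine_hours")


class WeatherSeries:
    """A gap-free daily weather record plus site latitude.

    Parameters
    ----------
    days
        Consecutive :class:`WeatherDay` records (one per calendar day).
    latitude
        Site latitude in decimal degrees, used for daylength and
        extraterrestrial radiation when converting sunshine duration to
        global radiation.
    """

    def __init__(self, days: Sequence[WeatherDay], latitude: float = 39.5):
        days = list(days)
        if not days:
            raise ValueError("empty weather series")
        for prev, cur in zip(days, days[1:]):
            delta = (cur.date - prev.date).days
            if delta != 1:
                raise ValueError(
                    f"weather gap: {prev.date} followed by {cur.date} (expected next day)"
                )
        self.days = days
        self.latitude = float(latitude)
        self.dates = [d.date for d in days]
        self.tmax = np.array([d.tmax for d in days])
        self.tmin = np.array([d.tmin for d in days])
        self.precip = np.array([d.precip for d in days])
        doy = np.array([d.date.timetuple().tm_yday for d in days])
        self.daylength, self._ra = _solar_geometry(doy, self.latitude)
        srad = np.empty(len(days))
        for i, d in enumerate(days):
            if d.srad is not None:
                srad[i] = d.srad
            else:
                s = min(d.sunshine_hours, self.daylength[i])
                srad[i] = solar_radiation_angstrom(s, self.daylength[i], self._ra[i])
        self.srad = srad

    def __len__(self) -> int:
        return len(self.days)

    @property
    def start(self) -> dt.date:
        return self.dates[0]

    @property
    def end(self) -> dt.date:
        return self.dates[-1]

    def index_of(self, date: dt.date) -> int:
        i = (date - self.start).days
        if i < 0 or i >= len(self.days):
            raise KeyError(f"date {date} outside weather record {self.start}..{self.end}")
        return i


@dataclass(frozen=True)
class SoilInit:
    """Initial soil state of the 0-30 cm layer."""

    no3_n: float = 10.0            # mg kg-1
    nh4_n: float = 5.0             # mg kg-1
    organic_matter: float = 12.0   # g kg-1 (held for provenance; not cycled)
    water_holding_capacity: float = 180.0  # mm plant-available at field capacity
    initial_water: float = 140.0   # mm

    def __post_init__(self) -> None:
        for name in ("no3_n", "nh4_n", "organic_matter", "water_holding_capacity", "initial_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.initial_water > self.water_holding_capacity + 1e-9:
            raise ValueError("initial_water exceeds water_holding_capacity")

    @property
    def mineral_n_kg_ha(self) -> float:
        """Initial mineral N pool converted from mg kg-1 to kg ha-1 (0-30 cm)."""
        return (self.no3_n + self.nh4_n) * MGKG_TO_KGHA


@dataclass(frozen=True)
class IrrigationEvent:
    date: dt.date
    amount_mm: float

    def __post_init__(self) -> None:
        if self.amount_mm < 0:
            raise ValueError("negative irrigation amount")


@dataclass(frozen=True)
class FertilizationEvent:
    """A dated N application; ``topdress=True`` marks the jointing-stage event
    that the recommendation step varies."""

    date: dt.date
    amount_kg_ha: float
    topdress: bool = False

    def __post_init__(self) -> None:
        if self.amount_kg_ha < 0:
            raise ValueError("negative fertilization amount")


@dataclass(frozen=True)
class ManagementPlan:
    sowing_date: dt.date
    plant_density: float = 350.0   # plants m-2
    irrigation_events: tuple[IrrigationEvent, ...] = ()
    fertilization_events: tuple[FertilizationEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.plant_density <= 0:
            raise ValueError("plant_density must be positive")
        object.__setattr__(self, "irrigation_events", tuple(self.irrigation_events))
        object.__setattr__(self, "fertilization_events", tuple(self.fertilization_events))

    @property
    def total_irrigation(self) -> float:
        return sum(e.amount_mm for e in self.irrigation_events)

    @property
    def total_fertilization(self) -> float:
        return sum(e.amount_kg_ha for e in self.fertilization_events)

    def scaled_irrigation(self, total_mm: float) -> "ManagementPlan":
        """Return a plan whose irrigation events are rescaled to ``total_mm``,
        preserving dates and proportions (a single mid-season event is created
        when the plan has none)."""
        if total_mm < 0:
            raise ValueError("negative irrigation total")
        cur = self.total_irrigation
        if cur > 0:
            events = tuple(
                IrrigationEvent(e.date, e.amount_mm * total_mm / cur)
                for e in self.irrigation_events
            )
        elif total_mm > 0:
            events = (IrrigationEvent(self.sowing_date + dt.timedelta(days=150), total_mm),)
        else:
            events = ()
        return replace(self, irrigation_events=events)

    def scaled_fertilization(self, total_kg_ha: float) -> "ManagementPlan":
        """Rescale fertilization events to a seasonal total, preserving splits."""
        if total_kg_ha < 0:
            raise ValueError("negative fertilization total")
        cur = self.total_fertilization
        if cur > 0:
            events = tuple(
                FertilizationEvent(e.date, e.amount_kg_ha * total_kg_ha / cur, e.topdress)
                for e in self.fertilization_events
            )
        elif total_kg_ha > 0:
            events = (FertilizationEvent(self.sowing_date, total_kg_ha),)
        else:
            events = ()
        return replace(self, fertilization_events=events)

    def with_topdressing(self, amount_kg_ha: float, date: dt.date) -> "ManagementPlan":
        """Replace any topdressing events with a single event of the given
        amount at ``date`` (typically the simulated jointing date)."""
        kept = tuple(e for e in self.fertilization_events if not e.topdress)
        events = kept + (FertilizationEvent(date, amount_kg_ha, topdress=True),)
        return replace(self, fertilization_events=events)


#: (name, initial, lower, upper) for the seven assimilated quantities.
PARAMETER_TABLE = (
    ("plant_density", 350.0, 300.0, 400.0),
    ("irrigation", 150.0, 90.0, 240.0),
    ("fertilization", 200.0, 0.0, 400.0),
    ("p1d", 50.0, 30.0, 70.0),
    ("phint", 100.0, 90.0, 120.0),
    ("rdgs", 3.0, 2.5, 3.5),
    ("slpf", 1.0, 0.8, 1.0),
)

_CULTIVAR_BOUNDS = {name: (lo, hi) for name, _, lo, hi in PARAMETER_TABLE if name in
                    ("p1d", "phint", "rdgs", "slpf")}


@dataclass(frozen=True)
class CultivarParams:
    """Four genotype traits re-estimated by the assimilation step."""

    p1d: float = 50.0    # photoperiod sensitivity, dimensionless
    phint: float = 100.0 # phyllochron interval (scales phenology thresholds)
    rdgs: float = 3.0    # root depth growth rate, cm d-1
    slpf: float = 1.0    # photosynthesis / soil fertility factor

    def validated(self, clamp: bool = False) -> "CultivarParams":
        """Check each trait against its calibration range.

        ``clamp=True`` (assimilation mode) silently clips out-of-range values;
        otherwise a :class:`ValueError` is raised.
        """
        values = {}
        for name, (lo, hi) in _CULTIVAR_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                if not clamp:
                    raise ValueError(f"cultivar parameter {name}={v} outside [{lo}, {hi}]")
                v = min(max(v, lo), hi)
            values[name] = v
        return CultivarParams(**values)


@dataclass
class SimulationOutput:
    """Daily trajectory and end-of-season summary of one run."""

    dates: list[dt.date]
    daily_gdd: np.ndarray          # cumulative degC d from sowing
    daily_agb: np.ndarray          # t ha-1, non-decreasing
    daily_stage: np.ndarray        # Stage codes
    yield_t_ha: float              # dry-basis grain yield
    n_stress: np.ndarray           # daily N factor in [0, 1] (1 = no stress)
    water_stress: np.ndarray       # daily water factor in [0, 1]
    n_uptake_kg_ha: float = 0.0
    stage_dates: dict[str, dt.date] = field(default_factory=dict)

    @property
    def final_agb(self) -> float:
        return float(self.daily_agb[-1])

    def agb_on(self, date: dt.date) -> float:
        i = (date - self.dates[0]).days
        if i < 0 or i >= len(self.dates):
            raise KeyError(f"date {date} outside simulated season")
        return float(self.daily_agb[i])

    def gdd_on(self, date: dt.date) -> float:
        i = (date - self.dates[0]).days
        if i < 0 or i >= len(self.dates):
            raise KeyError(f"date {date} outside simulated season")
        return float(self.daily_gdd[i])

    @property
    def jointing_date(self) -> dt.date:
        return self.stage_dates["jointing"]

    def yield_at_14pct_moisture(self) -> float:
        """Optional fresh-weight equivalence of the dry-basis yield."""
        return self.yield_t_ha * CONSTANTS["moisture_factor_14pct"]


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class CropModel(Protocol):
    """Contract any crop model adapter must satisfy."""

    def simulate(
        self,
        weather: WeatherSeries,
        soil: SoilInit,
        mgmt: ManagementPlan,
        cultivar: CultivarParams,
        clamp_params: bool = False,
    ) -> SimulationOutput: ...


def _critical_n_percent(agb_t_ha: float) -> float:
    """Critical N concentration (% of dry mass) from the dilution power law,
    with a plateau below 1 t/ha where dilution has not begun."""
    if agb_t_ha <= 1.0:
        return CONSTANTS["crit_n_a"]
    return CONSTANTS["crit_n_a"] * agb_t_ha ** (-CONSTANTS["crit_n_b"])


def simulate_season(
    weather: WeatherSeries,
    soil: SoilInit,
    mgmt: ManagementPlan,
    cultivar: CultivarParams | None = None,
    clamp_params: bool = False,
) -> SimulationOutput:
    """Run the daily loop from sowing to maturity (or end of weather).

    The loop per day: accumulate GDD; advance phenophase on
    photoperiod-modulated GDD thresholds scaled by ``phint``; compute
    potential growth from intercepted radiation and radiation-use
    efficiency; update the water bucket and mineral-N pool; reduce growth
    by ``min(water factor, N factor)``; finally yield = harvest index x
    final AGB, the index eroded by mean grain-fill stress.

    Parameters outside their calibration ranges raise ``ValueError`` unless
    ``clamp_params`` is set (assimilation mode), in which case they are
    clipped.
    """
    cultivar = (cultivar or CultivarParams()).validated(clamp=clamp_params)
    c = CONSTANTS

    try:
        start = weather.index_of(mgmt.sowing_date)
    except KeyError as exc:
        raise ValueError(f"sowing date not covered by weather: {exc}") from exc

    n_days = len(weather) - start
    dates = weather.dates[start:]
    tmax = weather.tmax[start:]
    tmin = weather.tmin[start:]
    precip = weather.precip[start:]
    srad = weather.srad[start:]
    daylen = weather.daylength[start:]

    # GDD and photoperiod-modulated development GDD, vectorised up front.
    gdd_daily = np.maximum(0.0, 0.5 * (tmax + tmin) - c["tbase"])
    gdd_cum = np.cumsum(gdd_daily)
    photo = np.maximum(
        0.35,
        1.0 - c["photoperiod_slope"] * cultivar.p1d
        * np.maximum(0.0, c["photoperiod_crit_h"] - daylen),
    )
    dev_cum = np.cumsum(gdd_daily * photo)
    scale = cultivar.phint / 100.0
    thresholds = {k: v * scale for k, v in STAGE_THRESHOLDS.items()}

    stage = np.full(n_days, int(Stage.SOWN), dtype=int)
    stage[dev_cum >= thresholds["emergence"]] = int(Stage.EMERGED)
    stage[dev_cum >= thresholds["jointing"]] = int(Stage.JOINTING)
    stage[dev_cum >= thresholds["anthesis"]] = int(Stage.ANTHESIS)
    stage[dev_cum >= thresholds["maturity"]] = int(Stage.MATURE)

    stage_dates: dict[str, dt.date] = {"sowing": mgmt.sowing_date}
    for name, code in (("emergence", Stage.EMERGED), ("jointing", Stage.JOINTING),
                       ("anthesis", Stage.ANTHESIS), ("maturity", Stage.MATURE)):
        hit = np.nonzero(stage >= int(code))[0]
        if hit.size:
            stage_dates[name] = dates[hit[0]]
    if "jointing" not in stage_dates:
        raise ValueError("weather record ends before the jointing stage is reached")

    # dated event lookups (day index -> amount)
    irrig = np.zeros(n_days)
    for ev in mgmt.irrigation_events:
        i = (ev.date - dates[0]).days
        if 0 <= i < n_days:
            irrig[i] += ev.amount_mm
    fert = np.zeros(n_days)
    for ev in mgmt.fertilization_events:
        i = (ev.date - dates[0]).days
        if 0 <= i < n_days:
            fert[i] += ev.amount_kg_ha

    density_factor = (mgmt.plant_density / 350.0) ** 0.3

    agb = 0.0            # kg ha-1
    plant_n = 0.0        # kg ha-1
    soil_water = float(soil.initial_water)
    mineral_n = soil.mineral_n_kg_ha
    root_depth = 0.0
    n_uptake_total = 0.0

    daily_agb = np.zeros(n_days)
    nf_arr = np.ones(n_days)
    wf_arr = np.ones(n_days)
    fill_stress: list[float] = []

    whc = soil.water_holding_capacity
    sen_span = thresholds["maturity"] - thresholds["anthesis"]

    for i in range(n_days):
        st = stage[i]
        soil_water = min(whc, soil_water + precip[i] + irrig[i])
        mineral_n += fert[i]

        if st == Stage.SOWN:
            soil_water = max(0.0, soil_water - min(c["soil_evap_mm"], soil_water))
            daily_agb[i] = agb / 1000.0
            continue
        if agb == 0.0:  # emergence day: seedling stand appears
            agb = c["emergence_agb"] * 1000.0 * (mgmt.plant_density / 350.0)
            plant_n = agb * _critical_n_percent(agb / 1000.0) / 100.0
            root_depth = c["root_depth_init_cm"]

        if st >= Stage.MATURE:
            daily_agb[i] = agb / 1000.0
            continue

        root_depth = min(c["root_depth_max_cm"], root_depth + cultivar.rdgs)

        # potential growth (kg DM ha-1 d-1)
        green = 1.0
        if st >= Stage.ANTHESIS:  # linear senescence of the canopy
            green = max(0.2, 1.0 - 0.8 * (dev_cum[i] - thresholds["anthesis"]) / sen_span)
        lai = min(c["lai_max"], c["lai_per_tha"] * (agb / 1000.0) * green * density_factor)
        fipar = 1.0 - math.exp(-c["k_extinction"] * lai)
        tf = min(1.0, max(0.0, 0.5 * (tmax[i] + tmin[i]) / c["temp_opt"]))
        pot_growth = (
            c["rue"] * c["par_fraction"] * fipar * srad[i] * tf * cultivar.slpf * 10.0
        )  # g m-2 -> kg ha-1

        # water supply / demand
        available = soil_water * (root_depth / c["root_depth_max_cm"])
        supply_mm = c["water_extract_frac"] * available
        demand_mm = pot_growth / c["transp_efficiency"]
        wf = 1.0 if demand_mm <= 0 else min(1.0, supply_mm / demand_mm)

        # N uptake against the critical dilution demand
        crit_pct = _critical_n_percent((agb + pot_growth) / 1000.0)
        demand_n = max(0.0, (agb + pot_growth) * crit_pct / 100.0 - plant_n)
        uptake = min(demand_n, c["n_extract_frac"] * mineral_n)
        mineral_n -= uptake
        plant_n += uptake
        n_uptake_total += uptake
        crit_now = agb * _critical_n_percent(agb / 1000.0) / 100.0
        nf = 1.0 if crit_now <= 0 else min(1.0, plant_n / crit_now)

        growth = pot_growth * min(wf, nf ** c["n_stress_exponent"])
        transp = min(growth / c["transp_efficiency"], available)
        soil_water = max(0.0, soil_water - transp)
        evap = min(c["soil_evap_mm"] * math.exp(-0.7 * lai), soil_water)
        soil_water -= evap

        agb += growth
        wf_arr[i] = wf
        nf_arr[i] = nf
        if st == Stage.ANTHESIS:
            # HI erosion tracks N status only; water limitation already acts
            # through daily growth (keeps yield monotone in applied N)
            fill_stress.append(nf)
        daily_agb[i] = agb / 1000.0

    hi = c["harvest_index"]
    if fill_stress:
        mean_stress = float(np.mean(fill_stress))
        hi *= c["hi_stress_floor"] + (1.0 - c["hi_stress_floor"]) * mean_stress
    yield_t_ha = hi * daily_agb[-1]

    return SimulationOutput(
        dates=dates,
        daily_gdd=gdd_cum,
        daily_agb=daily_agb,
        daily_stage=stage,
        yield_t_ha=float(yield_t_ha),
        n_stress=nf_arr,
        water_stress=wf_arr,
        n_uptake_kg_ha=float(n_uptake_total),
        stage_dates=stage_dates,
    )


class SurrogateWheatModel:
    """Default :class:`CropModel` implementation backed by :func:`simulate_season`."""

    name = "surrogate"

    def simulate(self, weather, soil, mgmt, cultivar=None, clamp_params=False):
        return simulate_season(weather, soil, mgmt, cultivar, clamp_params=clamp_params)


_MODEL_REGISTRY: dict[str, CropModel] = {"surrogate": SurrogateWheatModel()}


def register_model(name: str, model: CropModel) -> None:
    """Register an alternate crop model implementation for CLI selection."""
    _MODEL_REGISTRY[name] = model


def get_model(name: str = "surrogate") -> CropModel:
    try:
        return _MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown crop model {name!r}; known: {sorted(_MODEL_REGISTRY)}")
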