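"""Seeded synthetic weather, soils, field trials and spectral observations.

Everything the pipeline consumes can be generated here with the statistical
structure it assumes: a sinusoidal temperature climate with AR(1) anomalies,
Markov-chain rainfall with gamma amounts scaled into a plausible seasonal
total, plot-level soil heterogeneity, destructive-sampling biomass with
multiplicative noise, and reflectance pairs manufactured by inverting the
biomass monitoring model so the index round-trips to the simulated truth.

The reflectance inversion needs the monitoring model's GDD covariate on the
scale that makes the published coefficients produce plausible biomass; the
generator divides cumulative degree days by :data:`GDD_COVARIATE_SCALE`
(default 12 degC d per covariate unit) and emits that scaled covariate in
its observation tables, documented here rather than silently absorbed.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import agb as agb_mod
from .crop_model import (
    CultivarParams,
    FertilizationEvent,
    IrrigationEvent,
    ManagementPlan,
    SimulationOutput,
    SoilInit,
    WeatherDay,
    WeatherSeries,
    get_model,
)
from .recommendation import EconomicParams, economic_benefit

__all__ = [
    "GDD_COVARIATE_SCALE",
    "ClimateProfile",
    "BEIJING_LIKE",
    "ExperimentDesign",
    "NoiseModel",
    "PlotData",
    "AGBSample",
    "ExperimentData",
    "generate_weather",
    "default_soil",
    "default_management",
    "variety_cultivar",
    "generate_experiment",
    "generate_topdressing_trial",
]

#: degC d of cumulative GDD per unit of the monitoring model's covariate.
#: Chosen so the published coefficients yield positive slopes and physical
#: index values over the four sampled stages of the default fixture.
GDD_COVARIATE_SCALE = 16.0

#: red reflectance assigned to synthesised canopies before noise.
_BASE_RED_REFLECTANCE = 0.08

#: four sampled phenophases: stem elongation, flag leaf, flowering, grain fill
STAGE_NAMES = ("stem_elongation", "flag_leaf", "flowering", "grain_filling")


@dataclass(frozen=True)
class ClimateProfile:
    """Parameters of the weather generator (defaults: North-China-Plain-like)."""

    name: str = "beijing_like"
    tmean_annual: float = 12.5
    tamp: float = 14.5
    warmest_doy: int = 197
    diurnal_range: float = 9.0
    ar1_rho: float = 0.7
    ar1_sd: float = 2.0
    rain_p_wet_after_dry: float = 0.10
    rain_p_wet_after_wet: float = 0.45
    rain_gamma_shape: float = 0.7
    annual_precip_range: tuple[float, float] = (400.0, 620.0)
    sunshine_frac_mean: float = 0.62
    sunshine_frac_sd: float = 0.15
    latitude: float = 39.5


BEIJING_LIKE = ClimateProfile()


def generate_weather(
    season_start: dt.date,
    n_days: int,
    profile: ClimateProfile = BEIJING_LIKE,
    seed: int | None = 0,
) -> WeatherSeries:
    """Seeded daily weather: sinusoid + AR(1) temperatures, Markov/gamma rain
    scaled to a seasonal total inside the profile's annual range (pro-rated
    by season length), sunshine hours bounded by daylength."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    p = profile
    dates = [season_start + dt.timedelta(days=i) for i in range(n_days)]
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    tclim = p.tmean_annual + p.tamp * np.cos(2.0 * np.pi * (doy - p.warmest_doy) / 365.0)
    anom = np.empty(n_days)
    anom[0] = rng.normal(0.0, p.ar1_sd)
    eps = rng.normal(0.0, p.ar1_sd * math.sqrt(1.0 - p.ar1_rho**2), size=n_days)
    for i in range(1, n_days):
        anom[i] = p.ar1_rho * anom[i - 1] + eps[i]
    tmean = tclim + anom
    half = 0.5 * p.diurnal_range + np.maximum(0.2, rng.normal(0.0, 1.0, n_days) * 0.8)
    tmax = tmean + half
    tmin = tmean - half

    wet = np.zeros(n_days, dtype=bool)
    u = rng.uniform(size=n_days)
    wet[0] = u[0] < p.rain_p_wet_after_dry
    for i in range(1, n_days):
        prob = p.rain_p_wet_after_wet if wet[i - 1] else p.rain_p_wet_after_dry
        wet[i] = u[i] < prob
    amounts = np.where(wet, rng.gamma(p.rain_gamma_shape, 8.0, size=n_days), 0.0)
    lo, hi = p.annual_precip_range
    target = rng.uniform(lo, hi) * n_days / 365.0
    raw = amounts.sum()
    if raw > 0:
        amounts *= target / raw

    frac = np.clip(rng.normal(p.sunshine_frac_mean, p.sunshine_frac_sd, n_days), 0.0, 1.0)
    frac = np.where(wet, frac * 0.35, frac)

    from .crop_model import _solar_geometry  # daylength for sunshine bound

    daylen, _ = _solar_geometry(doy, p.latitude)
    sunshine = np.minimum(frac * daylen, daylen)

    days = [
        WeatherDay(
            date=dates[i],
            tmax=float(tmax[i]),
            tmin=float(tmin[i]),
            precip=float(amounts[i]),
            sunshine_hours=float(sunshine[i]),
        )
        for i in range(n_days)
    ]
    return WeatherSeries(days, latitude=p.latitude)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial N-response trial layout."""

    varieties: int = 2
    n_rates: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    replicates: int = 4
    stages_sampled: int = 4
    topdressing_fractions: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75, 1.00, 1.25)

    @property
    def n_plots(self) -> int:
        return self.varieties * len(self.n_rates) * self.replicates

    @property
    def n_samples(self) -> int:
        return self.n_plots * self.stages_sampled


@dataclass(frozen=True)
class NoiseModel:
    """Observation / heterogeneity noise levels (all off when zero)."""

    agb_obs_cv: float = 0.05
    reflectance_sd: float = 0.01
    soil_spatial_cv: float = 0.0

    def __post_init__(self) -> None:
        if min(self.agb_obs_cv, self.reflectance_sd, self.soil_spatial_cv) < 0:
            raise ValueError("noise levels must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


def default_soil() -> SoilInit:
    """Moderately N-poor loam so the trial's N treatments separate clearly."""
    return SoilInit(
        no3_n=11.0,
        nh4_n=5.0,
        organic_matter=12.0,
        water_holding_capacity=180.0,
        initial_water=150.0,
    )


def default_management(
    sowing_date: dt.date,
    n_rate: float,
    jointing_guess_days: int = 175,
    basal_fraction: float = 0.5,
) -> ManagementPlan:
    """Basal + jointing-topdress split of the seasonal N rate, two irrigations."""
    basal = n_rate * basal_fraction
    topdress = n_rate - basal
    fert = []
    if basal > 0:
        fert.append(FertilizationEvent(sowing_date, basal))
    if topdress > 0:
        fert.append(
            FertilizationEvent(
                sowing_date + dt.timedelta(days=jointing_guess_days), topdress, topdress=True
            )
        )
    irr = (
        IrrigationEvent(sowing_date + dt.timedelta(days=jointing_guess_days), 75.0),
        IrrigationEvent(sowing_date + dt.timedelta(days=jointing_guess_days + 40), 75.0),
    )
    return ManagementPlan(
        sowing_date=sowing_date,
        plant_density=350.0,
        irrigation_events=irr,
        fertilization_events=tuple(fert),
    )


def variety_cultivar(index: int) -> CultivarParams:
    """Two stock varieties differing in phenology pace and photoperiod response."""
    presets = (
        CultivarParams(p1d=45.0, phint=98.0, rdgs=3.0, slpf=1.0),
        CultivarParams(p1d=55.0, phint=106.0, rdgs=3.0, slpf=0.95),
    )
    return presets[index % len(presets)]


@dataclass
class PlotData:
    plot_id: str
    variety: int
    n_rate: float
    replicate: int
    soil: SoilInit
    mgmt: ManagementPlan
    cultivar: CultivarParams
    truth: SimulationOutput
    sampling_dates: list[dt.date]


@dataclass(frozen=True)
class AGBSample:
    plot_id: str
    stage: str
    date: dt.date
    agb_true: float
    agb_observed: float


@dataclass
class ExperimentData:
    design: ExperimentDesign
    weather: WeatherSeries
    plots: list[PlotData]
    agb_samples: list[AGBSample]
    spectra: list[agb_mod.SpectralSample]
    gdd_covariate_scale: float = GDD_COVARIATE_SCALE


def _sampling_dates(truth: SimulationOutput) -> list[dt.date]:
    """Four stage-anchored sampling dates: shortly after jointing, midway to
    anthesis, at flowering, and mid grain fill."""
    sd = truth.stage_dates
    jointing = sd["jointing"]
    anthesis = sd.get("anthesis", truth.dates[-1])
    maturity = sd.get("maturity", truth.dates[-1])
    dates = [
        jointing + dt.timedelta(days=8),
        jointing + (anthesis - jointing) / 2,
        anthesis + dt.timedelta(days=2),
        anthesis + (maturity - anthesis) / 2,
    ]
    last = truth.dates[-1]
    return [min(d, last) for d in dates]


def _synthesize_spectrum(
    agb_true: float,
    gdd_cov: float,
    rng: np.random.Generator,
    noise: NoiseModel,
) -> tuple[float, float]:
    """Reflectance pair whose index inverts the monitoring model at the truth."""
    coeffs = agb_mod.PUBLISHED_COEFFICIENTS
    b0, b1 = coeffs.level1(gdd_cov)
    if b1 <= 0:
        raise ValueError(
            f"monitoring-model slope non-positive at covariate {gdd_cov:.1f}; "
            "sampling stage too early for the published coefficient scale"
        )
    target = (agb_true - b0) / b1
    target = min(max(target, 0.02), 1.2)  # keep reflectances physical
    red = _BASE_RED_REFLECTANCE
    nir = agb_mod.evi2_to_nir(target, red)
    if noise.reflectance_sd > 0:
        nir += rng.normal(0.0, noise.reflectance_sd)
        red += rng.normal(0.0, noise.reflectance_sd * 0.5)
    nir = float(min(max(nir, 0.0), 1.0))
    red = float(min(max(red, 0.005), 1.0))
    return nir, red


def _perturb_soil(soil: SoilInit, cv: float, rng: np.random.Generator) -> SoilInit:
    if cv <= 0:
        return soil
    sigma = math.sqrt(math.log(1.0 + cv**2))
    f_n = float(rng.lognormal(-0.5 * sigma**2, sigma))
    f_w = float(rng.lognormal(-0.5 * sigma**2, sigma))
    whc = soil.water_holding_capacity * f_w
    return replace(
        soil,
        no3_n=soil.no3_n * f_n,
        nh4_n=soil.nh4_n * f_n,
        water_holding_capacity=whc,
        initial_water=min(soil.initial_water * f_w, whc),
    )


def generate_experiment(
    design: ExperimentDesign | None = None,
    weather: WeatherSeries | None = None,
    soil: SoilInit | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sowing_date: dt.date | None = None,
    model_name: str = "surrogate",
) -> ExperimentData:
    """Run the factorial trial and emit truth plus noisy observations.

    Per plot: soil perturbed by the spatial heterogeneity CV, the growth
    surrogate run for the plot's treatment, biomass sampled at the four
    stage dates with multiplicative noise, and a reflectance pair per sample
    manufactured so the index -> biomass round-trip approximates the truth.
    """
    design = design or ExperimentDesign()
    noise = noise or NoiseModel()
    soil = soil or default_soil()
    rng = np.random.default_rng(seed)
    if weather is None:
        sowing_date = sowing_date or dt.date(2020, 10, 5)
        weather = generate_weather(sowing_date - dt.timedelta(days=3), 275, seed=seed)
    else:
        sowing_date = sowing_date or weather.start
    model = get_model(model_name)

    plots: list[PlotData] = []
    samples: list[AGBSample] = []
    spectra: list[agb_mod.SpectralSample] = []
    for vi in range(design.varieties):
        cultivar = variety_cultivar(vi)
        for n_rate in design.n_rates:
            for rep in range(design.replicates):
                plot_id = f"V{vi + 1}N{int(n_rate)}R{rep + 1}"
                plot_soil = _perturb_soil(soil, noise.soil_spatial_cv, rng)
                mgmt = default_management(sowing_date, n_rate)
                truth = model.simulate(weather, plot_soil, mgmt, cultivar)
                dates = _sampling_dates(truth)[: design.stages_sampled]
                plots.append(
                    PlotData(plot_id, vi, n_rate, rep, plot_soil, mgmt, cultivar, truth, dates)
                )
                for stage, date in zip(STAGE_NAMES, dates):
                    agb_true = truth.agb_on(date)
                    mult = 1.0 + (rng.normal(0.0, noise.agb_obs_cv) if noise.agb_obs_cv else 0.0)
                    observed = max(0.0, agb_true * mult)
                    samples.append(AGBSample(plot_id, stage, date, agb_true, observed))
                    gdd_cov = truth.gdd_on(date) / GDD_COVARIATE_SCALE
                    nir, red = _synthesize_spectrum(agb_true, gdd_cov, rng, noise)
                    spectra.append(
                        agb_mod.SpectralSample(
                            plot_id=plot_id,
                            date=date,
                            nir=nir,
                            red=red,
                            gdd=gdd_cov,
                            agb_measured=observed,
                        )
                    )
    return ExperimentData(design, weather, plots, samples, spectra)


@dataclass(frozen=True)
class TopdressingOutcome:
    plot_id: str
    fraction: float
    n_applied: float      # kg N ha-1 at jointing
    yield_t_ha: float
    benefit: float        # CNY ha-1, counting only the topdressed N


def generate_topdressing_trial(
    recommended_n: dict[str, float],
    plots: Sequence[PlotData],
    weather: WeatherSeries,
    fractions: Sequence[float] = (0.0, 0.25, 0.50, 0.75, 1.00, 1.25),
    prices: EconomicParams | None = None,
    model_name: str = "surrogate",
) -> list[TopdressingOutcome]:
    """Apply fractions of each plot's recommended rate at jointing and report
    yield and economics per treatment."""
    prices = prices or EconomicParams()
    model = get_model(model_name)
    out: list[TopdressingOutcome] = []
    for plot in plots:
        rec = recommended_n[plot.plot_id]
        jointing = plot.truth.jointing_date
        for frac in fractions:
            amount = rec * frac
            plan = plot.mgmt.with_topdressing(amount, jointing)
            sim = model.simulate(weather, plot.soil, plan, plot.cultivar)
            benefit = economic_benefit(sim.yield_t_ha * 1000.0, amount, prices)
            out.append(
                TopdressingOutcome(plot.plot_id, frac, amount, sim.yield_t_ha, benefit)
            )
    return out
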