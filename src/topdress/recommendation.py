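"""Economic target-yield nitrogen topdressing recommendation.

Given an assimilated crop model, the recommender sweeps the jointing-stage
topdressing rate over a grid, computes net economic benefit
``E = Y * P_Y - N * P_N`` for each rate, takes the target yield to be the
yield at the benefit-maximising rate, and recommends the lowest grid rate
whose yield meets that target (on a monotone response curve the two rates
coincide; both are reported so users can audit).

A fitted power-law reference curve mapping jointing-stage biomass directly
to a recommended rate is provided as a lightweight alternative for gridded
(map) use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .crop_model import (
    CropModel,
    CultivarParams,
    ManagementPlan,
    SoilInit,
    WeatherSeries,
)

__all__ = [
    "EconomicParams",
    "NSearchGrid",
    "ResponsePoint",
    "RecommendationResult",
    "PowerLawCurve",
    "PUBLISHED_REFERENCE_CURVE",
    "economic_benefit",
    "yield_response_curve",
    "economic_optimum",
    "recommend_n",
    "recommend_from_model",
    "reference_curve_predict",
    "fit_reference_curve",
]


@dataclass(frozen=True)
class EconomicParams:
    """Grain and fertilizer prices (CNY per kg)."""

    grain_price: float = 2.4
    n_price: float = 2.75

    def __post_init__(self) -> None:
        if self.grain_price <= 0 or self.n_price <= 0:
            raise ValueError("prices must be positive")


@dataclass(frozen=True)
class NSearchGrid:
    """Topdressing search grid in kg N per ha."""

    n_min: float = 0.0
    n_max: float = 360.0
    step: float = 10.0

    def __post_init__(self) -> None:
        if self.n_min > self.n_max:
            raise ValueError("n_min > n_max")
        if self.step <= 0:
            raise ValueError("step must be positive")

    def rates(self) -> np.ndarray:
        n = int(math.floor((self.n_max - self.n_min) / self.step)) + 1
        return self.n_min + self.step * np.arange(n)


@dataclass(frozen=True)
class ResponsePoint:
    n_rate: float        # kg N ha-1
    yield_kg_ha: float
    benefit: float       # CNY ha-1


@dataclass(frozen=True)
class RecommendationResult:
    response_curve: tuple[ResponsePoint, ...]
    n_economic_optimum: float
    target_yield: float           # kg ha-1
    n_recommended: float
    infeasible: bool = False


@dataclass(frozen=True)
class PowerLawCurve:
    """``N = a * AGB^b`` with AGB in t/ha at jointing and N in kg/ha."""

    a: float = 92.61
    b: float = -0.88

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("coefficient a must be positive")
        if self.b >= 0:
            raise ValueError("exponent b must be negative")


PUBLISHED_REFERENCE_CURVE = PowerLawCurve()


def economic_benefit(yield_kg_ha: float, n_rate: float, prices: EconomicParams | None = None) -> float:
    """Net benefit ``Y * P_Y - N * P_N`` in CNY per ha."""
    prices = prices or EconomicParams()
    if yield_kg_ha < 0 or n_rate < 0:
        raise ValueError("yield and N rate must be non-negative")
    return yield_kg_ha * prices.grain_price - n_rate * prices.n_price


def yield_response_curve(
    model: CropModel,
    mgmt: ManagementPlan,
    soil: SoilInit,
    weather: WeatherSeries,
    cultivar: CultivarParams | None = None,
    grid: NSearchGrid | None = None,
    prices: EconomicParams | None = None,
) -> tuple[ResponsePoint, ...]:
    """One simulation per grid rate, varying only the jointing topdressing.

    The jointing date is taken from a probe run of the supplied plan; every
    grid run replaces the plan's topdressing events with a single event of
    the grid amount on that date.
    """
    grid = grid or NSearchGrid()
    prices = prices or EconomicParams()
    cultivar = cultivar or CultivarParams()
    probe = model.simulate(weather, soil, mgmt, cultivar, clamp_params=True)
    jointing = probe.jointing_date
    points = []
    for n in grid.rates():
        plan = mgmt.with_topdressing(float(n), jointing)
        try:
            sim = model.simulate(weather, soil, plan, cultivar, clamp_params=True)
        except Exception as exc:
            raise RuntimeError(f"simulation failed at N = {n} kg/ha: {exc}") from exc
        y = sim.yield_t_ha * 1000.0  # kg ha-1
        points.append(ResponsePoint(float(n), y, economic_benefit(y, float(n), prices)))
    return tuple(points)


def economic_optimum(curve: Sequence[ResponsePoint]) -> tuple[float, float]:
    """Grid rate maximising net benefit (lowest rate on ties) and its yield."""
    if not curve:
        raise ValueError("empty response curve")
    best = curve[0]
    for pt in curve[1:]:
        if pt.benefit > best.benefit:  # strict: ties keep the lower rate
            best = pt
    return best.n_rate, best.yield_kg_ha


def recommend_n(curve: Sequence[ResponsePoint], target_yield: float) -> tuple[float, bool]:
    """Smallest grid rate whose yield meets the target.

    Returns ``(rate, infeasible)``; when no rate attains the target the rate
    of maximum yield is returned with the infeasible flag set.
    """
    if not curve:
        raise ValueError("empty response curve")
    feasible = [pt for pt in curve if pt.yield_kg_ha >= target_yield]
    if feasible:
        return min(pt.n_rate for pt in feasible), False
    best = max(curve, key=lambda pt: (pt.yield_kg_ha, -pt.n_rate))
    return best.n_rate, True


def recommend_from_model(
    model: CropModel,
    mgmt: ManagementPlan,
    soil: SoilInit,
    weather: WeatherSeries,
    cultivar: CultivarParams | None = None,
    grid: NSearchGrid | None = None,
    prices: EconomicParams | None = None,
) -> RecommendationResult:
    """Full rule: response curve -> economic optimum -> lowest rate meeting it."""
    curve = yield_response_curve(model, mgmt, soil, weather, cultivar, grid, prices)
    n_opt, target = economic_optimum(curve)
    n_rec, infeasible = recommend_n(curve, target)
    return RecommendationResult(
        response_curve=curve,
        n_economic_optimum=n_opt,
        target_yield=target,
        n_recommended=n_rec,
        infeasible=infeasible,
    )


def reference_curve_predict(agb_jointing: float, curve: PowerLawCurve | None = None) -> float:
    """Recommended N from jointing-stage AGB via the power-law curve."""
    curve = curve or PUBLISHED_REFERENCE_CURVE
    if agb_jointing <= 0:
        raise ValueError("jointing-stage AGB must be positive")
    return curve.a * agb_jointing ** curve.b


@dataclass(frozen=True)
class PowerLawFit:
    curve: PowerLawCurve
    r2_log: float
    r2_linear: float


def fit_reference_curve(pairs: Sequence[tuple[float, float]]) -> PowerLawFit:
    """Least-squares fit of ``ln N = ln a + b ln AGB``.

    Reports R2 on the log scale (the fitting scale) and on the original
    scale, both labelled.  Requires at least three strictly positive pairs.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("pairs must be strictly positive for a log-log fit")
    lx, ly = np.log(x), np.log(y)
    X = np.column_stack([np.ones_like(lx), lx])
    beta, *_ = np.linalg.lstsq(X, ly, rcond=None)
    log_a, b = float(beta[0]), float(beta[1])
    pred_log = X @ beta
    ss = lambda r: float(np.sum(r**2))
    r2_log = 1.0 - ss(ly - pred_log) / ss(ly - ly.mean()) if np.ptp(ly) > 0 else 1.0
    pred_lin = np.exp(pred_log)
    r2_lin = 1.0 - ss(y - pred_lin) / ss(y - y.mean()) if np.ptp(y) > 0 else 1.0
    return PowerLawFit(PowerLawCurve(math.exp(log_a), b), r2_log=r2_log, r2_linear=r2_lin)
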