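"""Particle-swarm assimilation of biomass observations into the crop model.

The swarm searches (a subset of) seven quantities — four genotype traits and
three management totals — minimising the mean relative-squared misfit
between observed and simulated aboveground biomass on the observation dates.

Velocity update (inertia weight ``w`` defaults to 1, i.e. the plain form):

    v <- w*v + c1*xi*(pbest - x) + c2*eta*(gbest - x)
    x <- x + v

with per-dimension uniform draws ``xi``, ``eta`` in [0, 1], positions clamped
to bounds (velocity zeroed in clamped dimensions) and velocities clamped to
the initialisation fraction of each range every step, which keeps the
w = 1 formulation stable.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .crop_model import (
    PARAMETER_TABLE,
    CropModel,
    CultivarParams,
    ManagementPlan,
    SimulationOutput,
    SoilInit,
    WeatherSeries,
)

__all__ = [
    "ParameterSpec",
    "default_parameter_specs",
    "Particle",
    "SwarmConfig",
    "AssimilationResult",
    "fitness_j",
    "initialize_swarm",
    "update_particle",
    "assimilate",
    "apply_parameters",
]

logger = logging.getLogger(__name__)

_CULTIVAR_NAMES = ("p1d", "phint", "rdgs", "slpf")
_MANAGEMENT_NAMES = ("plant_density", "irrigation", "fertilization")


@dataclass(frozen=True)
class ParameterSpec:
    """Name, starting value and calibration range of one tunable quantity."""

    name: str
    initial_value: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if not self.lower_bound <= self.initial_value <= self.upper_bound:
            raise ValueError(
                f"{self.name}: initial {self.initial_value} outside "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )

    @property
    def range(self) -> float:
        return self.upper_bound - self.lower_bound


def default_parameter_specs(names: Sequence[str] | None = None) -> list[ParameterSpec]:
    """The default seven-parameter spec set, optionally restricted by name.

    Restricting to a subset fixes the remaining quantities at the values in
    the base management plan / cultivar (both supported modes).
    """
    table = {name: (init, lo, hi) for name, init, lo, hi in PARAMETER_TABLE}
    if names is None:
        names = [row[0] for row in PARAMETER_TABLE]
    specs = []
    for name in names:
        if name not in table:
            raise KeyError(f"unknown parameter {name!r}; known: {sorted(table)}")
        init, lo, hi = table[name]
        specs.append(ParameterSpec(name, init, lo, hi))
    return specs


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_cost: float = np.inf


@dataclass(frozen=True)
class SwarmConfig:
    n_particles: int = 25
    c1: float = 2.0
    c2: float = 2.0
    max_iterations: int = 100
    initial_velocity_fraction: float = 0.10
    inertia_weight: float = 1.0
    convergence_tolerance: float = 1e-6
    convergence_patience: int = 10
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.max_iterations < 0:
            raise ValueError("n_particles and max_iterations must be positive")
        if not 0 < self.initial_velocity_fraction <= 1:
            raise ValueError("initial_velocity_fraction must be in (0, 1]")
        if self.c1 < 0 or self.c2 < 0 or self.inertia_weight < 0:
            raise ValueError("c1, c2 and inertia_weight must be non-negative")


@dataclass
class AssimilationResult:
    best_parameters: dict[str, float]
    best_cost: float
    cost_trajectory: list[float]
    simulation: SimulationOutput
    n_evaluations: int = 0
    config: SwarmConfig = field(default_factory=SwarmConfig)


def fitness_j(agb_simulated, agb_observed) -> float:
    """Mean relative-squared misfit ``(1/m) * sum(((s - r) / r)^2)``."""
    s = np.asarray(agb_simulated, dtype=float)
    r = np.asarray(agb_observed, dtype=float)
    if s.shape != r.shape:
        raise ValueError(f"length mismatch: simulated {s.shape} vs observed {r.shape}")
    if s.size == 0:
        raise ValueError("empty vectors")
    if np.any(r <= 0):
        raise ValueError("observed AGB must be positive (relative error undefined)")
    return float(np.mean(((s - r) / r) ** 2))


def initialize_swarm(
    specs: Sequence[ParameterSpec],
    config: SwarmConfig,
    rng: np.random.Generator,
) -> list[Particle]:
    """Seeded swarm: one particle at the spec initial values, the rest uniform
    within bounds; velocities uniform in +-fraction*range per dimension."""
    if not specs:
        raise ValueError("empty parameter spec list")
    lo = np.array([s.lower_bound for s in specs])
    hi = np.array([s.upper_bound for s in specs])
    vmax = config.initial_velocity_fraction * (hi - lo)
    particles = []
    for i in range(config.n_particles):
        if i == 0:
            x = np.array([s.initial_value for s in specs], dtype=float)
        else:
            x = rng.uniform(lo, hi)
        v = rng.uniform(-vmax, vmax)
        particles.append(Particle(position=x, velocity=v, best_position=x.copy()))
    return particles


def update_particle(
    p: Particle,
    gbest: np.ndarray,
    specs: Sequence[ParameterSpec],
    config: SwarmConfig,
    draws: tuple[np.ndarray, np.ndarray],
) -> None:
    """In-place velocity/position update with bound and velocity clamping."""
    xi, eta = draws
    lo = np.array([s.lower_bound for s in specs])
    hi = np.array([s.upper_bound for s in specs])
    vmax = config.initial_velocity_fraction * (hi - lo)
    v = (
        config.inertia_weight * p.velocity
        + config.c1 * xi * (p.best_position - p.position)
        + config.c2 * eta * (gbest - p.position)
    )
    v = np.clip(v, -vmax, vmax)
    x = p.position + v
    clamped_lo = x < lo
    clamped_hi = x > hi
    x = np.clip(x, lo, hi)
    v[clamped_lo | clamped_hi] = 0.0
    p.position = x
    p.velocity = v


def apply_parameters(
    names: Sequence[str],
    values: np.ndarray,
    base_mgmt: ManagementPlan,
    base_cultivar: CultivarParams,
) -> tuple[ManagementPlan, CultivarParams]:
    """Map a parameter vector onto a management plan and cultivar.

    Management totals rescale the dated events of the base plan, preserving
    split proportions; genotype traits replace the cultivar fields.
    """
    mgmt = base_mgmt
    cult_kwargs: dict[str, float] = {}
    for name, value in zip(names, values):
        if name == "plant_density":
            mgmt = replace(mgmt, plant_density=float(value))
        elif name == "irrigation":
            mgmt = mgmt.scaled_irrigation(float(value))
        elif name == "fertilization":
            mgmt = mgmt.scaled_fertilization(float(value))
        elif name in _CULTIVAR_NAMES:
            cult_kwargs[name] = float(value)
        else:
            raise KeyError(f"unknown parameter {name!r}")
    cultivar = replace(base_cultivar, **cult_kwargs) if cult_kwargs else base_cultivar
    return mgmt, cultivar


def assimilate(
    model: CropModel,
    specs: Sequence[ParameterSpec],
    observations: Sequence[tuple[dt.date, float]],
    base_mgmt: ManagementPlan,
    soil: SoilInit,
    weather: WeatherSeries,
    config: SwarmConfig | None = None,
    base_cultivar: CultivarParams | None = None,
) -> AssimilationResult:
    """Run the swarm against dated AGB observations and return the best fit.

    Stops at ``max_iterations`` or when the best cost improves by less than
    ``convergence_tolerance`` over ``convergence_patience`` iterations; the
    model is rerun at the best parameters for the returned trajectory.
    """
    config = config or SwarmConfig()
    base_cultivar = base_cultivar or CultivarParams()
    if not observations:
        raise ValueError("no observations")
    obs_dates = [d for d, _ in observations]
    obs_vals = np.array([v for _, v in observations], dtype=float)

    probe = model.simulate(weather, soil, base_mgmt, base_cultivar, clamp_params=True)
    season = set(probe.dates)
    bad = [d for d in obs_dates if d not in season]
    if bad:
        raise ValueError(
            "observation dates outside simulated season: "
            + ", ".join(d.isoformat() for d in bad)
        )

    names = [s.name for s in specs]
    n_evals = 0

    def cost(position: np.ndarray) -> tuple[float, SimulationOutput]:
        nonlocal n_evals
        mgmt, cultivar = apply_parameters(names, position, base_mgmt, base_cultivar)
        sim = model.simulate(weather, soil, mgmt, cultivar, clamp_params=True)
        n_evals += 1
        simulated = np.array([sim.agb_on(d) for d in obs_dates])
        return fitness_j(simulated, obs_vals), sim

    rng = np.random.default_rng(config.random_seed)
    particles = initialize_swarm(specs, config, rng)

    gbest = particles[0].position.copy()
    gbest_cost = np.inf
    for p in particles:
        c, _ = cost(p.position)
        p.best_cost = c
        if c < gbest_cost:  # strict: first-found wins on ties
            gbest_cost = c
            gbest = p.position.copy()

    trajectory = [gbest_cost]
    stall = 0
    ndim = len(specs)
    for _ in range(config.max_iterations):
        improved_by = 0.0
        for p in particles:
            xi = rng.uniform(0.0, 1.0, size=ndim)
            eta = rng.uniform(0.0, 1.0, size=ndim)
            update_particle(p, gbest, specs, config, (xi, eta))
            c, _ = cost(p.position)
            if c < p.best_cost:
                p.best_cost = c
                p.best_position = p.position.copy()
            if c < gbest_cost:
                improved_by = max(improved_by, gbest_cost - c)
                gbest_cost = c
                gbest = p.position.copy()
        trajectory.append(gbest_cost)
        logger.debug("pso iteration %d: best J = %.6g", len(trajectory) - 1, gbest_cost)
        stall = stall + 1 if improved_by < config.convergence_tolerance else 0
        if stall >= config.convergence_patience:
            break

    best_cost, best_sim = cost(gbest)
    return AssimilationResult(
        best_parameters=dict(zip(names, (float(v) for v in gbest))),
        best_cost=gbest_cost,
        cost_trajectory=trajectory,
        simulation=best_sim,
        n_evaluations=n_evals,
        config=config,
    )
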