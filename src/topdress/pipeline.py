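"""End-to-end orchestration: estimate AGB -> assimilate -> recommend.

The three stages mirror the module APIs exactly; the orchestrator only adds
file plumbing, per-plot iteration and provenance (config hash + seed in
every report), so a pipeline run equals composing the module calls by hand.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import io as tio
from .agb import PUBLISHED_COEFFICIENTS, HLMCoefficients, SpectralSample, hlm_fit, hlm_predict
from .assimilation import (
    AssimilationResult,
    SwarmConfig,
    apply_parameters,
    assimilate,
    default_parameter_specs,
)
from .crop_model import CultivarParams, get_model
from .recommendation import (
    EconomicParams,
    NSearchGrid,
    RecommendationResult,
    recommend_from_model,
)

__all__ = ["RunConfig", "PlotResult", "PipelineReport", "run_pipeline", "estimate_agb"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")


@dataclass(frozen=True)
class RunConfig:
    weather_csv: str
    soil_yaml: str
    mgmt_yaml: str
    spectra_csv: str
    params_yaml: str | None = None          # default: fertilization only
    free_parameters: tuple[str, ...] = ("fertilization",)
    hlm_coefficients: str = "published"     # or a JSON file with g00..g11
    latitude: float = 39.5
    swarm: SwarmConfig = field(default_factory=lambda: SwarmConfig(max_iterations=40))
    grid: NSearchGrid = field(default_factory=NSearchGrid)
    prices: EconomicParams = field(default_factory=EconomicParams)
    seed: int = 0
    out_dir: str = "out"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where results land does not change what they are
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PlotResult:
    plot_id: str
    agb_jointing: float          # t/ha from the assimilated simulation
    n_recommended: float
    n_economic_optimum: float
    target_yield: float          # kg/ha
    expected_benefit: float      # CNY/ha at the recommended rate
    infeasible: bool
    best_parameters: dict[str, float]
    best_cost: float


@dataclass
class PipelineReport:
    config_hash: str
    seed: int
    plots: list[PlotResult]

    def to_dict(self) -> dict[str, Any]:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "plots": [dataclasses.asdict(p) for p in self.plots],
        }


def estimate_agb(
    spectra: Sequence[SpectralSample],
    coefficients: HLMCoefficients = PUBLISHED_COEFFICIENTS,
    clamp_negative: bool = False,
) -> dict[str, list[tuple[dt.date, float]]]:
    """Per-plot dated AGB estimates from reflectance via the monitoring model.

    Non-positive raw estimates cannot enter the relative-error cost and are
    dropped with a warning unless ``clamp_negative`` floors them at zero
    (map-production mode).
    """
    out: dict[str, list[tuple[dt.date, float]]] = {}
    for s in spectra:
        est = hlm_predict(s.evi2, s.gdd, coefficients)
        if est <= 0 and not clamp_negative:
            logger.warning("dropping non-positive AGB estimate %.3f for %s %s", est, s.plot_id, s.date)
            continue
        out.setdefault(s.plot_id, []).append((s.date, max(est, 0.0) if clamp_negative else est))
    return out


def _load_coefficients(spec: str, spectra: Sequence[SpectralSample]) -> HLMCoefficients:
    if spec == "published":
        return PUBLISHED_COEFFICIENTS
    if spec == "fit":
        return hlm_fit(spectra).coefficients
    data = json.loads(Path(spec).read_text())
    return HLMCoefficients(**data)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the three stages and write ``report.json`` plus a per-plot CSV."""
    try:
        weather = tio.read_weather_csv(config.weather_csv, latitude=config.latitude)
        soil = tio.read_soil(config.soil_yaml)
        mgmt = tio.read_management(config.mgmt_yaml)
        spectra = tio.read_spectra_csv(config.spectra_csv)
    except (OSError, ValueError) as exc:
        raise StageError("load-inputs", str(exc)) from exc

    try:
        coeffs = _load_coefficients(config.hlm_coefficients, spectra)
        observations = estimate_agb(spectra, coeffs)
        if not observations:
            raise ValueError("no usable AGB estimates")
    except (OSError, ValueError) as exc:
        raise StageError("estimate-agb", str(exc)) from exc

    if config.params_yaml:
        specs = tio.read_parameter_specs(config.params_yaml)
    else:
        specs = default_parameter_specs(list(config.free_parameters))

    model = get_model()
    results: list[PlotResult] = []
    for plot_id in sorted(observations):
        obs = sorted(observations[plot_id])
        try:
            swarm = dataclasses.replace(config.swarm, random_seed=config.seed)
            assim: AssimilationResult = assimilate(
                model, specs, obs, mgmt, soil, weather, swarm
            )
        except ValueError as exc:
            raise StageError("assimilate", f"plot {plot_id}: {exc}") from exc
        names = list(assim.best_parameters)
        values = [assim.best_parameters[n] for n in names]
        plot_mgmt, cultivar = apply_parameters(names, np.array(values), mgmt, CultivarParams())
        try:
            rec: RecommendationResult = recommend_from_model(
                model, plot_mgmt, soil, weather, cultivar, config.grid, config.prices
            )
        except (ValueError, RuntimeError) as exc:
            raise StageError("recommend", f"plot {plot_id}: {exc}") from exc
        sim = assim.simulation
        rec_point = next(p for p in rec.response_curve if p.n_rate == rec.n_recommended)
        results.append(
            PlotResult(
                plot_id=plot_id,
                agb_jointing=sim.agb_on(sim.jointing_date),
                n_recommended=rec.n_recommended,
                n_economic_optimum=rec.n_economic_optimum,
                target_yield=rec.target_yield,
                expected_benefit=rec_point.benefit,
                infeasible=rec.infeasible,
                best_parameters=assim.best_parameters,
                best_cost=assim.best_cost,
            )
        )

    report = PipelineReport(config_hash=config.config_hash, seed=config.seed, plots=results)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    with (out_dir / "plots.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plot_id", "agb_jointing", "n_recommended", "target_yield", "expected_E"])
        for r in results:
            w.writerow(
                [r.plot_id, repr(r.agb_jointing), repr(r.n_recommended),
                 repr(r.target_yield), repr(r.expected_benefit)]
            )
    return report
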