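import datetime as dt

import numpy as np
import pytest

from topdress import synthetic as syn
from topdress.assimilation import (
    ParameterSpec,
    Particle,
    SwarmConfig,
    apply_parameters,
    assimilate,
    default_parameter_specs,
    fitness_j,
    initialize_swarm,
    update_particle,
)
from topdress.crop_model import CultivarParams, simulate_season


class TestFitnessJ:
    def test_perfect_match(self):
        assert fitness_j([5, 6], [5, 6]) == 0.0

    def test_derived_two_points(self):
        assert fitness_j([5, 6], [4, 6]) == pytest.approx(0.03125)

    def test_derived_single(self):
        assert fitness_j([2], [4]) == pytest.approx(0.25)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fitness_j([1.0], [0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fitness_j([1, 2], [1])


class TestInitializeSwarm:
    def test_default_count_and_bounds(self):
        specs = default_parameter_specs()
        rng = np.random.default_rng(0)
        swarm = initialize_swarm(specs, SwarmConfig(), rng)
        assert len(swarm) == 25
        lo = np.array([s.lower_bound for s in specs])
        hi = np.array([s.upper_bound for s in specs])
        for p in swarm:
            assert np.all(p.position >= lo) and np.all(p.position <= hi)

    def test_velocity_within_ten_percent_of_range(self):
        specs = default_parameter_specs()
        rng = np.random.default_rng(0)
        swarm = initialize_swarm(specs, SwarmConfig(), rng)
        vmax = 0.1 * np.array([s.range for s in specs])
        for p in swarm:
            assert np.all(np.abs(p.velocity) <= vmax + 1e-12)

    def test_first_particle_at_initial_values(self):
        specs = default_parameter_specs()
        swarm = initialize_swarm(specs, SwarmConfig(), np.random.default_rng(0))
        assert list(swarm[0].position) == [s.initial_value for s in specs]

    def test_seeded_determinism(self):
        specs = default_parameter_specs()
        a = initialize_swarm(specs, SwarmConfig(), np.random.default_rng(7))
        b = initialize_swarm(specs, SwarmConfig(), np.random.default_rng(7))
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.position, pb.position)
            assert np.array_equal(pa.velocity, pb.velocity)

    def test_empty_specs_rejected(self):
        with pytest.raises(ValueError):
            initialize_swarm([], SwarmConfig(), np.random.default_rng(0))


def _particle(x, v):
    x = np.array([float(x)])
    return Particle(position=x, velocity=np.array([float(v)]), best_position=x.copy())


class TestUpdateParticle:
    def test_fixed_point(self):
        spec = [ParameterSpec("x", 0.0, -10.0, 10.0)]
        p = _particle(0.0, 0.0)
        update_particle(p, np.array([0.0]), spec, SwarmConfig(), (np.array([0.5]), np.array([0.5])))
        assert p.position[0] == 0.0 and p.velocity[0] == 0.0

    def test_derived_inertia_only(self):
        spec = [ParameterSpec("x", 0.0, -10.0, 10.0)]
        p = _particle(0.0, 1.0)
        update_particle(p, np.array([0.0]), spec, SwarmConfig(), (np.array([0.5]), np.array([0.5])))
        assert p.velocity[0] == pytest.approx(1.0)
        assert p.position[0] == pytest.approx(1.0)

    def test_derived_social_pull(self):
        spec = [ParameterSpec("x", 0.0, -50.0, 50.0)]
        p = _particle(0.0, 0.0)
        update_particle(
            p, np.array([4.0]), spec, SwarmConfig(c1=2.0, c2=2.0),
            (np.array([0.0]), np.array([0.5])),
        )
        assert p.velocity[0] == pytest.approx(4.0)
        assert p.position[0] == pytest.approx(4.0)

    def test_bound_clamp_zeroes_velocity(self):
        spec = [ParameterSpec("x", 0.0, -1.0, 1.0)]
        p = _particle(0.9, 0.0)
        update_particle(
            p, np.array([1.0e3]), spec, SwarmConfig(initial_velocity_fraction=1.0),
            (np.array([0.0]), np.array([1.0])),
        )
        assert p.position[0] == 1.0
        assert p.velocity[0] == 0.0

    def test_velocity_clamped_to_fraction(self):
        spec = [ParameterSpec("x", 0.0, -1.0, 1.0)]
        p = _particle(0.0, 0.0)
        update_particle(
            p, np.array([1.0]), spec, SwarmConfig(),  # fraction 0.1 -> vmax 0.2
            (np.array([0.0]), np.array([1.0])),
        )
        assert abs(p.velocity[0]) <= 0.2 + 1e-12


@pytest.fixture(scope="module")
def twin_setup(weather):
    soil = syn.default_soil()
    mgmt = syn.default_management(dt.date(2020, 10, 5), 100.0, basal_fraction=0.0)
    truth = simulate_season(weather, soil, mgmt)
    obs_dates = [
        truth.stage_dates["jointing"] + dt.timedelta(days=8),
        truth.stage_dates["anthesis"] + dt.timedelta(days=2),
        truth.stage_dates["anthesis"]
        + (truth.stage_dates["maturity"] - truth.stage_dates["anthesis"]) / 2,
    ]
    obs = [(d, truth.agb_on(d)) for d in obs_dates]
    return soil, mgmt, truth, obs


class TestAssimilate:
    def test_truth_in_swarm_gives_zero_cost(self, model, weather, twin_setup):
        soil, mgmt, truth, obs = twin_setup
        specs = default_parameter_specs(["fertilization"])
        # spec initial value = 200; rebuild so the seeded particle IS the truth
        specs = [ParameterSpec("fertilization", 100.0, 0.0, 400.0)]
        cfg = SwarmConfig(n_particles=5, max_iterations=0, random_seed=1)
        res = assimilate(model, specs, obs, mgmt, soil, weather, cfg)
        assert res.best_cost == pytest.approx(0.0, abs=1e-20)
        assert res.cost_trajectory[0] == pytest.approx(0.0, abs=1e-20)

    def test_cost_trajectory_non_increasing(self, model, weather, twin_setup):
        soil, mgmt, truth, obs = twin_setup
        specs = default_parameter_specs(["fertilization"])
        for seed in (0, 1, 2):
            cfg = SwarmConfig(n_particles=8, max_iterations=10, random_seed=seed)
            res = assimilate(model, specs, obs, mgmt, soil, weather, cfg)
            t = res.cost_trajectory
            assert all(a >= b - 1e-15 for a, b in zip(t, t[1:]))

    def test_final_cost_not_worse_than_truth(self, model, weather, twin_setup):
        soil, mgmt, truth, obs = twin_setup
        specs = [ParameterSpec("fertilization", 100.0, 0.0, 400.0)]
        cfg = SwarmConfig(n_particles=8, max_iterations=5, random_seed=3)
        res = assimilate(model, specs, obs, mgmt, soil, weather, cfg)
        assert res.best_cost <= 1e-20  # truth seeded and noiseless

    def test_twin_matches_grid_search_oracle(self, model, weather, twin_setup):
        soil, mgmt, truth, obs = twin_setup
        obs_dates = [d for d, _ in obs]
        obs_vals = np.array([v for _, v in obs])

        def j(total):
            sim = simulate_season(weather, soil, mgmt.scaled_fertilization(total))
            return float(np.mean(
                ((np.array([sim.agb_on(d) for d in obs_dates]) - obs_vals) / obs_vals) ** 2
            ))

        grid = np.arange(0.0, 401.0, 1.0)
        oracle_n = grid[int(np.argmin([j(g) for g in grid]))]
        specs = default_parameter_specs(["fertilization"])
        cfg = SwarmConfig(n_particles=12, max_iterations=30, random_seed=5)
        res = assimilate(model, specs, obs, mgmt, soil, weather, cfg)
        assert abs(res.best_parameters["fertilization"] - oracle_n) <= 1.0

    def test_observation_outside_season_rejected(self, model, weather, twin_setup):
        soil, mgmt, truth, obs = twin_setup
        bad = obs + [(dt.date(2025, 1, 1), 5.0)]
        specs = default_parameter_specs(["fertilization"])
        with pytest.raises(ValueError, match="2025-01-01"):
            assimilate(model, specs, bad, mgmt, soil, weather, SwarmConfig())


class TestApplyParameters:
    def test_management_and_cultivar_mapping(self, mgmt):
        plan, cult = apply_parameters(
            ["fertilization", "irrigation", "plant_density", "p1d"],
            np.array([120.0, 200.0, 320.0, 60.0]),
            mgmt, CultivarParams(),
        )
        assert plan.total_fertilization == pytest.approx(120.0)
        assert plan.total_irrigation == pytest.approx(200.0)
        assert plan.plant_density == 320.0
        assert cult.p1d == 60.0

    def test_unknown_name_rejected(self, mgmt):
        with pytest.raises(KeyError):
            apply_parameters(["bogus"], np.array([1.0]), mgmt, CultivarParams())


def test_parameter_spec_validation():
    with pytest.raises(ValueError):
        ParameterSpec("x", 5.0, 0.0, 1.0)
    with pytest.raises(KeyError):
        default_parameter_specs(["nope"])
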