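"""Grid search behavior and genetic-algorithm mechanics and recovery."""

import numpy as np
import pytest

from perturbscape.fc import compute_fc, simulated_bold
from perturbscape.fitting import (
    GAConfig,
    _ga_minimize,
    _next_generation,
    derive_seed,
    evaluate_fitness,
    fit_group,
    homogeneous_grid_search,
    run_genetic_algorithm,
)
from perturbscape.hopf import HopfParams, SimulationConfig, integrate_hopf
from perturbscape.priors import build_membership_prior, combine_delta
from perturbscape.synthetic import SyntheticSpec, generate_connectome, generate_group_fc, generate_region_metadata

SIM240 = SimulationConfig(duration=240.0, transient=20.0)


def _single_run_target(world, a0, G0, seed):
    params = HopfParams(a=np.full(20, a0), omega=world["omega"], G=G0)
    cfg = SimulationConfig(duration=240.0, transient=20.0, seed=seed)
    sig = integrate_hopf(params, world["conn"], cfg)
    return compute_fc(simulated_bold(sig), world["conn"].region_labels)


class TestGAConfig:
    def test_canonical_offspring_counts(self):
        cfg = GAConfig()
        assert (cfg.n_elite, cfg.n_crossover, cfg.n_mutation) == (2, 6, 2)

    def test_noninteger_fraction_split_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            GAConfig(population_size=7)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GAConfig(elite_fraction=0.3)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=2)


class TestGAMechanics:
    def test_offspring_composition_exact_every_generation(self):
        cfg = GAConfig(seed=0)
        rng = np.random.default_rng(1)
        pop = rng.uniform(-0.1, 0.1, (10, 6))
        gofs = rng.random(10)
        for _ in range(5):
            offspring, counts = _next_generation(pop, gofs, rng, cfg)
            assert counts == (2, 6, 2)
            assert offspring.shape == (10, 6)
            # elite children are exact copies of the two fittest parents
            order = np.argsort(gofs, kind="stable")
            np.testing.assert_array_equal(offspring[0], pop[order[0]])
            np.testing.assert_array_equal(offspring[1], pop[order[1]])
            pop, gofs = offspring, rng.random(10)

    def test_constant_fitness_halts_on_best_stall(self):
        cfg = GAConfig(seed=2, max_generations=200, stall_generations=50)
        res = _ga_minimize(lambda d, s: 1.0, 6, cfg)
        assert res.halting_reason == "stall_best"
        assert len(res.history["best"]) == 51

    def test_ever_improving_fitness_halts_at_generation_limit(self):
        calls = {"n": 0}

        def fitness(d, s):
            calls["n"] += 1
            return -0.01 * calls["n"]

        cfg = GAConfig(seed=3, max_generations=55, stall_generations=50)
        res = _ga_minimize(fitness, 6, cfg)
        assert res.halting_reason == "max_generations"
        assert len(res.history["best"]) == 55

    def test_constant_mean_improving_best_halts_on_mean_stall(self):
        calls = {"n": 0}

        def fitness(d, s):
            i = calls["n"] % 10
            gen = calls["n"] // 10
            calls["n"] += 1
            best = 1.0 - 0.002 * gen
            return best if i == 0 else (10.0 - best) / 9.0

        cfg = GAConfig(seed=4, max_generations=200, stall_generations=50)
        res = _ga_minimize(fitness, 6, cfg)
        assert res.halting_reason == "stall_mean"
        assert np.ptp(res.history["mean"][-51:]) < 1e-6

    def test_best_ever_history_is_nonincreasing(self):
        rng = np.random.default_rng(5)
        res = _ga_minimize(lambda d, s: float(np.sum(d**2) + 0.01 * rng.random()), 6,
                           GAConfig(seed=6, max_generations=40, stall_generations=30))
        assert np.all(np.diff(res.history["best"]) <= 0)

    def test_quadratic_surrogate_recovery(self):
        rng = np.random.default_rng(3)
        target = rng.uniform(-0.1, 0.1, 6)
        res = _ga_minimize(
            lambda d, s: float(np.sum((d - target) ** 2)),
            6,
            GAConfig(seed=5, max_generations=200),
        )
        assert len(res.history["best"]) <= 200
        assert np.linalg.norm(res.best_delta - target) < 0.05


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, world20):
        target = _single_run_target(world20, 0.0, 0.6, seed=999)
        res = homogeneous_grid_search(
            world20["conn"], world20["omega"], target,
            a_values=np.array([0.05]), G_values=np.array([0.4]),
            runs=1, seed=0, sim_config=SIM240,
        )
        assert res.argmin == (0.05, 0.4)
        assert res.gof_surface.shape == (1, 1)

    def test_deterministic_surface_for_fixed_seed(self, world20):
        target = _single_run_target(world20, 0.0, 0.6, seed=999)
        kwargs = dict(a_values=np.array([-0.1, 0.1]), G_values=np.array([0.3, 0.9]),
                      runs=1, seed=3, sim_config=SIM240)
        a = homogeneous_grid_search(world20["conn"], world20["omega"], target, **kwargs)
        b = homogeneous_grid_search(world20["conn"], world20["omega"], target, **kwargs)
        np.testing.assert_array_equal(a.gof_surface, b.gof_surface)

    def test_self_consistency_recovery(self, world20):
        """The model's own (a0, G0) is recovered up to the landscape's geometry.

        The bifurcation parameter is identified to within one grid cell; the
        coupling valley is shallow, so the true cell is required to sit
        within sampling noise of the surface minimum rather than to be the
        exact argmin.
        """
        a0, G0 = 0.0, 0.6
        target = _single_run_target(world20, a0, G0, seed=999)
        a_values = np.linspace(-0.2, 0.2, 11)
        G_values = np.linspace(0.0, 3.0, 11)
        res = homogeneous_grid_search(
            world20["conn"], world20["omega"], target,
            a_values=a_values, G_values=G_values,
            runs=3, seed=1, sim_config=SIM240,
        )
        assert abs(res.argmin[0] - a0) <= 0.04 + 1e-9
        truth_cell = res.gof_surface[
            int(np.argmin(np.abs(a_values - a0))), int(np.argmin(np.abs(G_values - G0)))
        ]
        assert truth_cell - res.gof_surface[res.argmin_idx] <= 0.02


class TestEvaluateFitness:
    def test_deterministic_for_same_seed(self, world20):
        target = _single_run_target(world20, 0.0, 0.5, seed=7)
        d = np.full(6, 0.02)
        a = evaluate_fitness(d, world20["M"], world20["conn"], world20["omega"], 0.5, target,
                             seed=11, sim_config=SIM240)
        b = evaluate_fitness(d, world20["M"], world20["conn"], world20["omega"], 0.5, target,
                             seed=11, sim_config=SIM240)
        assert a == b

    def test_zero_delta_matches_homogeneous_model_at_zero(self, world20):
        target = _single_run_target(world20, 0.0, 0.5, seed=7)
        via_delta = evaluate_fitness(
            np.zeros(6), world20["M"], world20["conn"], world20["omega"], 0.5, target,
            seed=13, sim_config=SIM240, ssim_mode="global",
        )
        grid = homogeneous_grid_search(
            world20["conn"], world20["omega"], target,
            a_values=np.array([0.0]), G_values=np.array([0.5]),
            runs=1, seed=0, sim_config=SIM240,
        )
        # same model family; both score a homogeneous a=0, G=0.5 simulation
        assert via_delta == pytest.approx(grid.gof_surface[0, 0], abs=0.15)


class TestEnsembles:
    def _surrogate(self, d, s):
        return float(np.sum((d - 0.05) ** 2))

    def test_runs_have_distinct_seeds_and_histories(self, world20):
        results = fit_group(
            world20["M"], world20["conn"], world20["omega"], None,
            n_runs=3, base_seed=1, ga_config=GAConfig(max_generations=10, stall_generations=8),
            fitness_fn=self._surrogate,
        )
        assert len({r.seed for r in results}) == 3
        assert len({tuple(r.best_delta) for r in results}) == 3

    def test_same_base_seed_reproduces_ensemble(self, world20):
        kwargs = dict(n_runs=2, base_seed=5,
                      ga_config=GAConfig(max_generations=8, stall_generations=6),
                      fitness_fn=self._surrogate)
        a = fit_group(world20["M"], world20["conn"], world20["omega"], None, **kwargs)
        b = fit_group(world20["M"], world20["conn"], world20["omega"], None, **kwargs)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.best_delta, rb.best_delta)
            assert ra.best_gof == rb.best_gof


class TestFullScaleRecovery:
    def test_parameter_recovery_at_full_90_region_scale(self):
        """Known group coefficients are recovered from the 90-region emulation.

        The per-region bifurcation pattern correlates with the ground truth
        in most independent reduced-budget GA runs at the full parcellation
        scale, where the SSIM objective averages over enough FC entries for
        single-simulation evaluations to be informative.
        """
        delta_star = np.array([-0.2, 0.15, -0.2, 0.15, -0.2, 0.15])
        spec = SyntheticSpec(seed=0, n_regions=90, duration=480.0,
                             group_deltas={"TRUTH": delta_star})
        conn = generate_connectome(spec)
        meta = generate_region_metadata(spec)
        M = build_membership_prior(meta.labels)
        omega = 2 * np.pi * meta.natural_frequencies
        _, target, truth = generate_group_fc(spec, "TRUTH", conn, M, omega)
        corrs = []
        for run in range(3):
            ga = GAConfig(max_generations=60, stall_generations=50,
                          seed=derive_seed(42, run), mutation_sigma=0.08)
            res = run_genetic_algorithm(M, conn, omega, target, ga, G=0.5, sim_config=SIM240)
            corrs.append(np.corrcoef(combine_delta(M, res.best_delta), truth.a_star)[0, 1])
            assert np.all(np.diff(res.history["best"]) <= 0)
        assert sum(c >= 0.8 for c in corrs) >= 2
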