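"""Two-stage model fitting.

Stage 1 scans a homogeneous (a, G) grid, scoring each cell by the SSIM-based
fit distance between simulated and target FC, to pick the global coupling G
(the full fit then keeps G fixed, 0.5 by default).  Stage 2 optimizes the
group coefficients delta of a fixed prior with a genetic algorithm: each
generation keeps the top 20% unchanged (elite), builds 60% by uniform
per-gene crossover of fitness-proportionally selected parents, and 20% by
single-gene Gaussian mutation of selected parents; it halts at the
generation limit or when the best (or mean) fit stalls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fc import FCMatrix, compute_fc, goodness_of_fit, simulated_bold
from .hopf import Connectome, HopfParams, SimulationConfig, integrate_hopf
from .priors import GroupingMatrix, combine_delta

__all__ = [
    "GAConfig",
    "GridSearchResult",
    "FitResult",
    "homogeneous_grid_search",
    "evaluate_fitness",
    "run_genetic_algorithm",
    "fit_group",
    "derive_seed",
]

logger = logging.getLogger(__name__)


def derive_seed(*keys: int) -> int:
    """Deterministic child seed (< 2^31) from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


@dataclass
class GAConfig:
    """Genetic-algorithm settings.

    The offspring fractions must multiply the population size to integers
    that sum back to the population size (e.g. 2 elite / 6 crossover /
    2 mutation at population 10).

    ``eval_seed_policy`` controls the noise seen by the fitness: ``"frozen"``
    (default) evaluates every individual of a run against the same
    simulation seed (common random numbers), making the fitness a
    deterministic surface and protecting the best-ever record from a
    winner's curse over lucky noise draws; ``"per_eval"`` derives a fresh
    seed from (generation, individual) for every evaluation.
    """

    population_size: int = 10
    elite_fraction: float = 0.2
    crossover_fraction: float = 0.6
    mutation_fraction: float = 0.2
    max_generations: int = 200
    stall_generations: int = 50
    stall_tolerance: float = 1e-6
    eval_runs_per_individual: int = 1
    seed: int = 0
    init_scale: float = 0.02
    mutation_sigma: float = 0.02
    bounds: tuple[float, float] = (-0.3, 0.3)
    eval_seed_policy: str = "frozen"

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        fractions = (self.elite_fraction, self.crossover_fraction, self.mutation_fraction)
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("elite + crossover + mutation fractions must sum to 1")
        counts = [f * self.population_size for f in fractions]
        rounded = [int(round(c)) for c in counts]
        if any(abs(c - r) > 1e-9 for c, r in zip(counts, rounded)) or sum(
            rounded
        ) != self.population_size:
            raise ValueError(
                "fractions x population_size must give integer counts summing "
                f"to the population size; got {counts}"
            )
        if any(r < 0 for r in rounded):
            raise ValueError("offspring counts must be nonnegative")
        if self.eval_seed_policy not in ("frozen", "per_eval"):
            raise ValueError("eval_seed_policy must be 'frozen' or 'per_eval'")
        self._counts = tuple(rounded)

    @property
    def n_elite(self) -> int:
        return self._counts[0]

    @property
    def n_crossover(self) -> int:
        return self._counts[1]

    @property
    def n_mutation(self) -> int:
        return self._counts[2]


@dataclass
class GridSearchResult:
    """Fit-distance surface over the homogeneous (a, G) grid."""

    a_values: np.ndarray
    G_values: np.ndarray
    gof_surface: np.ndarray
    argmin: tuple[float, float]
    argmin_idx: tuple[int, int]


@dataclass
class FitResult:
    """Output of one genetic-algorithm run."""

    best_delta: np.ndarray
    best_gof: float
    best_fc: FCMatrix | None
    history: dict[str, np.ndarray]
    halting_reason: str
    seed: int
    composition: tuple[int, int, int] = (0, 0, 0)


def _simulate_fc(
    a: np.ndarray,
    connectome: Connectome,
    omega: np.ndarray,
    G: float,
    beta: float,
    sim_config: SimulationConfig,
    seed: int,
) -> FCMatrix:
    params = HopfParams(a=a, omega=omega, G=G, beta=beta)
    cfg = SimulationConfig(
        dt=sim_config.dt,
        duration=sim_config.duration,
        transient=sim_config.transient,
        seed=seed,
        initial_state=sim_config.initial_state,
    )
    signals = integrate_hopf(params, connectome, cfg)
    return compute_fc(simulated_bold(signals), connectome.region_labels)


def homogeneous_grid_search(
    connectome: Connectome,
    omega: np.ndarray,
    target_fc: FCMatrix,
    a_values: np.ndarray | None = None,
    G_values: np.ndarray | None = None,
    runs: int = 1,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    beta: float = 0.04,
    ssim_mode: str = "windowed",
) -> GridSearchResult:
    """Exhaustive scan of spatially homogeneous (a, G) combinations.

    For each grid cell the model is simulated ``runs`` times (seeds derived
    from the cell indices), the simulated FC is computed, and the fit
    distance to ``target_fc`` is averaged.  Cells whose simulation diverges
    are marked NaN and excluded from the argmin.  The canonical full-scale
    grid is 100 x 100 over a in [-0.2, 0.2] and G in [0, 3].

    Cells are scored with the windowed SSIM distance, the same objective the
    genetic stage minimizes.  The landscape typically shows a sharp valley
    in ``a`` and a shallow one in ``G``: coupling changes trade off against
    the bifurcation parameter, so cells along the valley floor can be
    statistically indistinguishable at modest run counts.
    """
    a_values = np.linspace(-0.2, 0.2, 100) if a_values is None else np.asarray(a_values, float)
    G_values = np.linspace(0.0, 3.0, 100) if G_values is None else np.asarray(G_values, float)
    if a_values.size < 1 or G_values.size < 1:
        raise ValueError("grid must contain at least one cell")
    sim_config = sim_config or SimulationConfig()

    surface = np.full((a_values.size, G_values.size), np.nan)
    for ia, a0 in enumerate(a_values):
        for ig, g0 in enumerate(G_values):
            vals = []
            for run in range(runs):
                try:
                    fc = _simulate_fc(
                        np.full(connectome.n_regions, a0),
                        connectome,
                        omega,
                        float(g0),
                        beta,
                        sim_config,
                        derive_seed(seed, ia, ig, run),
                    )
                    vals.append(goodness_of_fit(fc, target_fc, mode=ssim_mode))
                except Exception as exc:  # noqa: BLE001 - cell-level isolation
                    logger.warning("grid cell (a=%g, G=%g) run %d failed: %s", a0, g0, run, exc)
            if vals:
                surface[ia, ig] = float(np.mean(vals))
    if np.all(np.isnan(surface)):
        raise RuntimeError("every grid cell failed")
    idx = np.unravel_index(np.nanargmin(surface), surface.shape)
    return GridSearchResult(
        a_values=a_values,
        G_values=G_values,
        gof_surface=surface,
        argmin=(float(a_values[idx[0]]), float(G_values[idx[1]])),
        argmin_idx=(int(idx[0]), int(idx[1])),
    )


def evaluate_fitness(
    delta: np.ndarray,
    M: GroupingMatrix,
    connectome: Connectome,
    omega: np.ndarray,
    G: float,
    target_fc: FCMatrix,
    runs: int = 1,
    seed: int = 0,
    sim_config: SimulationConfig | None = None,
    beta: float = 0.04,
    ssim_mode: str = "windowed",
) -> float:
    """Fit distance of the model at a = M @ delta, averaged over ``runs`` simulations."""
    sim_config = sim_config or SimulationConfig()
    a = combine_delta(M, delta)
    vals = []
    for run in range(runs):
        seed_r = seed if runs == 1 else derive_seed(seed, run)
        try:
            fc = _simulate_fc(a, connectome, omega, G, beta, sim_config, seed_r)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for delta={np.round(delta, 4)}: {exc}") from exc
        vals.append(goodness_of_fit(fc, target_fc, mode=ssim_mode))
    return float(np.mean(vals))


def _select_parent(rng: np.random.Generator, probs: np.ndarray) -> int:
    return int(rng.choice(probs.size, p=probs))


def _next_generation(
    pop: np.ndarray,
    gofs: np.ndarray,
    rng: np.random.Generator,
    config: GAConfig,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Build the next population: elite copies, crossover children, mutants."""
    order = np.argsort(gofs, kind="stable")
    # lower distance -> higher score; proportional (roulette) selection
    scores = gofs.max() - gofs + 1e-9
    probs = scores / scores.sum()
    lo, hi = config.bounds
    children = [pop[i].copy() for i in order[: config.n_elite]]
    n_genes = pop.shape[1]
    for _ in range(config.n_crossover):
        p1 = pop[_select_parent(rng, probs)]
        p2 = pop[_select_parent(rng, probs)]
        mask = rng.integers(0, 2, size=n_genes).astype(bool)
        children.append(np.where(mask, p1, p2))
    for _ in range(config.n_mutation):
        child = pop[_select_parent(rng, probs)].copy()
        gene = int(rng.integers(n_genes))
        child[gene] += rng.normal(0.0, config.mutation_sigma)
        children.append(child)
    offspring = np.clip(np.asarray(children), lo, hi)
    return offspring, (config.n_elite, config.n_crossover, config.n_mutation)


def _ga_minimize(
    fitness: Callable[[np.ndarray, int], float],
    n_genes: int,
    config: GAConfig,
) -> FitResult:
    """Core GA loop over a fitness callable ``fitness(delta, eval_seed)``."""
    rng = np.random.default_rng(config.seed)
    pop = rng.uniform(-config.init_scale, config.init_scale, size=(config.population_size, n_genes))
    pop = np.clip(pop, *config.bounds)

    best_hist: list[float] = []
    mean_hist: list[float] = []
    best_delta: np.ndarray | None = None
    best_gof = np.inf
    halting_reason = "max_generations"
    composition = (config.n_elite, config.n_crossover, config.n_mutation)
    stall = config.stall_generations

    frozen_seed = derive_seed(config.seed, 999)
    for gen in range(config.max_generations):
        if config.eval_seed_policy == "frozen":
            seeds = [frozen_seed] * config.population_size
        else:
            seeds = [derive_seed(config.seed, gen, i) for i in range(config.population_size)]
        gofs = np.array(
            [fitness(pop[i], seeds[i]) for i in range(config.population_size)]
        )
        if not np.all(np.isfinite(gofs)):
            raise RuntimeError(f"non-finite fitness in generation {gen}")
        gen_best = int(np.argmin(gofs))
        if gofs[gen_best] < best_gof:
            best_gof = float(gofs[gen_best])
            best_delta = pop[gen_best].copy()
        best_hist.append(best_gof)
        mean_hist.append(float(gofs.mean()))

        if len(best_hist) > stall and best_hist[-1 - stall] - best_hist[-1] < config.stall_tolerance:
            halting_reason = "stall_best"
            break
        if len(mean_hist) > stall and abs(mean_hist[-1 - stall] - mean_hist[-1]) < config.stall_tolerance:
            halting_reason = "stall_mean"
            break
        if gen == config.max_generations - 1:
            halting_reason = "max_generations"
            break
        pop, composition = _next_generation(pop, gofs, rng, config)

    assert best_delta is not None
    return FitResult(
        best_delta=best_delta,
        best_gof=best_gof,
        best_fc=None,
        history={"best": np.asarray(best_hist), "mean": np.asarray(mean_hist)},
        halting_reason=halting_reason,
        seed=config.seed,
        composition=composition,
    )


def run_genetic_algorithm(
    M: GroupingMatrix,
    connectome: Connectome,
    omega: np.ndarray,
    target_fc: FCMatrix,
    ga_config: GAConfig | None = None,
    G: float = 0.5,
    sim_config: SimulationConfig | None = None,
    beta: float = 0.04,
    ssim_mode: str = "windowed",
    fitness_fn: Callable[[np.ndarray, int], float] | None = None,
) -> FitResult:
    """Optimize the prior's group coefficients delta by the genetic algorithm.

    The fitness of an individual is :func:`evaluate_fitness` at that delta
    (``fitness_fn`` can substitute a surrogate, e.g. for testing the GA
    mechanics in isolation).  Returns the best-ever delta, its fit distance,
    the simulated FC at that delta, and the per-generation best/mean history.
    """
    ga_config = ga_config or GAConfig()
    sim_config = sim_config or SimulationConfig()
    if fitness_fn is None:

        def fitness_fn(delta: np.ndarray, eval_seed: int) -> float:
            return evaluate_fitness(
                delta,
                M,
                connectome,
                omega,
                G,
                target_fc,
                runs=ga_config.eval_runs_per_individual,
                seed=eval_seed,
                sim_config=sim_config,
                beta=beta,
                ssim_mode=ssim_mode,
            )

        simulate_best = True
    else:
        simulate_best = False

    result = _ga_minimize(fitness_fn, M.n_groups, ga_config)
    if simulate_best:
        result.best_fc = _simulate_fc(
            combine_delta(M, result.best_delta),
            connectome,
            omega,
            G,
            beta,
            sim_config,
            derive_seed(ga_config.seed, 2**20),
        )
    return result


def fit_group(
    M: GroupingMatrix,
    connectome: Connectome,
    omega: np.ndarray,
    target_fc: FCMatrix,
    n_runs: int = 10,
    base_seed: int = 0,
    ga_config: GAConfig | None = None,
    **kwargs,
) -> list[FitResult]:
    """Independent GA runs with derived seeds, for ensemble comparisons.

    Failures of individual runs are logged and skipped; the successful
    results are returned (with a count check left to the caller).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base = ga_config or GAConfig()
    results = []
    for i in range(n_runs):
        cfg = GAConfig(
            population_size=base.population_size,
            elite_fraction=base.elite_fraction,
            crossover_fraction=base.crossover_fraction,
            mutation_fraction=base.mutation_fraction,
            max_generations=base.max_generations,
            stall_generations=base.stall_generations,
            stall_tolerance=base.stall_tolerance,
            eval_runs_per_individual=base.eval_runs_per_individual,
            seed=derive_seed(base_seed, i),
            init_scale=base.init_scale,
            mutation_sigma=base.mutation_sigma,
            bounds=base.bounds,
            eval_seed_policy=base.eval_seed_policy,
        )
        try:
            results.append(run_genetic_algorithm(M, connectome, omega, target_fc, cfg, **kwargs))
        except Exception as exc:  # noqa: BLE001 - run-level isolation
            logger.warning("GA run %d failed: %s", i, exc)
    if not results:
        raise RuntimeError("every GA run failed")
    return results
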