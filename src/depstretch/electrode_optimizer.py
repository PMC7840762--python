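"""Genetic-algorithm search for the electrode geometry maximizing cell elongation.

Six electrode-shape scenarios (the unordered pairings of rectangular,
triangular and elliptical tips) are each optimized over electrode width
``w`` in [5, 50] um and gap ``d`` in [20, 70] um.  The objective, the
reciprocal of the simulated normalized elongation, is minimized by a
real-coded GA: tournament selection, blend crossover, Gaussian mutation
with clipping to bounds, and one elite carried over per generation.  The
elongation landscape is monotone (smaller gap and wider electrodes both
increase the stretch), so the optimum sits at the (w=50, d=20) corner
and the GA's role is to confirm convergence behaviour.

Objective evaluations run the field solve at coarse resolution and are
memoized on (w, d, scenario, resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .elastic_response import ElasticProperties
from .geometry_field import COARSE, ElectrodePair, Resolution
from .pipeline import StretchConfig, simulate_stretch

#: the six tip-shape pairings considered
SIX_SCENARIOS: tuple[tuple[str, str], ...] = (
    ("rectangular", "rectangular"),
    ("rectangular", "triangular"),
    ("rectangular", "elliptical"),
    ("triangular", "triangular"),
    ("triangular", "elliptical"),
    ("elliptical", "elliptical"),
)

#: objective returned when a simulation fails (worse than any finite stretch)
PENALTY = 1e12


@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA settings; defaults are 20 individuals for 10 generations."""

    population: int = 20
    generations: int = 10
    w_bounds_um: tuple[float, float] = (5.0, 50.0)
    d_bounds_um: tuple[float, float] = (20.0, 70.0)
    tournament: int = 3
    crossover_rate: float = 0.9
    blend_alpha: float = 0.5
    mutation_rate: float = 0.2
    mutation_sigma_frac: float = 0.1
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for lo, hi in (self.w_bounds_um, self.d_bounds_um):
            if not lo < hi:
                raise ValueError("bounds must be nonempty intervals")


@dataclass
class GAResult:
    """Best individual, its elongation, and the per-generation best-objective trace."""

    best_w_um: float
    best_d_um: float
    best_objective: float
    best_lstar: float
    history: list[float]
    n_evaluations: int
    evaluated: pd.DataFrame | None = None

    def convergence_after(self, generation: int) -> float:
        """Relative change of the best objective after ``generation`` (1-based)."""
        before = self.history[generation - 1]
        return abs(self.history[-1] - before) / abs(before)


def default_base_config(resolution: Resolution = COARSE) -> StretchConfig:
    """The optimization-study conditions: 8 um cell, 0.1 kPa modulus, 80/120, 10 V."""
    return StretchConfig(
        pair=ElectrodePair(width_um=30.0, gap_um=45.0),
        cell_radius_um=4.0,
        eps_m=80.0,
        eps_c=120.0,
        voltage=10.0,
        props=ElasticProperties(youngs_modulus_pa=100.0),
        resolution=resolution,
        on_overlap="allow",
    )


def objective(
    w_um: float,
    d_um: float,
    scenario: tuple[str, str],
    base_config: StretchConfig | None = None,
    cache: dict | None = None,
) -> float:
    """Reciprocal elongation 1/L* at (w, d) for a shape scenario (minimized).

    Simulation failures return a large penalty instead of raising, so the
    GA can keep moving.  Pass a dict as ``cache`` to memoize evaluations
    on (w, d, scenario, resolution).
    """
    base = base_config or default_base_config()
    key = (round(w_um, 9), round(d_um, 9), scenario, base.resolution)
    if cache is not None and key in cache:
        return cache[key]
    cfg = replace(
        base,
        pair=replace(
            base.pair,
            width_um=w_um,
            gap_um=d_um,
            left_shape=scenario[0],
            right_shape=scenario[1],
        ),
    )
    try:
        lstar = simulate_stretch(cfg).lstar
        value = 1.0 / lstar if lstar > 0 else PENALTY
    except Exception:  # noqa: BLE001 - GA treats failures as penalties
        value = PENALTY
    if cache is not None:
        cache[key] = value
    return value


def ga_optimize(
    scenario: tuple[str, str],
    ga: GAConfig | None = None,
    base_config: StretchConfig | None = None,
) -> GAResult:
    """Seeded, reproducible GA run over (w, d) for one shape scenario."""
    ga = ga or GAConfig()
    base = base_config or default_base_config()
    rng = np.random.default_rng(ga.seed)
    lo = np.array([ga.w_bounds_um[0], ga.d_bounds_um[0]])
    hi = np.array([ga.w_bounds_um[1], ga.d_bounds_um[1]])
    span = hi - lo
    cache: dict = {}
    evals = [0]

    def evaluate(ind: np.ndarray) -> float:
        before = len(cache)
        val = objective(ind[0], ind[1], scenario, base, cache)
        if len(cache) > before:
            evals[0] += 1
        return val

    # the random initial population is generation 1
    pop = lo + rng.random((ga.population, 2)) * span
    fitness = np.array([evaluate(ind) for ind in pop])
    history: list[float] = [float(fitness.min())]

    for _ in range(ga.generations - 1):
        order = np.argsort(fitness)
        elites = pop[order[: ga.elitism]].copy()
        children = list(elites)
        while len(children) < ga.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, ga.tournament)
                parents.append(pop[contenders[np.argmin(fitness[contenders])]])
            p1, p2 = parents
            if rng.random() < ga.crossover_rate:
                # blend (BLX-alpha) crossover
                cmin = np.minimum(p1, p2)
                cmax = np.maximum(p1, p2)
                rng_w = cmax - cmin
                child = rng.uniform(
                    cmin - ga.blend_alpha * rng_w, cmax + ga.blend_alpha * rng_w
                )
            else:
                child = p1.copy()
            mutate = rng.random(2) < ga.mutation_rate
            child = child + mutate * rng.normal(0, ga.mutation_sigma_frac * span)
            children.append(np.clip(child, lo, hi))
        pop = np.array(children[: ga.population])
        fitness = np.array([evaluate(ind) for ind in pop])
        history.append(float(fitness.min()))

    best = int(np.argmin(fitness))
    best_obj = float(fitness[best])
    rows = [
        {"w_um": k[0], "d_um": k[1], "objective": v}
        for k, v in cache.items()
        if k[2] == scenario
    ]
    return GAResult(
        best_w_um=float(pop[best, 0]),
        best_d_um=float(pop[best, 1]),
        best_objective=best_obj,
        best_lstar=1.0 / best_obj if best_obj < PENALTY else 0.0,
        history=history,
        n_evaluations=evals[0],
        evaluated=pd.DataFrame(rows),
    )


def rank_scenarios(
    scenarios=SIX_SCENARIOS,
    *,
    optimized: bool = False,
    ga: GAConfig | None = None,
    base_config: StretchConfig | None = None,
    at_um: tuple[float, float] = (50.0, 20.0),
) -> pd.DataFrame:
    """Rank shape scenarios by their (optimized or corner-point) elongation.

    With ``optimized=False`` every scenario is evaluated at ``at_um``
    (default the large-width/small-gap corner, where the monotone
    landscape peaks); with ``optimized=True`` a GA run per scenario finds
    the evaluation point.  Returns a descending ranking; the ordering is
    independent of the drive voltage, which scales all entries alike.
    """
    scenarios = list(scenarios)
    if len(scenarios) < 1:
        raise ValueError("need at least one scenario")
    base = base_config or default_base_config()
    rows = []
    for scen in scenarios:
        scen = tuple(scen)
        if optimized:
            result = ga_optimize(scen, ga, base)
            w, d, lstar = result.best_w_um, result.best_d_um, result.best_lstar
        else:
            w, d = at_um
            obj = objective(w, d, scen, base)
            lstar = 1.0 / obj if obj < PENALTY else 0.0
        rows.append(
            {
                "left": scen[0],
                "right": scen[1],
                "w_um": w,
                "d_um": d,
                "Lstar": lstar,
            }
        )
    ranking = pd.DataFrame(rows).sort_values("Lstar", ascending=False)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking.reset_index(drop=True)
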