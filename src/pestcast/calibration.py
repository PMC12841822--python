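"""Genetic-algorithm calibration of the ecoclimatic engine to occurrences.

Two agreement objectives are provided.  ``fitness`` is the simple
coverage-minus-overprediction score: the fraction of occurrence cells
rendered suitable (EI > 0) minus a penalty proportional to the
area-weighted fraction of the world rendered suitable.  That score only
sees the *support* of the EI surface, so it cannot identify the optimum
range (DV1, DV2), which shapes EI's magnitude but not where EI > 0.  The
default objective of ``fit_parameters`` is therefore a graded agreement
score: the log-likelihood of the records under intensity-proportional
sampling (records drawn with probability ∝ EI), which rewards high EI
where records are dense and, through its normalizer, penalizes EI mass
elsewhere — overprediction — with no extra weight to tune.

The search is a real-coded GA (tournament selection, uniform crossover,
Gaussian mutation with ordering repair, elitism), optionally followed by a
Nelder–Mead polish of the GA incumbent; stress settings default to
literature-derived fixed values and are not searched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate import MonthlyClimateGrid
from .engine import ClimexParameters, EngineInputs, prepare_engine_inputs, run_weekly
from .mapping import grid_cell_areas
from .occurrences import OccurrenceSet

__all__ = ["GAConfig", "FitResult", "fitness", "fit_parameters", "repair", "DEFAULT_BOUNDS"]

#: search bounds for the parameters freed by default
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "DV0": (-30.0, 10.0),
    "DV1": (-5.0, 25.0),
    "DV2": (5.0, 35.0),
    "DV3": (25.0, 55.0),
    "SM0": (0.0, 0.3),
    "SM1": (0.1, 1.0),
    "SM2": (0.4, 1.4),
    "SM3": (0.8, 2.0),
}

_ORDER_GROUPS = (("DV0", "DV1", "DV2", "DV3"), ("SM0", "SM1", "SM2", "SM3"))


@dataclass
class GAConfig:
    """GA settings; ``objective`` is "loglik" (graded agreement, default) or
    "coverage" (binary coverage minus area penalty)."""

    population_size: int = 30
    generations: int = 40
    mutation_rate: float = 0.25
    crossover_rate: float = 0.7
    parameter_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    seed: int = 0
    train_fraction: float = 0.75
    penalty_weight: float = 0.3
    objective: str = "loglik"
    polish: bool = True
    base_parameters: ClimexParameters = field(default_factory=ClimexParameters)

    def __post_init__(self) -> None:
        if not (0 < self.mutation_rate < 1 and 0 < self.crossover_rate < 1):
            raise ValueError("mutation and crossover rates must lie in (0, 1)")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        for name, (lo, hi) in self.parameter_bounds.items():
            if not lo <= hi:
                raise ValueError(f"bounds for {name} are reversed ({lo} > {hi})")


@dataclass
class FitResult:
    best_parameters: ClimexParameters
    fitness_trace: np.ndarray
    train_coverage: float
    test_coverage: float
    overprediction: float


def repair(values: dict[str, float]) -> dict[str, float]:
    """Restore threshold ordering (DV0≤…≤DV3, SM0≤…≤SM3) by sorting each
    group in place; idempotent on already-ordered vectors."""
    out = dict(values)
    for group in _ORDER_GROUPS:
        present = [g for g in group if g in out]
        if len(present) > 1:
            ordered = sorted(out[g] for g in present)
            for g, v in zip(present, ordered):
                out[g] = v
    return out


def _nearest_index(axis: np.ndarray, coords: np.ndarray) -> np.ndarray:
    step = axis[1] - axis[0] if axis.size > 1 else 1.0
    return np.clip(np.round((coords - axis[0]) / step).astype(int), 0, axis.size - 1)


def _occurrence_cells(occurrences: OccurrenceSet, inputs: EngineInputs) -> np.ndarray:
    """Column indices (into the valid-cell stack) of each occurrence; drops
    records falling on nodata cells."""
    flat_index = np.full(inputs.valid.shape, -1, dtype=int)
    flat_index[inputs.valid] = np.arange(int(inputs.valid.sum()))
    ilat = _nearest_index(inputs.lat_axis, occurrences.lat)
    ilon = _nearest_index(inputs.lon_axis, occurrences.lon)
    cols = flat_index[ilat, ilon]
    return cols[cols >= 0]


def fitness(
    p: ClimexParameters,
    occurrences: OccurrenceSet,
    climate: MonthlyClimateGrid | EngineInputs,
    penalty_weight: float = 0.3,
) -> float:
    """Coverage-minus-overprediction score of a parameter set.

    score = coverage − penalty_weight · suitable_area_fraction, where
    coverage is the fraction of occurrence cells with EI > 0 and the area
    fraction is weighted by true (latitude-dependent) cell areas.
    """
    inputs = climate if isinstance(climate, EngineInputs) else prepare_engine_inputs(climate)
    if len(occurrences) == 0:
        raise ValueError("fitness requires at least one occurrence record")
    cols = _occurrence_cells(occurrences, inputs)
    if cols.size == 0:
        raise ValueError("no occurrence falls on a valid climate cell")
    ei = run_weekly(inputs.tavg, inputs.moisture, p).EI
    suitable = ei > 0
    coverage = float(suitable[cols].mean())
    w = grid_cell_areas(inputs.lat_axis, inputs.lon_axis)[inputs.valid]
    area_fraction = float(w[suitable].sum() / w.sum())
    return coverage - penalty_weight * area_fraction


#: floor added inside the log so empty cells score finitely; EI is on 0–100
_LOG_EPS = 1e-3


def occurrence_loglik(
    p: ClimexParameters, cols: np.ndarray, inputs: EngineInputs
) -> float:
    """Mean log-likelihood of records drawn with probability ∝ EI.

    score = mean_occ log(EI + ε) − log(mean_cells EI + ε); the normalizer
    makes the score scale-free and penalizes suitability predicted far from
    any record.
    """
    ei = run_weekly(inputs.tavg, inputs.moisture, p).EI
    return float(np.log(ei[cols] + _LOG_EPS).mean() - np.log(ei.mean() + _LOG_EPS))


def fit_parameters(
    config: GAConfig,
    occurrences: OccurrenceSet,
    climate: MonthlyClimateGrid | EngineInputs,
) -> FitResult:
    """Fit the freed engine parameters to presence records with a real-coded GA.

    Tournament selection (size 2), uniform crossover, Gaussian mutation
    clipped to bounds, ordering repair after every variation, and elitism
    (the incumbent best survives unchanged), all driven by ``config.seed``.
    75% of the records (by default) train the objective; the held-out rest
    report an independent coverage.
    """
    inputs = climate if isinstance(climate, EngineInputs) else prepare_engine_inputs(climate)
    presences = occurrences.presences
    if len(presences) < 5:
        raise ValueError("need at least 5 presence records on valid cells")
    rng = np.random.default_rng(config.seed)
    names = list(config.parameter_bounds.keys())
    lo = np.array([config.parameter_bounds[n][0] for n in names])
    hi = np.array([config.parameter_bounds[n][1] for n in names])

    all_cols = _occurrence_cells(presences, inputs)
    if all_cols.size < 5:
        raise ValueError("need at least 5 presence records on valid cells")
    perm = rng.permutation(all_cols.size)
    n_train = max(1, int(round(config.train_fraction * all_cols.size)))
    train_cols = all_cols[perm[:n_train]]
    test_cols = all_cols[perm[n_train:]]

    def to_params(vec: np.ndarray) -> ClimexParameters:
        vals = repair(dict(zip(names, vec.tolist())))
        return config.base_parameters.replace(**vals)

    if config.objective == "loglik":
        def score(vec: np.ndarray) -> float:
            return occurrence_loglik(to_params(vec), train_cols, inputs)
    elif config.objective == "coverage":
        w_area = grid_cell_areas(inputs.lat_axis, inputs.lon_axis)[inputs.valid]

        def score(vec: np.ndarray) -> float:
            ei = run_weekly(inputs.tavg, inputs.moisture, to_params(vec)).EI
            suitable = ei > 0
            cov = float(suitable[train_cols].mean())
            return cov - config.penalty_weight * float(w_area[suitable].sum() / w_area.sum())
    else:
        raise ValueError(f"unknown objective {config.objective!r}")

    pop = lo + rng.random((config.population_size, len(names))) * (hi - lo)
    fit = np.array([score(v) for v in pop])
    best_idx = int(np.argmax(fit))
    best_vec, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    trace = [best_fit]

    for _ in range(config.generations):
        children = np.empty_like(pop)
        for c in range(config.population_size):
            # tournament selection, size 2
            a, b = rng.integers(config.population_size, size=2)
            pa = pop[a] if fit[a] >= fit[b] else pop[b]
            a, b = rng.integers(config.population_size, size=2)
            pb = pop[a] if fit[a] >= fit[b] else pop[b]
            child = pa.copy()
            if rng.random() < config.crossover_rate:
                swap = rng.random(len(names)) < 0.5
                child[swap] = pb[swap]
            mutate = rng.random(len(names)) < config.mutation_rate
            child[mutate] += rng.normal(0.0, 0.1 * (hi - lo)[mutate])
            children[c] = np.clip(child, lo, hi)
        pop = children
        fit = np.array([score(v) for v in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_vec = pop[gen_best].copy()
        else:  # elitism: reinstate incumbent over the worst child
            worst = int(np.argmin(fit))
            pop[worst] = best_vec
            fit[worst] = best_fit
        trace.append(best_fit)

    if config.polish and config.generations > 0:
        from scipy.optimize import minimize

        # local refinement from several deterministic starts: the GA
        # incumbent, the template (base) parameter vector, and the bounds
        # midpoint — NM from a single start can stall in a nearby basin
        base_vec = np.clip(
            np.array([getattr(config.base_parameters, n) for n in names]), lo, hi
        )
        starts = [best_vec.copy(), base_vec, 0.5 * (lo + hi)]
        for x0 in starts:
            res = minimize(
                lambda v: -score(np.clip(v, lo, hi)),
                x0,
                method="Nelder-Mead",
                options={"maxfev": 500 * len(names), "xatol": 1e-4, "fatol": 1e-10},
            )
            if -res.fun > best_fit:
                best_vec, best_fit = np.clip(res.x, lo, hi), float(-res.fun)
        trace.append(best_fit)

    best_params = to_params(best_vec)
    ei = run_weekly(inputs.tavg, inputs.moisture, best_params).EI
    suitable = ei > 0
    occupied = np.zeros_like(suitable)
    occupied[all_cols] = True
    overpred = float((suitable & ~occupied).sum() / max(1, suitable.sum()))
    return FitResult(
        best_parameters=best_params,
        fitness_trace=np.asarray(trace),
        train_coverage=float(suitable[train_cols].mean()),
        test_coverage=float(suitable[test_cols].mean()) if test_cols.size else float("nan"),
        overprediction=overpred,
    )
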