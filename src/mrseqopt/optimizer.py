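"""Evolutionary sequence optimization with penalty fitness and repair.

Candidates are real-valued genomes in [0, 1]^10, affinely mapped onto the
ranges the training grid spans for the 10 numeric sequence parameters.  A
decoded candidate is *repaired* before evaluation: the refocussing angle is
rounded to recover the echo type, the EPI factor to recover the readout
type, every parameter snaps to the nearest admissible grid value of the
recovered family, and an infeasible TE/TR pair is replaced by the nearest
feasible grid pair (values beyond the family maximum clamp to the largest
pair).  Fitness follows the penalty construction

    fitness(x) = p_goal(x) - sum_i ps_i(x) - sum_j pv_j(x)

with the goal prediction negated for minimization, a constant penalty per
violated strict constraint, a penalty proportional to |p_goal| per violated
vague constraint, and — for the artifact metrics ghost/motion/distortion —
an exponential penalty exp(a * (p_m - c_m)) in the degree of violation.
The loop uses tournament selection with elitism, line crossover
(probability 0.1) and per-gene Gaussian mutation (probability 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from . import sequence_engine
from .dataset import NUMERIC_COLUMNS, TRAINING_GRID, spec_to_vector, vector_to_spec
from .dsl import METRIC_NAMES, NumericConstraint, OptimizationProblem, SequenceSpec
from .metrics import METRIC_FIELDS
from .surrogate import SurrogateModel, predict_batch

__all__ = [
    "FitnessConfig",
    "EAConfig",
    "OptimizationResult",
    "gene_ranges",
    "decode",
    "repair",
    "fitness",
    "evolve",
    "evolve_genomes",
]


@dataclass(frozen=True)
class FitnessConfig:
    strict_penalty: float = 1000.0  # constant per violated strict constraint
    vague_fraction: float = 0.1  # of |goal prediction|, per violated vague one
    artifact_factor: float = 50.0  # a in exp(a * violation)
    goal_scale: float = 1.0  # divides the goal prediction (for time goals)
    relation_tolerance: float = 1e-9


@dataclass(frozen=True)
class EAConfig:
    population: int = 50
    generations: int = 100
    crossover_prob: float = 0.1
    mutation_prob: float = 0.9
    mutation_step: float = 0.1  # std of the Gaussian step, in gene units
    mutation_per_gene: Optional[float] = None  # gene flip rate; None = 1/n_genes
    elite: int = 2
    tournament: int = 3
    crossover_extension: float = 0.1  # line crossover samples u in [-e, 1+e]
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class OptimizationResult:
    best_spec: SequenceSpec
    best_vector: dict
    best_fitness: float
    best_predictions: Dict[str, float]
    trace: np.ndarray  # per-generation best fitness (non-decreasing)
    seed: int


# --------------------------------------------------------------------------
# genome <-> sequence vector
# --------------------------------------------------------------------------


def gene_ranges(grid_cfg: Optional[dict] = None) -> List[Tuple[float, float]]:
    """[min, max] per numeric parameter, spanning the training grid."""
    grid_cfg = grid_cfg or TRAINING_GRID
    ranges = []
    for col in NUMERIC_COLUMNS:
        values = [v for params in grid_cfg.values() for v in params[col]]
        ranges.append((float(min(values)), float(max(values))))
    return ranges


def decode(genome: np.ndarray, ranges: List[Tuple[float, float]]) -> dict:
    """Affine map of a [0,1] genome onto raw (unrepaired) parameter values."""
    return {
        col: lo + float(g) * (hi - lo)
        for col, g, (lo, hi) in zip(NUMERIC_COLUMNS, genome, ranges)
    }


def _nearest(value: float, options) -> float:
    options = list(options)
    return min(options, key=lambda opt: (abs(opt - value), opt))


def repair(decoded: dict, grid_cfg: Optional[dict] = None) -> SequenceSpec:
    """Project a raw decoded candidate onto the nearest valid grid sequence."""
    grid_cfg = grid_cfg or TRAINING_GRID
    refoc_options = sorted(
        {v for params in grid_cfg.values() for v in params["refocussing_angle"]} | {0.0}
    )
    epi_options = sorted(
        {v for params in grid_cfg.values() for v in params["epi_factor"]} | {1}
    )
    refoc = _nearest(float(decoded["refocussing_angle"]), refoc_options)
    epi_raw = _nearest(float(decoded["epi_factor"]), epi_options)
    echo = "SpinEcho" if refoc > 0 else "GradientEcho"
    readout = "LineReadout" if epi_raw <= 1 else "EPIReadout"
    family = {
        ("SpinEcho", "LineReadout"): "RARE",
        ("SpinEcho", "EPIReadout"): "SE-EPI",
        ("GradientEcho", "EPIReadout"): "EPI",
        ("GradientEcho", "LineReadout"): "bSSFP",
    }[(echo, readout)]
    params = grid_cfg[family]

    vec = {"echo_type": echo, "readout_type": readout}
    matrix = _nearest(float(decoded["matrix"]), params["matrix"])
    vec["matrix"] = matrix
    for col in ("readout_duration", "excitation_angle", "refocussing_angle",
                "measurements", "prescans"):
        vec[col] = _nearest(float(decoded[col]), params[col])
    # echo-train lengths must divide the matrix
    for col in ("etl", "epi_factor"):
        options = [v for v in params[col] if matrix % v == 0] or list(params[col])
        vec[col] = _nearest(float(decoded[col]), options)

    # TE/TR: nearest feasible grid pair for this family (clamps from above)
    te_values, tr_values = params["te"], params["tr"]
    vec["te"] = _nearest(float(decoded["te"]), te_values)
    vec["tr"] = _nearest(float(decoded["tr"]), tr_values)
    spec = vector_to_spec(vec)
    if not sequence_engine.validate(spec).valid:
        te_span = max(te_values) - min(te_values) or 1.0
        tr_span = max(tr_values) - min(tr_values) or 1.0
        best, best_dist = None, np.inf
        for te in te_values:
            for tr in tr_values:
                candidate = vector_to_spec({**vec, "te": te, "tr": tr})
                if not sequence_engine.validate(candidate).valid:
                    continue
                dist = (
                    ((te - decoded["te"]) / te_span) ** 2
                    + ((tr - decoded["tr"]) / tr_span) ** 2
                )
                if dist < best_dist:
                    best, best_dist = candidate, dist
        if best is None:
            raise ValueError(f"no feasible TE/TR grid pair for family {family}")
        spec = best
    return spec


# --------------------------------------------------------------------------
# fitness
# --------------------------------------------------------------------------


def _violated(value: float, constraint: NumericConstraint, rhs: float, tol: float) -> bool:
    # strict inequalities: a prediction exactly at the bound counts as
    # violated (the artifact penalty is exp(0) = 1 there)
    if constraint.relation == "lt":
        return value >= rhs - tol
    if constraint.relation == "gt":
        return value <= rhs + tol
    return abs(value - rhs) > tol * max(1.0, abs(rhs))


def _resolve(name_or_number, predictions: Dict[str, float], vector: dict) -> float:
    if isinstance(name_or_number, (int, float)):
        return float(name_or_number)
    if name_or_number in METRIC_NAMES:
        return predictions[name_or_number]
    return float(vector[name_or_number])


def _fitness_from_predictions(
    predictions: Dict[str, float],
    vector: dict,
    problem: OptimizationProblem,
    cfg: FitnessConfig,
) -> float:
    goal = predictions[problem.goal_metric] / cfg.goal_scale
    value = goal if problem.direction == "maximize" else -goal
    fit = value
    for constraint in problem.strict:
        lhs = _resolve(constraint.lhs, predictions, vector)
        rhs = _resolve(constraint.rhs, predictions, vector)
        if _violated(lhs, constraint, rhs, cfg.relation_tolerance):
            fit -= cfg.strict_penalty
    for constraint in problem.vague:
        lhs = _resolve(constraint.lhs, predictions, vector)
        rhs = _resolve(constraint.rhs, predictions, vector)
        if _violated(lhs, constraint, rhs, cfg.relation_tolerance):
            if constraint.artifact:
                degree = lhs - rhs if constraint.relation == "lt" else rhs - lhs
                fit -= float(np.exp(cfg.artifact_factor * degree))
            else:
                fit -= cfg.vague_fraction * abs(value)
    return float(fit)


def fitness(
    genome: np.ndarray,
    problem: OptimizationProblem,
    models: Dict[str, SurrogateModel],
    cfg: FitnessConfig = FitnessConfig(),
    ranges: Optional[List[Tuple[float, float]]] = None,
    grid_cfg: Optional[dict] = None,
) -> float:
    """Penalty fitness of one genome (repaired before prediction)."""
    ranges = ranges or gene_ranges(grid_cfg)
    spec = repair(decode(np.asarray(genome, float), ranges), grid_cfg)
    vector = spec_to_vector(spec)
    x = np.array([[float(vector[c]) for c in NUMERIC_COLUMNS]])
    raw = predict_batch(models, x)
    predictions = {name: float(raw[METRIC_FIELDS[name]][0]) for name in METRIC_NAMES}
    return _fitness_from_predictions(predictions, vector, problem, cfg)


# --------------------------------------------------------------------------
# the evolutionary loop
# --------------------------------------------------------------------------


def evolve_genomes(
    fitness_fn: Callable[[np.ndarray], np.ndarray],
    n_genes: int,
    cfg: EAConfig,
) -> Tuple[np.ndarray, float, np.ndarray]:
    """Generic EA over [0,1]^n with elitism; returns (best, fitness, trace).

    ``fitness_fn`` maps a (pop, n_genes) matrix to a (pop,) fitness vector
    (larger is better).
    """
    rng = np.random.default_rng(cfg.seed)
    pop = rng.uniform(size=(cfg.population, n_genes))
    fit = np.asarray(fitness_fn(pop), dtype=float)
    trace = np.empty(cfg.generations)
    best_idx = int(np.argmax(fit))
    best, best_fit = pop[best_idx].copy(), float(fit[best_idx])

    def tournament() -> np.ndarray:
        contenders = rng.integers(0, cfg.population, size=cfg.tournament)
        return pop[contenders[np.argmax(fit[contenders])]]

    for gen in range(cfg.generations):
        elite_idx = np.argsort(fit)[::-1][: cfg.elite]
        offspring = [pop[i].copy() for i in elite_idx]
        while len(offspring) < cfg.population:
            child = tournament().copy()
            if rng.uniform() < cfg.crossover_prob:
                mate = tournament()
                u = rng.uniform(-cfg.crossover_extension, 1 + cfg.crossover_extension)
                child = child + u * (mate - child)
            if rng.uniform() < cfg.mutation_prob:
                rate = cfg.mutation_per_gene or 1.0 / n_genes
                genes = rng.uniform(size=n_genes) < rate
                if not genes.any():
                    genes[rng.integers(n_genes)] = True
                child = child + genes * rng.normal(0.0, cfg.mutation_step, size=n_genes)
            offspring.append(np.clip(child, 0.0, 1.0))
        pop = np.asarray(offspring)
        fit = np.asarray(fitness_fn(pop), dtype=float)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fit[gen_best])
        trace[gen] = best_fit
    return best, best_fit, trace


def evolve(
    problem: OptimizationProblem,
    models: Dict[str, SurrogateModel],
    ea_cfg: EAConfig = EAConfig(),
    fit_cfg: FitnessConfig = FitnessConfig(),
    grid_cfg: Optional[dict] = None,
) -> OptimizationResult:
    """Optimize a translated requirement against the trained surrogates."""
    ranges = gene_ranges(grid_cfg)

    def batch_fitness(pop: np.ndarray) -> np.ndarray:
        specs = [repair(decode(g, ranges), grid_cfg) for g in pop]
        vectors = [spec_to_vector(s) for s in specs]
        X = np.array([[float(v[c]) for c in NUMERIC_COLUMNS] for v in vectors])
        raw = predict_batch(models, X)
        out = np.empty(len(pop))
        for i, vector in enumerate(vectors):
            predictions = {
                name: float(raw[METRIC_FIELDS[name]][i]) for name in METRIC_NAMES
            }
            out[i] = _fitness_from_predictions(predictions, vector, problem, fit_cfg)
        return out

    best_genome, best_fit, trace = evolve_genomes(
        batch_fitness, len(NUMERIC_COLUMNS), ea_cfg
    )
    best_spec = repair(decode(best_genome, ranges), grid_cfg)
    vector = spec_to_vector(best_spec)
    X = np.array([[float(vector[c]) for c in NUMERIC_COLUMNS]])
    raw = predict_batch(models, X)
    predictions = {name: float(raw[METRIC_FIELDS[name]][0]) for name in METRIC_NAMES}
    return OptimizationResult(
        best_spec=best_spec,
        best_vector=vector,
        best_fitness=best_fit,
        best_predictions=predictions,
        trace=trace,
        seed=ea_cfg.seed,
    )
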