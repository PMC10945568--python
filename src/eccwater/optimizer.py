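"""Three-phase parameter search: random-walk seeding, differential evolution
with surrogate gating, and surrogate-guided refinement.

The loop mirrors an automated force-field optimization campaign:

1. a bounded *random walk* sparsely samples the parameter box and seeds the
   population (each step also hands the previous evaluation's state to the
   evaluator as a warm start, which a real MD evaluator can use as its
   starting configuration);
2. *differential evolution* proposes candidates as linear combinations of
   elite population members; when enough true evaluations have accumulated
   a neural surrogate is (re)trained on all of them and candidates whose
   predicted cost exceeds a threshold skip the expensive evaluation;
3. a short *refinement* phase proposes minimizers of the surrogate found by
   multi-start coordinate-wise line search, each truly evaluated.

Everything is reproducible under a single master seed, and every proposed
candidate — evaluated, gated away, or failed — lands in an append-only
ledger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd

from .cost import (CostValue, CostWeights, DEFAULT_WEIGHTS, PropertyResult,
                   VARIANT_ECC, cost as compute_cost, is_better)
from .mapper import (MapperConfig, SkipDecision, TrainingSet, should_skip,
                     train_mapper)
from .reference_data import ReferenceSet
from .watermodel import (DEFAULT_BOUNDS, INITIAL_GUESS, ParameterBounds,
                         WaterModelParams, denormalize_params,
                         normalize_params)

__all__ = [
    "Candidate",
    "Population",
    "OptimizerConfig",
    "OptimizerState",
    "random_walk_step",
    "de_propose",
    "accept_candidate",
    "refine",
    "run_optimization",
]

Evaluator = Callable[..., Dict[str, PropertyResult]]


@dataclass
class Candidate:
    """One proposed parameter set with its evaluation bookkeeping."""

    params: WaterModelParams
    x: np.ndarray                       # normalized 6-vector
    provenance: str                     # rw | de | refine | seed
    state: str = "pending"              # pending | evaluated | skipped | failed
    cost: Optional[CostValue] = None
    predicted_cost: Optional[float] = None
    iteration: int = -1

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)

    @property
    def evaluated(self) -> bool:
        return self.state == "evaluated" and self.cost is not None


class Population:
    """Bounded pool of the best evaluated candidates, sortable by cost."""

    def __init__(self, capacity: int = 64):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.members: List[Candidate] = []

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> List[Candidate]:
        return sorted(self.members, key=lambda c: c.cost.total)

    def best(self) -> Candidate:
        return min(self.members, key=lambda c: c.cost.total)

    def worst(self) -> Candidate:
        return max(self.members, key=lambda c: c.cost.total)


def accept_candidate(candidate: Candidate, population: Population) -> Population:
    """Admit ``candidate`` iff it strictly improves on the worst retained member.

    Under capacity every evaluated candidate is admitted; at capacity the
    worst member is evicted only on strict improvement (ties keep the
    incumbent).
    """
    if not candidate.evaluated:
        raise ValueError("only evaluated candidates can enter the population")
    if len(population) < population.capacity:
        population.members.append(candidate)
        return population
    worst = population.worst()
    if is_better(candidate.cost, worst.cost):
        population.members.remove(worst)
        population.members.append(candidate)
    return population


def random_walk_step(
    current: Candidate,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    step_scale: float = 0.02,
    rng: Optional[np.random.Generator] = None,
) -> Candidate:
    """One reflected random-walk step in normalized space.

    Each coordinate moves by a uniform perturbation of ±``step_scale``
    (fractions of the parameter range) and is reflected at the box faces,
    so the walk never leaves the bounds.
    """
    if not (0 < step_scale < 1):
        raise ValueError("step_scale must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    x = current.x + rng.uniform(-step_scale, step_scale, size=current.x.shape)
    # reflect into [0, 1]
    x = np.abs(x)
    x = 1.0 - np.abs(1.0 - x)
    x = np.clip(x, 0.0, 1.0)
    return Candidate(params=denormalize_params(x, bounds), x=x, provenance="rw")


@dataclass(frozen=True)
class DEParams:
    F: float = 0.7
    CR: float = 0.7
    elite_fraction: float = 0.25
    #: half-width of the uniform dither on F (0 disables); dithering the
    #: amplification factor is the standard guard against the difference
    #: vectors collapsing prematurely on smooth landscapes
    dither: float = 0.25


def de_propose(
    population: Population,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    de_params: DEParams = DEParams(),
    rng: Optional[np.random.Generator] = None,
) -> Candidate:
    """Differential-evolution proposal from the elite of the population.

    Mutation ``x_a + F (x_b - x_c)`` with a, b, c distinct members of the
    elite (best ``elite_fraction`` of the population) and F dithered
    uniformly, binomial crossover with probability ``CR`` against a member
    drawn from the better half of the population (diversity injection that
    does not resurrect long-evicted search regions), then clipping to the
    unit cube.
    """
    if len(population) < 4:
        raise ValueError("differential evolution needs a population of at least 4")
    rng = rng if rng is not None else np.random.default_rng()
    ranked = population.sorted_members()
    n_elite = max(3, math.ceil(de_params.elite_fraction * len(ranked)))
    elite = ranked[:min(n_elite, len(ranked))]

    if len(elite) >= 3:
        a, b, c = (elite[i] for i in rng.choice(len(elite), size=3, replace=False))
    else:  # tiny populations: fall back to whole-population draws
        a, b, c = (ranked[i] for i in rng.choice(len(ranked), size=3, replace=False))
    F = de_params.F
    if de_params.dither > 0:
        F = rng.uniform(F - de_params.dither, F + de_params.dither)
    mutant = a.x + F * (b.x - c.x)

    half = max(4, len(ranked) // 2)
    target = ranked[int(rng.integers(min(half, len(ranked))))]
    cross = rng.random(mutant.shape) < de_params.CR
    cross[int(rng.integers(mutant.shape[0]))] = True  # guarantee one mutant coord
    x = np.where(cross, mutant, target.x)
    x = np.clip(x, 0.0, 1.0)
    return Candidate(params=denormalize_params(x, bounds), x=x, provenance="de")


def refine(
    surrogate,
    population: Population,
    bounds: ParameterBounds = DEFAULT_BOUNDS,
    rng: Optional[np.random.Generator] = None,
    n_starts: int = 4,
    sweeps: int = 3,
    grid: int = 33,
    zoom_levels: int = 3,
    zoom_factor: float = 0.12,
) -> Candidate:
    """Propose the surrogate minimizer found by multi-start coordinate search.

    Starts from elite members (plus jittered copies when more starts are
    requested than elites exist) and alternates coordinate-wise line
    searches, first on a uniform grid spanning [0, 1] and then on
    successively zoomed windows around the running best, so the final
    resolution is far below the coarse grid spacing.  The best point over
    all starts is returned as a pending candidate for true evaluation.
    """
    if not getattr(surrogate, "trained", False):
        raise ValueError("refinement requires a trained surrogate")
    rng = rng if rng is not None else np.random.default_rng()
    ranked = population.sorted_members() if len(population) else []
    starts: List[np.ndarray] = [c.x.copy() for c in ranked[:n_starts]]
    while len(starts) < n_starts:
        base = starts[0] if starts else rng.random(6)
        starts.append(np.clip(base + rng.normal(0, 0.1, size=6), 0.0, 1.0))

    best_x, best_pred = None, math.inf
    for x0 in starts:
        x = x0.copy()
        half_width = 0.5
        for level in range(zoom_levels):
            for _ in range(sweeps):
                for j in range(x.shape[0]):
                    lo = max(0.0, x[j] - half_width)
                    hi = min(1.0, x[j] + half_width)
                    line = np.linspace(lo, hi, grid)
                    trial = np.repeat(x[None, :], grid, axis=0)
                    trial[:, j] = line
                    preds = surrogate.predict(trial)
                    x[j] = line[int(np.argmin(preds))]
            half_width *= zoom_factor
        pred = float(surrogate.predict(x[None, :])[0])
        if pred < best_pred:
            best_pred, best_x = pred, x
    cand = Candidate(params=denormalize_params(best_x, bounds), x=best_x,
                     provenance="refine")
    cand.predicted_cost = best_pred
    return cand


@dataclass
class OptimizerConfig:
    """Knobs of the three-phase search (defaults are the study conditions)."""

    bounds: ParameterBounds = field(default_factory=lambda: DEFAULT_BOUNDS)
    start: WaterModelParams = field(default_factory=lambda: INITIAL_GUESS)
    rw_count: int = 1000
    rw_step_scale: float = 0.02
    de_params: DEParams = field(default_factory=DEParams)
    population_capacity: int = 96
    gate_threshold: Optional[float] = 0.7   # None disables the gate
    #: fraction of gate-rejected candidates evaluated anyway; this is how
    #: wrongly rejected regions get re-sampled and the surrogate corrected
    gate_exploration: float = 0.1
    #: the working bar is max(gate_threshold, gate_kappa * current best):
    #: until the search has actually reached the absolute quality band the
    #: gate only discards candidates predicted much worse than the best
    #: point found so far, so correct predictions cannot wall off the
    #: approach path to that band
    gate_kappa: float = 1.75
    retrain_every: int = 25
    #: also retrain after this many proposals even if few true evaluations
    #: arrived (skip-heavy stretches otherwise freeze a bad fit in place;
    #: the refit sees the same data but a fresh initialization)
    retrain_every_proposals: int = 150
    refine_count: int = 10
    variant: str = VARIANT_ECC
    stagnation_window: int = 500
    stagnation_tol: float = 0.01
    mapper: MapperConfig = field(default_factory=MapperConfig)
    seed: int = 0


@dataclass
class OptimizerState:
    """Counters, history and artifacts of one optimization run."""

    phase: str = "rw"
    n_proposed: int = 0
    n_evaluated: int = 0
    n_skipped: int = 0
    n_failed: int = 0
    best_history: List[float] = field(default_factory=list)
    population: Population = field(default_factory=Population)
    surrogate: object = None
    ledger: List[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def best_cost(self) -> Optional[float]:
        return self.best_history[-1] if self.best_history else None

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ledger)

    def write_ledger(self, path) -> None:
        self.ledger_frame().to_csv(path, index=False)


_PARAM_COLS = ("sigma", "epsilon", "q_H", "d_OH", "d_OM", "theta")


def _log(state: OptimizerState, cand: Candidate, phase: str) -> None:
    row = {"iteration": cand.iteration, "phase": phase, "provenance": cand.provenance,
           "state": cand.state}
    for name, value in zip(_PARAM_COLS, cand.params.as_array()):
        row[name] = value
    for j, value in enumerate(cand.x):
        row[f"x{j}"] = value
    row["predicted_cost"] = cand.predicted_cost
    row["cost"] = cand.cost.total if cand.cost is not None else None
    row["best_cost"] = state.best_history[-1] if state.best_history else None
    state.ledger.append(row)


def run_optimization(
    evaluator: Evaluator,
    reference: Optional[ReferenceSet] = None,
    weights: CostWeights = DEFAULT_WEIGHTS,
    budget: int = 2000,
    config: Optional[OptimizerConfig] = None,
) -> OptimizerState:
    """Run the full RW → DE(+gate) → refine loop within a proposal budget.

    ``budget`` counts *proposals*; with the gate disabled every proposal is
    truly evaluated, with the gate enabled skipped proposals consume budget
    but no evaluation.  The run stops early when the best cost has improved
    by less than ``stagnation_tol`` (relative) over ``stagnation_window``
    consecutive proposals.

    Evaluator failures (exceptions) mark the candidate failed and the loop
    continues — an automated campaign must survive individual crashes.
    """
    config = config if config is not None else OptimizerConfig()
    reference = reference if reference is not None else ReferenceSet.default()
    rng = np.random.default_rng(config.seed)
    mapper_seed_stream = np.random.default_rng(rng.integers(2**31))

    state = OptimizerState(seed=config.seed)
    state.population = Population(capacity=config.population_capacity)

    evals_since_train = 0
    proposals_since_train = 0
    training_rows_X: List[np.ndarray] = []
    training_rows_y: List[float] = []
    warm_start: Dict[str, object] = {"configuration": None}
    stagnation_anchor: Optional[tuple] = None  # (n_evaluated, best_cost)

    def _true_evaluate(cand: Candidate) -> None:
        nonlocal evals_since_train
        cand.iteration = state.n_proposed
        try:
            results = evaluator(cand.params, warm_start=warm_start["configuration"])
        except Exception:
            cand.state = "failed"
            state.n_failed += 1
            return
        warm_start["configuration"] = cand.params  # hook for warm-startable evaluators
        cand.cost = compute_cost(results, reference, weights, variant=config.variant)
        cand.state = "evaluated"
        state.n_evaluated += 1
        evals_since_train += 1
        training_rows_X.append(cand.x.copy())
        training_rows_y.append(cand.cost.total)
        accept_candidate(cand, state.population)

    def _push_best() -> None:
        best = (state.population.best().cost.total if len(state.population) else math.inf)
        state.best_history.append(best)

    def _stagnated() -> bool:
        nonlocal stagnation_anchor
        if not state.best_history or not math.isfinite(state.best_history[-1]):
            return False
        current = state.best_history[-1]
        # the clock counts true evaluations: a skipped proposal adds no
        # information about convergence and must not run it down
        if stagnation_anchor is None:
            stagnation_anchor = (state.n_evaluated, current)
            return False
        anchor_n, anchor_cost = stagnation_anchor
        if current < anchor_cost * (1.0 - config.stagnation_tol):
            stagnation_anchor = (state.n_evaluated, current)
            return False
        return state.n_evaluated - anchor_n >= config.stagnation_window

    def _maybe_retrain(force: bool = False) -> None:
        nonlocal evals_since_train, proposals_since_train
        if len(training_rows_y) < config.mapper.min_rows:
            return
        due = (evals_since_train >= config.retrain_every
               or (proposals_since_train >= config.retrain_every_proposals
                   and evals_since_train > 0))
        if not (force or due):
            return
        data = TrainingSet(X=np.array(training_rows_X), y=np.array(training_rows_y))
        seed = int(mapper_seed_stream.integers(2**31))
        state.surrogate = train_mapper(data, replace(config.mapper, seed=seed))
        evals_since_train = 0
        proposals_since_train = 0

    # --- phase 1: random walk seeding ---
    state.phase = "rw"
    x0 = normalize_params(config.start, config.bounds)
    current = Candidate(params=config.start, x=x0, provenance="seed")
    n_rw = min(config.rw_count, budget)
    for _ in range(n_rw):
        cand = random_walk_step(current, config.bounds, config.rw_step_scale, rng)
        state.n_proposed += 1
        _true_evaluate(cand)
        _push_best()
        _log(state, cand, "rw")
        if cand.state == "evaluated":
            current = cand  # the walk continues from the evaluated point

    # --- phase 2: differential evolution with the mapper gate ---
    state.phase = "de"
    de_budget = max(0, budget - state.n_proposed - config.refine_count)
    for _ in range(de_budget):
        if len(state.population) < 4:
            cand = random_walk_step(current, config.bounds, config.rw_step_scale, rng)
        else:
            cand = de_propose(state.population, config.bounds, config.de_params, rng)
        state.n_proposed += 1
        proposals_since_train += 1
        cand.iteration = state.n_proposed

        if config.gate_threshold is not None:
            _maybe_retrain()
            bar = config.gate_threshold
            if len(state.population):
                bar = max(bar, config.gate_kappa * state.population.best().cost.total)
            decision: SkipDecision = should_skip(
                state.surrogate if state.surrogate is not None else _PASS,
                cand.x, bar,
            )
            cand.predicted_cost = decision.predicted_cost
            if decision.skipped and rng.random() >= config.gate_exploration:
                cand.state = "skipped"
                state.n_skipped += 1
                _push_best()
                _log(state, cand, "de")
                if _stagnated():
                    break
                continue
        _true_evaluate(cand)
        _push_best()
        _log(state, cand, "de")
        if _stagnated():
            break

    # --- phase 3: surrogate-guided refinement ---
    state.phase = "refine"
    if config.refine_count > 0 and state.n_proposed < budget and len(state.population) > 0:
        _maybe_retrain(force=True)
        if state.surrogate is not None and getattr(state.surrogate, "trained", False):
            for _ in range(config.refine_count):
                if state.n_proposed >= budget:
                    break
                cand = refine(state.surrogate, state.population, config.bounds, rng)
                state.n_proposed += 1
                _true_evaluate(cand)
                _push_best()
                _log(state, cand, "refine")
                _maybe_retrain()

    state.phase = "done"
    return state


class _Pass:
    trained = False


_PASS = _Pass()
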