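"""Random-walk, differential-evolution and refinement mechanics."""

import numpy as np
import pytest

from eccwater import (
    Candidate,
    CostValue,
    DEFAULT_BOUNDS,
    DEParams,
    INITIAL_GUESS,
    OptimizerConfig,
    Population,
    ToyEvaluator,
    ToyLandscapeConfig,
    VARIANT_ECC,
    accept_candidate,
    de_propose,
    denormalize_params,
    normalize_params,
    random_walk_step,
    refine,
    run_optimization,
)


def make_candidate(x, cost_total=None):
    x = np.asarray(x, dtype=float)
    cand = Candidate(params=denormalize_params(x), x=x, provenance="de")
    if cost_total is not None:
        cand.cost = CostValue(total=cost_total, variant=VARIANT_ECC)
        cand.state = "evaluated"
    return cand


def seeded_population(points_with_costs, capacity=96):
    pop = Population(capacity=capacity)
    for x, c in points_with_costs:
        accept_candidate(make_candidate(x, c), pop)
    return pop


class TestRandomWalk:
    def test_stays_in_bounds_over_long_walks(self, rng):
        cand = make_candidate(normalize_params(INITIAL_GUESS))
        for _ in range(10_000):
            cand = random_walk_step(cand, DEFAULT_BOUNDS, 0.02, rng)
            assert np.all(cand.x >= 0.0) and np.all(cand.x <= 1.0)
            assert DEFAULT_BOUNDS.contains(cand.params, atol=1e-12)

    def test_tiny_step_stays_near_start(self, rng):
        x0 = normalize_params(INITIAL_GUESS)
        cand = make_candidate(x0)
        for _ in range(100):
            cand = random_walk_step(cand, DEFAULT_BOUNDS, 1e-9, rng)
        np.testing.assert_allclose(cand.x, x0, atol=1e-6)

    def test_reflected_walk_covers_each_range(self, rng):
        # ergodicity: marginal occupancy should span nearly the whole range
        # (step chosen so the 1-D crossing time is well under the walk length)
        cand = make_candidate(normalize_params(INITIAL_GUESS))
        visited = np.empty((10_000, 6))
        for i in range(10_000):
            cand = random_walk_step(cand, DEFAULT_BOUNDS, 0.05, rng)
            visited[i] = cand.x
        span = visited.max(axis=0) - visited.min(axis=0)
        assert np.all(span >= 0.95)

    def test_invalid_step_scale_rejected(self, rng):
        cand = make_candidate(np.full(6, 0.5))
        for bad in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                random_walk_step(cand, DEFAULT_BOUNDS, bad, rng)


class TestDifferentialEvolution:
    def test_identical_population_returns_that_point(self, rng):
        x = np.full(6, 0.4)
        pop = seeded_population([(x, 0.5 + 1e-6 * i) for i in range(6)])
        prop = de_propose(pop, DEFAULT_BOUNDS, DEParams(), rng)
        np.testing.assert_allclose(prop.x, x, atol=1e-12)

    def test_degenerate_de_copies_a_member(self, rng):
        pts = [np.full(6, v) for v in (0.2, 0.4, 0.6, 0.8)]
        pop = seeded_population([(p, 0.1 * i) for i, p in enumerate(pts)])
        prop = de_propose(pop, DEFAULT_BOUNDS,
                          DEParams(F=1e-300, CR=1.0, dither=0.0), rng)
        assert any(np.allclose(prop.x, p, atol=1e-12) for p in pts)

    def test_proposals_always_in_unit_cube(self, rng):
        pop = seeded_population(
            [(rng.random(6), float(i)) for i in range(20)]
        )
        for _ in range(200):
            prop = de_propose(pop, DEFAULT_BOUNDS, DEParams(), rng)
            assert np.all(prop.x >= 0.0) and np.all(prop.x <= 1.0)

    def test_small_population_rejected(self, rng):
        pop = seeded_population([(np.full(6, 0.5), 0.1)])
        with pytest.raises(ValueError):
            de_propose(pop, DEFAULT_BOUNDS, DEParams(), rng)


class TestPopulation:
    def test_insert_evicts_worst_at_capacity(self):
        pop = seeded_population([(np.full(6, 0.5), 0.30), (np.full(6, 0.4), 0.10)],
                                capacity=2)
        accept_candidate(make_candidate(np.full(6, 0.6), 0.25), pop)
        costs = sorted(c.cost.total for c in pop.members)
        assert costs == [0.10, 0.25]

    def test_tie_with_worst_keeps_incumbent(self):
        incumbent = make_candidate(np.full(6, 0.5), 0.30)
        pop = Population(capacity=1)
        accept_candidate(incumbent, pop)
        accept_candidate(make_candidate(np.full(6, 0.6), 0.30), pop)
        assert pop.members == [incumbent]

    def test_best_cost_monotone_under_insertions(self, rng):
        pop = Population(capacity=8)
        best_seen = np.inf
        for i in range(50):
            accept_candidate(make_candidate(rng.random(6), float(rng.uniform(0, 1))), pop)
            assert pop.best().cost.total <= best_seen + 1e-15
            best_seen = pop.best().cost.total

    def test_unevaluated_candidate_rejected(self):
        pop = Population()
        with pytest.raises(ValueError):
            accept_candidate(make_candidate(np.full(6, 0.5)), pop)


class QuadraticSurrogate:
    """Analytic convex bowl standing in for a trained cost surrogate."""

    trained = True

    def __init__(self, center):
        self.center = np.asarray(center, dtype=float)

    def predict(self, X):
        X = np.atleast_2d(X)
        d = X - self.center
        return np.sum(d * d, axis=1)

    def predict_one(self, x):
        return float(self.predict(x)[0])


class TestRefine:
    def test_finds_minimum_of_convex_bowl(self, rng):
        center = np.array([0.52, 0.31, 0.77, 0.45, 0.62, 0.28])
        surrogate = QuadraticSurrogate(center)
        pop = seeded_population([(rng.random(6), float(i)) for i in range(8)])
        prop = refine(surrogate, pop, DEFAULT_BOUNDS, rng)
        np.testing.assert_allclose(prop.x, center, atol=0.01)

    def test_never_leaves_unit_cube(self, rng):
        surrogate = QuadraticSurrogate(np.full(6, 1.2))  # minimum outside the box
        pop = seeded_population([(rng.random(6), float(i)) for i in range(8)])
        prop = refine(surrogate, pop, DEFAULT_BOUNDS, rng)
        assert np.all(prop.x >= 0.0) and np.all(prop.x <= 1.0)

    def test_untrained_surrogate_rejected(self, rng):
        from eccwater import PassThroughSurrogate

        pop = seeded_population([(np.full(6, 0.5), 0.1)])
        with pytest.raises(ValueError):
            refine(PassThroughSurrogate(), pop, DEFAULT_BOUNDS, rng)


class TestRunOptimization:
    def test_zero_budget_returns_empty_state(self):
        st = run_optimization(ToyEvaluator(), budget=0,
                              config=OptimizerConfig(seed=0))
        assert st.n_proposed == st.n_evaluated == 0
        assert len(st.population) == 0 and st.ledger == []

    def test_every_logged_candidate_in_bounds(self):
        cfg = OptimizerConfig(seed=4, rw_count=60, refine_count=0,
                              gate_threshold=None)
        st = run_optimization(ToyEvaluator(ToyLandscapeConfig(seed=4)),
                              budget=200, config=cfg)
        df = st.ledger_frame()
        xcols = [f"x{j}" for j in range(6)]
        assert len(df) == 200
        assert (df[xcols].to_numpy() >= -1e-12).all()
        assert (df[xcols].to_numpy() <= 1 + 1e-12).all()

    def test_best_cost_history_non_increasing(self):
        cfg = OptimizerConfig(seed=5, rw_count=60, refine_count=0,
                              gate_threshold=None)
        st = run_optimization(ToyEvaluator(ToyLandscapeConfig(seed=5)),
                              budget=300, config=cfg)
        hist = np.array(st.best_history)
        assert np.all(np.diff(hist) <= 1e-15)

    def test_fixed_seed_reproduces_ledger_exactly(self):
        def one():
            cfg = OptimizerConfig(seed=9, rw_count=50, refine_count=5)
            return run_optimization(
                ToyEvaluator(ToyLandscapeConfig(seed=9)), budget=260, config=cfg
            ).ledger_frame()

        a, b = one(), one()
        assert a.equals(b)

    def test_failed_evaluations_are_survived(self):
        calls = {"n": 0}
        inner = ToyEvaluator(ToyLandscapeConfig(seed=1))

        def flaky(params, warm_start=None):
            calls["n"] += 1
            if calls["n"] % 5 == 0:
                raise RuntimeError("engine crashed")
            return inner(params, warm_start)

        cfg = OptimizerConfig(seed=1, rw_count=40, refine_count=0, gate_threshold=None)
        st = run_optimization(flaky, budget=120, config=cfg)
        assert st.n_failed > 0
        assert st.n_evaluated + st.n_failed == st.n_proposed
        assert len(st.population) > 0

    def test_gate_disabled_evaluates_everything(self):
        cfg = OptimizerConfig(seed=2, rw_count=50, refine_count=0, gate_threshold=None)
        st = run_optimization(ToyEvaluator(ToyLandscapeConfig(seed=2)),
                              budget=150, config=cfg)
        assert st.n_skipped == 0 and st.n_evaluated == 150
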