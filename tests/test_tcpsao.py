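import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafseg import (
    OptimizerConfig,
    benchmark_objective,
    init_population,
    melting_rate,
    optimize,
    select_elite,
    step,
    tent_iterates,
    tent_map,
)
from leafseg.tcpsao import _subpopulation_split, make_state


def _cfg(**kwargs):
    defaults = dict(n_particles=20, dim=5, h_max=50, lb=-5.0, ub=5.0, seed=0)
    defaults.update(kwargs)
    return OptimizerConfig(**defaults)


class TestTentMap:
    def test_zero_is_fixed_point(self):
        assert tent_map(0.0) == 0.0

    def test_apex_maps_to_one(self):
        assert tent_map(0.5, alpha=0.5) == 1.0

    def test_left_branch_scalar_evaluation(self):
        assert tent_map(0.25, alpha=0.5) == 0.5

    def test_output_stays_in_unit_interval(self):
        x = np.linspace(0, 1, 1001)
        for alpha in (0.3, 0.5, 0.7):
            y = tent_map(x, alpha)
            assert y.min() >= 0 and y.max() <= 1

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(min_value=0.0, max_value=1.0),
        alpha=st.floats(min_value=0.01, max_value=0.99),
    )
    def test_maps_unit_interval_onto_itself(self, x, alpha):
        y = tent_map(x, alpha)
        assert 0.0 <= y <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tent_map(1.5)
        with pytest.raises(ValueError):
            tent_map(0.5, alpha=1.0)

    def test_chained_iterates_survive_precision_collapse(self):
        out = tent_iterates(np.pi - 3, 5000, rng=0)
        assert out.min() > 0 and out.max() < 1


class TestInitPopulation:
    def test_within_bounds_unit_box(self):
        cfg = _cfg(lb=0.0, ub=1.0)
        pop = init_population(cfg)
        assert pop.min() >= 0 and pop.max() <= 1

    def test_within_narrow_bounds(self):
        cfg = _cfg(lb=1.0, ub=1.0 + 1e-9)
        pop = init_population(cfg)
        assert (pop >= 1.0).all() and (pop <= 1.0 + 1e-9).all()

    def test_fixed_seed_is_bit_identical(self):
        cfg = _cfg(seed=123)
        assert np.array_equal(init_population(cfg), init_population(cfg))


class TestMeltingRate:
    def test_initial_iteration_value(self):
        for h_max in (1, 10, 100, 12345):
            assert melting_rate(0, h_max) == pytest.approx(0.35, abs=1e-15)

    def test_final_iteration_closed_form(self):
        assert melting_rate(100, 100) == pytest.approx(0.6 / np.e, abs=1e-12)

    def test_positive_throughout(self):
        assert all(melting_rate(h, 200) > 0 for h in range(201))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            melting_rate(101, 100)


class TestSelectElite:
    def test_degenerate_population_returns_shared_vector(self):
        cfg = _cfg(n_particles=4, dim=3)
        pos = np.tile([1.0, 2.0, 3.0], (4, 1))
        state = make_state(lambda x: 0.0, pos)
        elite = select_elite(state, np.random.default_rng(0))
        assert np.array_equal(elite, [1.0, 2.0, 3.0])

    def test_uniform_selection_frequencies(self):
        rng = np.random.default_rng(5)
        pos = np.diag([1.0, 2.0, 3.0, 4.0])
        state = make_state(lambda x: float(x.max()), pos)
        options = [
            state.gbest,
            pos[1],
            pos[2],
            state.leaders_centroid(),
        ]
        hits = np.zeros(4)
        draws = 10_000
        for _ in range(draws):
            elite = select_elite(state, rng)
            hits[next(i for i, o in enumerate(options) if np.allclose(o, elite))] += 1
        assert np.allclose(hits / draws, 0.25, atol=0.02)

    def test_leaders_centroid_hand_computation(self):
        # fitness f_i = i on basis vectors: top half = first N/2 basis vectors
        n = 6
        pos = np.eye(n)
        state = make_state(lambda x: float(np.argmax(x)), pos)
        expected = np.eye(n)[: n // 2].mean(axis=0)
        assert np.allclose(state.leaders_centroid(), expected)


class TestStep:
    def test_global_best_never_worsens(self):
        sphere = benchmark_objective("sphere", 5)
        befores, afters = [], []
        for seed in range(50):
            cfg = _cfg(seed=seed)
            rng = np.random.default_rng(seed)
            state = make_state(sphere, init_population(cfg, rng))
            befores.append(state.gbest_f)
            step(state, sphere, cfg, rng)
            afters.append(state.gbest_f)
            assert state.gbest_f <= befores[-1]
        assert np.mean(afters) <= np.mean(befores)

    def test_positions_clamped_to_bounds(self):
        sphere = benchmark_objective("sphere", 5)
        cfg = _cfg(lb=-0.5, ub=0.5)
        rng = np.random.default_rng(2)
        state = make_state(sphere, init_population(cfg, rng))
        for _ in range(20):
            step(state, sphere, cfg, rng)
            assert (state.positions >= -0.5).all() and (state.positions <= 0.5).all()

    def test_fixed_seed_identical_trajectories(self):
        sphere = benchmark_objective("sphere", 5)
        trajectories = []
        for _ in range(2):
            cfg = _cfg(seed=9)
            rng = np.random.default_rng(9)
            state = make_state(sphere, init_population(cfg, rng))
            for _ in range(10):
                step(state, sphere, cfg, rng)
            trajectories.append(state.positions.copy())
        assert np.array_equal(*trajectories)

    def test_non_finite_objective_raises(self):
        cfg = _cfg()
        rng = np.random.default_rng(0)
        with pytest.raises(FloatingPointError):
            make_state(lambda x: float("nan"), init_population(cfg, rng))

    def test_subpopulation_schedule(self):
        n, h_max = 30, 200
        rng = np.random.default_rng(0)
        sizes = []
        for h in range(h_max):
            ia, ib = _subpopulation_split(n, h, h_max, rng)
            assert len(ia) + len(ib) == n
            assert len(np.union1d(ia, ib)) == n
            sizes.append(len(ib))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] == n // 2 and sizes[-1] >= 1


class TestOptimize:
    def test_constant_objective_flat_history(self):
        result = optimize(lambda x: 3.5, _cfg(h_max=20))
        assert result.fun == 3.5
        assert (result.history == 3.5).all()

    def test_one_dimensional_recovery(self):
        cfg = OptimizerConfig(n_particles=30, dim=1, h_max=100, lb=0.0, ub=5.0, seed=0)
        result = optimize(lambda x: (x[0] - 2.0) ** 2, cfg)
        assert abs(result.x[0] - 2.0) < 0.01

    @pytest.mark.parametrize("variant", ["tcpsao", "sao", "pso"])
    def test_history_non_increasing_for_every_variant(self, variant):
        sphere = benchmark_objective("sphere", 5)
        for seed in range(3):
            result = optimize(sphere, _cfg(seed=seed), variant=variant)
            assert (np.diff(result.history) <= 0).all()
            assert result.fun == result.history[-1]

    def test_sao_ablation_depends_only_on_seed(self):
        rastrigin = benchmark_objective("rastrigin", 5)
        a = optimize(rastrigin, _cfg(seed=4), variant="sao")
        b = optimize(rastrigin, _cfg(seed=4), variant="sao")
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.x, b.x)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            optimize(lambda x: 0.0, _cfg(), variant="simulated-annealing")

    def test_evaluation_count(self):
        cfg = _cfg(h_max=10)
        result = optimize(lambda x: float(np.sum(x**2)), cfg)
        assert result.nfev == cfg.n_particles * (cfg.h_max + 1)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_particles": 3},
            {"h_max": 0},
            {"alpha": 0.0},
            {"alpha": 1.0},
            {"lb": 5.0, "ub": -5.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            _cfg(**kwargs)
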