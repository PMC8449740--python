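import numpy as np
import pytest

from hybridsvm.fpso import (Particle, SearchSpace, SwarmState,
                            fitness_increment, fpso_minimize,
                            particle_distance, swarm_size, update_particle)
from hybridsvm.fuzzy import FuzzySettings


class TestSwarmSize:
    @pytest.mark.parametrize("M, expected", [(2, 12), (1, 12), (9, 16)])
    def test_heuristic_rounds_down(self, M, expected):
        assert swarm_size(M) == expected

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            swarm_size(0)


class TestDistances:
    def test_identical_points_zero(self):
        assert particle_distance([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_three_four_five(self):
        assert particle_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_box_diagonal(self):
        space = SearchSpace((0.0, 0.0), (30.0, 30.0))
        assert space.delta_max == pytest.approx(42.4264, abs=5e-5)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            particle_distance([0, 0], [1, 2, 3])


class TestFitnessIncrement:
    def test_zero_step_zero(self):
        assert fitness_increment(0.0, 10.0, 0.9, 0.1, 1.0) == 0.0

    def test_unchanged_fitness_zero(self):
        assert fitness_increment(5.0, 10.0, 0.4, 0.4, 1.0) == 0.0

    def test_worked_example(self):
        # half-diagonal step, fitness 0.4 -> 0.2 with worst 0.4: -0.25
        assert fitness_increment(5.0, 10.0, 0.4, 0.2, 0.4) == pytest.approx(-0.25)

    def test_zero_worst_fitness_defined_as_zero(self):
        assert fitness_increment(5.0, 10.0, 0.0, 0.0, 0.0) == 0.0

    def test_bounded_given_capped_fitness(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            f_wor = rng.uniform(0.1, 2.0)
            phi = fitness_increment(rng.uniform(0, 10), 10.0,
                                    rng.uniform(0, f_wor),
                                    rng.uniform(0, f_wor), f_wor)
            assert -1 <= phi <= 1


def _particle(x, v, best=None, fit=0.5, settings=None):
    x = np.asarray(x, float)
    return Particle(position=x.copy(), velocity=np.asarray(v, float),
                    best=np.asarray(best if best is not None else x, float),
                    best_fitness=fit, fitness=fit,
                    settings=settings or FuzzySettings(1.0, 0.0, 0.0, 0.0, 1.0))


class TestUpdateParticle:
    SPACE = SearchSpace((0.0, 0.0), (10.0, 10.0))

    def test_pure_inertia_keeps_velocity(self):
        p = _particle([5, 5], [0.5, -0.25])
        update_particle(p, np.array([5.0, 5.0]), self.SPACE,
                        np.random.default_rng(0))
        np.testing.assert_allclose(p.velocity, [0.5, -0.25])
        np.testing.assert_allclose(p.position, [5.5, 4.75])

    def test_velocity_clamped_to_eta_range(self):
        s = FuzzySettings(w=1.0, c_soc=0.0, c_cog=0.0, lam=0.0, eta=0.2)
        p = _particle([5, 5], [100.0, -100.0], settings=s)
        update_particle(p, np.array([5.0, 5.0]), self.SPACE,
                        np.random.default_rng(0))
        np.testing.assert_allclose(np.abs(p.velocity), 0.2 * 10.0)

    def test_minimum_velocity_floor_preserves_sign(self):
        s = FuzzySettings(w=1.0, c_soc=0.0, c_cog=0.0, lam=0.01, eta=0.2)
        p = _particle([5, 5], [1e-6, -1e-6], settings=s)
        update_particle(p, np.array([5.0, 5.0]), self.SPACE,
                        np.random.default_rng(0))
        np.testing.assert_allclose(p.velocity, [0.1, -0.1])

    def test_absorbing_wall_zeroes_velocity(self):
        s = FuzzySettings(w=1.0, c_soc=0.0, c_cog=0.0, lam=0.0, eta=1.0)
        p = _particle([10, 5], [3.0, 0.5], settings=s)
        update_particle(p, np.array([5.0, 5.0]), self.SPACE,
                        np.random.default_rng(0))
        assert p.position[0] == 10.0 and p.velocity[0] == 0.0
        assert p.velocity[1] == 0.5

    def test_repel_flag_flips_attraction(self):
        s = FuzzySettings(w=0.0, c_soc=1.0, c_cog=0.0, lam=0.0, eta=1.0)
        g = np.array([9.0, 9.0])
        rng_a, rng_b = np.random.default_rng(3), np.random.default_rng(3)
        pa, pb = _particle([5, 5], [0, 0], settings=s), _particle([5, 5], [0, 0], settings=s)
        update_particle(pa, g, self.SPACE, rng_a)
        update_particle(pb, g, self.SPACE, rng_b, repel=True)
        assert np.all(pa.position >= 5.0) and np.all(pb.position <= 5.0)


class TestMinimize:
    SPACE2 = SearchSpace((-5.0, -5.0), (5.0, 5.0))

    def test_sphere_converges(self):
        hits = sum(
            fpso_minimize(lambda x: float(np.sum(x ** 2)), self.SPACE2,
                          max_iter=100, seed=seed).best_fitness < 1e-2
            for seed in range(10))
        assert hits >= 9

    def test_constant_objective_flat_trace(self):
        res = fpso_minimize(lambda x: 3.25, self.SPACE2, max_iter=10, seed=0)
        assert res.best_fitness == 3.25
        assert np.all(res.trace_fitness() == 3.25)

    def test_1d_quadratic_finds_minimum(self):
        hits = 0
        for seed in range(10):
            res = fpso_minimize(lambda x: float((x[0] - 2) ** 2),
                                SearchSpace((-5.0,), (5.0,)),
                                max_iter=50, seed=seed)
            hits += abs(res.best_position[0] - 2) < 0.05
        assert hits >= 9

    def test_trace_monotone_and_sized(self):
        res = fpso_minimize(lambda x: float(np.sum(np.abs(x))), self.SPACE2,
                            max_iter=30, seed=5)
        fs = res.trace_fitness()
        assert len(fs) == 30
        assert np.all(np.diff(fs) <= 0)

    def test_positions_stay_inside_box(self):
        seen = []

        def objective(x):
            seen.append(x.copy())
            return float(np.sum(x ** 2))

        fpso_minimize(objective, self.SPACE2, max_iter=20, seed=1)
        pts = np.array(seen)
        assert np.all(pts >= -5.0) and np.all(pts <= 5.0)

    def test_identical_seed_identical_trace(self):
        f = lambda x: float(np.sum(x ** 2))  # noqa: E731
        a = fpso_minimize(f, self.SPACE2, max_iter=25, seed=9)
        b = fpso_minimize(f, self.SPACE2, max_iter=25, seed=9)
        np.testing.assert_array_equal(a.trace_fitness(), b.trace_fitness())
        np.testing.assert_array_equal(a.best_position, b.best_position)
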