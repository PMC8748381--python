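import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromforge.gradsim import LSSParams, simulate_separation
from chromforge.optimize import (
    SearchSpace,
    de_minimize,
    decode_program,
    optimize_separation,
    pareto_filter,
)

SPHERE_SPACE = SearchSpace(tuple((f"x{i}", -5.0, 5.0) for i in range(5)))


def sphere(x):
    return float(np.sum(x**2))


class TestDeMinimize:
    def test_sphere_converges(self):
        _, best = de_minimize(sphere, SPHERE_SPACE, pop=40, gens=200, seed=1)
        assert best < 1e-6

    def test_same_seed_identical_trajectory(self):
        hist1, hist2 = [], []
        de_minimize(sphere, SPHERE_SPACE, pop=20, gens=30, seed=7,
                    callback=lambda g, x, f: hist1.append(f))
        de_minimize(sphere, SPHERE_SPACE, pop=20, gens=30, seed=7,
                    callback=lambda g, x, f: hist2.append(f))
        assert hist1 == hist2

    def test_bounds_respected_under_adversarial_objective(self):
        # rewards leaving the box: any out-of-bounds vector would win
        lo, hi = -1.0, 2.0
        space = SearchSpace((("a", lo, hi), ("b", lo, hi)))

        seen = []

        def objective(x):
            seen.append(x.copy())
            return -float(np.sum(np.abs(x)))

        best, _ = de_minimize(objective, space, pop=10, gens=20, seed=0)
        arr = np.array(seen)
        assert arr.min() >= lo - 1e-12 and arr.max() <= hi + 1e-12
        assert np.all(best >= lo) and np.all(best <= hi)

    def test_nonfinite_objective_rejected_not_fatal(self):
        def objective(x):
            return math.nan if x[0] > 0 else float(np.sum(x**2))

        best, val = de_minimize(objective, SPHERE_SPACE, pop=12, gens=40, seed=2)
        assert math.isfinite(val)
        assert best[0] <= 0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            de_minimize(sphere, SPHERE_SPACE, pop=3)
        with pytest.raises(ValueError):
            de_minimize(sphere, SPHERE_SPACE, F=2.5)
        with pytest.raises(ValueError):
            de_minimize(sphere, SPHERE_SPACE, CR=1.5)


class TestParetoFilter:
    def test_single_point(self):
        assert pareto_filter([(1.0, 2.0)]) == [0]

    def test_dominated_point_removed(self):
        assert pareto_filter([(1, 2), (2, 1), (2, 2)]) == [0, 1]

    def test_duplicates_of_nondominated_point_retained(self):
        assert pareto_filter([(1, 1), (1, 1), (3, 0)]) == [0, 1, 2]

    def test_empty_input(self):
        assert pareto_filter([]) == []

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_dominance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((100, 2))
        keep = set(pareto_filter(pts))
        brute = {
            i
            for i, p in enumerate(pts)
            if not any(
                np.all(q <= p) and np.any(q < p)
                for j, q in enumerate(pts)
                if j != i
            )
        }
        assert keep == brute


class TestDecodeProgram:
    def test_any_inbounds_vector_gives_valid_program(self):
        space = SearchSpace(
            (("phi_initial", 0.0, 1.0), ("phi_final", 0.0, 1.0), ("t_G", 1.0, 30.0))
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = space.lows + rng.random(3) * (space.highs - space.lows)
            prog = decode_program(space, v)
            times = [t for t, _ in prog.nodes]
            assert times == sorted(times)
            assert all(0 <= p <= 1 for _, p in prog.nodes)

    def test_two_segment_encoding(self):
        space = SearchSpace(
            (
                ("phi_initial", 0.0, 0.3),
                ("phi_final", 0.5, 1.0),
                ("t_G", 5.0, 20.0),
                ("t_mid_frac", 0.0, 1.0),
                ("phi_mid", 0.0, 1.0),
            )
        )
        prog = decode_program(space, np.array([0.1, 0.9, 10.0, 0.4, 0.5]))
        assert len(prog.nodes) == 3
        assert prog.nodes[1] == (4.0, 0.5)


class TestOptimizeSeparation:
    TOY = {"A": LSSParams(2.0, 5.0), "B": LSSParams(1.4, 3.0)}  # lines cross at phi 0.3

    def test_isocratic_crossing_point_avoided(self):
        space = SearchSpace((("phi_initial", 0.05, 0.6),))
        defaults = {"isocratic": 1.0, "t_G": 0.0}
        front = optimize_separation(
            self.TOY, space, mode="pareto", seed=3, pop=20, gens=60,
            program_defaults=defaults, rs_cap=math.inf,
        )
        # Rs = 0 exactly at phi = 0.3: no front member sits there
        assert all(abs(m.vector[0] - 0.3) > 0.01 for m in front.members)
        # grid-search oracle over the same space
        best = 0.0
        for phi in np.linspace(0.05, 0.6, 50):
            prog = decode_program(space, np.array([phi]), defaults=defaults)
            sim = simulate_separation(self.TOY, prog)
            if math.isfinite(sim.runtime):
                best = max(best, sim.critical_Rs)
        assert front.best_critical_Rs >= 0.98 * best

    def test_single_component_minimizes_runtime(self):
        space = SearchSpace((("phi_initial", 0.05, 0.9),))
        defaults = {"isocratic": 1.0, "t_G": 0.0}
        front = optimize_separation(
            {"A": LSSParams(2.0, 4.0)}, space, mode="threshold_time", seed=1,
            pop=15, gens=30, program_defaults=defaults,
        )
        best = front.members[0]
        # runtime-minimal isocratic program pushes phi to its upper bound
        assert best.vector[0] > 0.85

    def test_front_is_self_consistent_under_pareto_filter(self):
        space = SearchSpace((("phi_initial", 0.05, 0.5), ("t_G", 2.0, 15.0)))
        front = optimize_separation(
            self.TOY, space, mode="pareto", seed=5, pop=16, gens=25,
        )
        objs = [(-m.objectives[0], m.objectives[1]) for m in front.members]
        keep = pareto_filter(objs)
        assert sorted(keep) == list(range(len(front.members)))

    def test_weighted_mode_returns_single_best(self):
        space = SearchSpace((("phi_initial", 0.05, 0.6),))
        front = optimize_separation(
            self.TOY, space, mode="weighted", seed=2, pop=15, gens=25,
            program_defaults={"isocratic": 1.0, "t_G": 0.0},
        )
        assert len(front.members) == 1
        assert front.members[0].objectives[0] > 1.0

    def test_runtime_objective_is_last_elution_not_gradient_time(self):
        space = SearchSpace((("phi_initial", 0.05, 0.6),))
        defaults = {"isocratic": 1.0, "t_G": 0.0}
        front = optimize_separation(
            self.TOY, space, mode="pareto", seed=4, pop=12, gens=15,
            program_defaults=defaults,
        )
        m = front.best_by_Rs()
        sim = simulate_separation(self.TOY, m.program)
        assert m.objectives[1] == pytest.approx(sim.runtime)
        assert m.objectives[1] != pytest.approx(m.program.span)
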