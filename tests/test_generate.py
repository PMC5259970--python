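"""Random (average-case) and Zhang (worst-case) instance generators."""

import pytest

from partialdigest import (
    InfeasibleParams,
    RandomInstanceParams,
    ZhangInstanceParams,
    delta_set,
    generate_random_instance,
    generate_zhang_instance,
    solve_bbb,
    solve_bbb2,
    solve_bbd,
    validate_instance,
)


class TestRandomInstances:
    def test_shape_and_bounds(self):
        X, D = generate_random_instance(RandomInstanceParams(n=5, M=50, seed=3))
        assert len(X) == 5 and len(D) == 10
        assert X[0] == 0 and max(X) <= 50
        assert len(set(X)) == 5
        assert D == delta_set(X)

    def test_forced_outcome_at_minimal_m(self):
        X, D = generate_random_instance(RandomInstanceParams(n=2, M=1))
        assert X == (0, 1)
        assert D.to_sorted_list() == [1]

    def test_seed_determinism(self):
        p = RandomInstanceParams(n=8, M=80, seed=42)
        assert generate_random_instance(p) == generate_random_instance(p)
        X2, _ = generate_random_instance(RandomInstanceParams(n=8, M=80, seed=43))
        assert X2 != generate_random_instance(p)[0]

    def test_solver_round_trip_recovers_generator(self):
        for seed in range(5):
            X, D = generate_random_instance(
                RandomInstanceParams(n=7, M=70, seed=seed)
            )
            assert X in solve_bbb(validate_instance(D))

    def test_infeasible_params_rejected(self):
        with pytest.raises(InfeasibleParams):
            RandomInstanceParams(n=5, M=3)
        with pytest.raises(InfeasibleParams):
            RandomInstanceParams(n=1, M=10)


class TestZhangInstances:
    @pytest.mark.parametrize("nb", [1, 2, 3, 5])
    def test_cardinality(self, nb):
        A, D = generate_zhang_instance(ZhangInstanceParams(n=nb, seed=1))
        assert len(A) == 5 * nb + 2
        assert len(D) == (5 * nb + 2) * (5 * nb + 1) // 2

    def test_endpoints_present(self):
        p = ZhangInstanceParams(n=3, seed=9)
        A, _ = generate_zhang_instance(p)
        assert A[0] == 0 and A[-1] == p.scale

    @pytest.mark.parametrize(
        "nb, scale, eps",
        [(2, 1000, 41), (3, 5000, 100), (4, 17000, 350), (6, 100000, 1000)],
    )
    def test_blocks_disjoint_under_eps_bound(self, nb, scale, eps):
        for seed in range(4):
            A, _ = generate_zhang_instance(
                ZhangInstanceParams(n=nb, scale=scale, eps=eps, seed=seed)
            )
            assert len(A) == 5 * nb + 2  # generator raises if blocks collide

    def test_seed_determinism(self):
        p = ZhangInstanceParams(n=4, seed=5)
        assert generate_zhang_instance(p)[0] == generate_zhang_instance(p)[0]

    def test_eps_bound_enforced(self):
        with pytest.raises(InfeasibleParams):
            ZhangInstanceParams(n=3, scale=100, eps=3)  # 12*3*3 = 108 >= 100

    def test_solvers_recover_generator_and_mirror(self):
        p = ZhangInstanceParams(n=2, seed=2)
        A, D = generate_zhang_instance(p)
        result = solve_bbb2(validate_instance(D))
        assert A in result
        assert tuple(sorted(p.scale - a for a in A)) in result

    def test_dedup_win_on_worst_case_instances(self):
        """Coincident distances make depth-first search re-explore identical
        subtrees; the deduplicating solver expands strictly fewer nodes and
        the two-stage variant holds no larger a frontier."""
        for nb, seed in [(3, 1), (4, 2)]:
            _, D = generate_zhang_instance(ZhangInstanceParams(n=nb, seed=seed))
            inst = validate_instance(D)
            rd = solve_bbd(inst)
            rb = solve_bbb(inst)
            r2 = solve_bbb2(inst)
            assert rd.solutions == rb.solutions == r2.solutions
            assert rb.stats.total_nodes < rd.stats.total_nodes
            assert r2.stats.peak_frontier <= rb.stats.peak_frontier
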