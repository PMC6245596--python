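"""Seeded LPs, penalized weights and the extraction loop."""

import numpy as np
import pytest
import scipy.stats

from efmsampler import (
    ExtractionState,
    LPSettings,
    Seed,
    compute_weights,
    generate_seed,
    run_extraction,
    solve_iteration,
    split_reversible,
    update_state,
)
from efmsampler.extraction import INFEASIBLE


class TestGenerateSeed:
    def test_k_equals_n_gives_the_full_index_set(self):
        rng = np.random.default_rng(0)
        assert generate_seed(rng, 4, 4).reaction_indices == frozenset(range(4))

    def test_reproducible_from_identical_rng_state(self):
        a = generate_seed(np.random.default_rng(7), 154, 4)
        b = generate_seed(np.random.default_rng(7), 154, 4)
        assert a.reaction_indices == b.reaction_indices

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            generate_seed(np.random.default_rng(0), 3, 4)

    def test_draws_are_uniform(self):
        # chi-square goodness of fit of per-index draw counts against uniform
        rng = np.random.default_rng(2024)
        n, k, draws = 10, 1, 100_000
        counts = np.zeros(n)
        for _ in range(draws):
            for i in generate_seed(rng, n, k).reaction_indices:
                counts[i] += 1
        pvalue = scipy.stats.chisquare(counts).pvalue
        assert pvalue > 1e-4


class TestComputeWeights:
    @pytest.mark.parametrize(
        "F,p,expected",
        [
            ([0.9, 0.1, 0.0], 5.0, [5.5, 1.5, 1.0]),
            ([0.3, 0.7], 0.0, [1.0, 1.0]),
            ([1.0], 2.0, [3.0]),
        ],
    )
    def test_affine_penalty_formula(self, F, p, expected):
        assert np.allclose(compute_weights(F, p), expected)

    def test_rejects_frequencies_outside_unit_interval(self):
        with pytest.raises(ValueError):
            compute_weights([1.2], 1.0)

    def test_rejects_negative_penalization(self):
        with pytest.raises(ValueError):
            compute_weights([0.5], -1.0)


class TestSolveIteration:
    def test_chain_seed_forces_the_whole_chain(self, chain):
        split = split_reversible(chain)
        sol = solve_iteration(split, Seed({0}), np.ones(3))
        assert np.allclose(sol.v, [1.0, 1.0, 1.0])
        assert sol.support == frozenset({0, 1, 2})
        assert sol.objective == pytest.approx(3.0)

    def test_dead_end_seed_is_infeasible_not_an_exception(self, dead_end):
        split = split_reversible(dead_end)
        assert solve_iteration(split, Seed({1}), np.ones(3)) == INFEASIBLE

    def test_diamond_double_branch_seed_needs_all_four_reactions(self, diamond):
        split = split_reversible(diamond)
        sol = solve_iteration(split, Seed({1, 2}), np.ones(4))
        assert sol.support == frozenset({0, 1, 2, 3})

    def test_weights_below_one_rejected(self, chain):
        with pytest.raises(ValueError, match=">= 1"):
            solve_iteration(split_reversible(chain), Seed({0}), np.full(3, 0.5))

    def test_seed_flux_respects_lower_bound(self, parallel5):
        split = split_reversible(parallel5)
        settings = LPSettings(seed_lower_bound=2.5)
        sol = solve_iteration(split, Seed({2}), np.ones(split.n_split), settings)
        assert sol.v[2] >= 2.5 * (1 - 1e-9)


class TestUpdateState:
    def test_counting_arithmetic(self):
        state = ExtractionState(n_split=3, p=0.0, N=3, O=np.array([3, 2, 1]))
        sol_support = frozenset({0, 2})
        sol = _fake_solution(sol_support)
        update_state(state, sol)
        assert state.N == 4
        assert state.O.tolist() == [4, 2, 2]
        assert np.allclose(state.F, [1.0, 0.5, 0.5])

    def test_first_solution_with_full_support_gives_unit_frequencies(self):
        state = ExtractionState(n_split=3, p=0.0)
        update_state(state, _fake_solution(frozenset({0, 1, 2})))
        assert np.allclose(state.F, 1.0)

    def test_weights_follow_the_penalty_formula(self):
        state = ExtractionState(n_split=1, p=2.0)
        update_state(state, _fake_solution(frozenset({0})))
        assert state.w[0] == pytest.approx(3.0)


def _fake_solution(support):
    from efmsampler import FluxSolution

    return FluxSolution(v=np.zeros(3), support=support, seed=Seed({0}), objective=0.0)


class TestRunExtraction:
    def test_chain_has_a_unique_pathway_support(self, chain):
        res = run_extraction(chain, N_target=10, p=3.0, k=1, rng_seed=5)
        assert res.status == "completed"
        assert all(sol.support == frozenset({0, 1, 2}) for sol in res.solutions)
        assert np.allclose(res.state.F, 1.0)

    def test_diamond_supports_are_pathway_supports(self, diamond):
        # brute force over the diamond: the only pathway supports are the two
        # EFMs {R_in,B1,R_out}, {R_in,B2,R_out} and the full network
        allowed = {frozenset({0, 1, 3}), frozenset({0, 2, 3}), frozenset({0, 1, 2, 3})}
        res = run_extraction(diamond, N_target=50, p=0.0, k=1, rng_seed=11)
        assert {sol.support for sol in res.solutions} <= allowed

    def test_p_zero_dynamic_matches_weight_mode_off(self, random20):
        a = run_extraction(random20, N_target=30, p=0.0, k=4, rng_seed=3, weight_mode="dynamic")
        b = run_extraction(random20, N_target=30, p=0.0, k=4, rng_seed=3, weight_mode="off")
        assert [s.support for s in a.solutions] == [s.support for s in b.solutions]

    def test_supports_are_bit_identical_across_runs(self, random20):
        a = run_extraction(random20, N_target=25, p=5.0, k=4, rng_seed=9)
        b = run_extraction(random20, N_target=25, p=5.0, k=4, rng_seed=9)
        assert [s.support for s in a.solutions] == [s.support for s in b.solutions]

    def test_every_solution_contains_its_seed_and_balances_metabolites(self, splits):
        settings = LPSettings()
        for name, split in splits.items():
            res = run_extraction(split, N_target=20, p=2.0, k=1, rng_seed=1, settings=settings)
            for sol in res.solutions:
                assert sol.seed.reaction_indices <= sol.support, name
                residual = np.abs(split.S_split @ sol.v).max()
                assert residual <= 1e-6 * (1 + sol.v.max()), name
                assert sol.v.min() >= -settings.solver_feas_tol, name

    def test_weight_bounds_hold_at_every_iteration(self, parallel5):
        split = split_reversible(parallel5)
        state = ExtractionState(n_split=split.n_split, p=20.0)
        rng = np.random.default_rng(4)
        for _ in range(30):
            seed = generate_seed(rng, split.n_split, 1)
            out = solve_iteration(split, seed, state.w)
            if out == INFEASIBLE:
                continue
            update_state(state, out)
            assert np.all(state.w >= 1.0) and np.all(state.w <= 1.0 + state.p)
            assert np.all(state.F >= 0.0) and np.all(state.F <= 1.0)
            assert np.all(state.O <= state.N)

    def test_drought_aborts_with_partial_results(self):
        from efmsampler import MetabolicNetwork

        # a single conversion reaction admits no nonzero steady state
        net = MetabolicNetwork(("A", "B"), ("R1",), np.array([[-1.0], [1.0]]),
                               np.zeros(1, bool))
        res = run_extraction(net, N_target=5, p=0.0, k=1, rng_seed=0, drought_cap=10)
        assert res.status == "drought"
        assert res.solutions == []
        assert res.infeasible_count == 10

    def test_two_cycle_seeds_can_be_excluded(self, chain_rev):
        split = split_reversible(chain_rev)
        res = run_extraction(split, N_target=15, p=0.0, k=2, rng_seed=2,
                             allow_two_cycle_seeds=False)
        fwd = split.split_reaction_ids.index("R2_fwd")
        bwd = split.split_reaction_ids.index("R2_bwd")
        for sol in res.solutions:
            assert not {fwd, bwd} <= sol.seed.reaction_indices

    def test_static_weight_mode_uses_the_supplied_frequencies(self, parallel5):
        base = run_extraction(parallel5, N_target=40, p=0.0, k=1, rng_seed=6)
        res = run_extraction(parallel5, N_target=40, p=20.0, k=1, rng_seed=6,
                             weight_mode="static", F0=base.state.F)
        assert res.status == "completed" and res.state.N == 40
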